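import numpy as np
import pytest

import geoadditive as ga
from geoadditive.model import GeoAdditiveLogistic


@pytest.fixture(scope="session")
def small_dataset():
    """Default-truth synthetic survey, 3,000 children on the 6x6 lattice."""
    truth = ga.default_truth(n_children=3000, seed=42)
    return ga.generate(truth)


@pytest.fixture(scope="session")
def small_m3_fit(small_dataset):
    """A quick full geo-additive fit (reduced bases, short chain) shared by
    summary-level tests."""
    ds = small_dataset
    model = GeoAdditiveLogistic(
        form="M3", n_segments=10, spatial_segments=4,
        n_iter=1500, n_burnin=500, random_state=7,
    )
    model.fit(ds.data, "anaemic", geography=ds.geography)
    return model
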