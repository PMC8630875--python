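"""Pre-model descriptive stage: prevalence tables and the chi-square screen."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

__all__ = ["prevalence_by", "chi2_screen"]

OVERALL_LABEL = "Overall"


def prevalence_by(data: pd.DataFrame, grouping: str,
                  outcome: str = "anaemic") -> pd.DataFrame:
    """Percent anaemic and anaemic count per level of ``grouping``.

    Appends an overall row pooling all groups.  Empty groups (possible with
    categorical dtypes) are dropped with a log entry.
    """
    if grouping not in data.columns:
        raise ValueError(f"grouping column {grouping!r} not in data")
    y = data[outcome].astype(float)
    g = data.groupby(grouping, observed=False)[outcome]
    tab = pd.DataFrame({
        "group": g.sum().index.astype(str),
        "percent_anaemic": 100.0 * g.mean().to_numpy(),
        "n_anaemic": g.sum().to_numpy(dtype=int),
        "n_total": g.size().to_numpy(dtype=int),
    })
    empty = tab["n_total"] == 0
    if empty.any():
        logger.info("dropping %d empty group(s) of %r", int(empty.sum()), grouping)
        tab = tab[~empty]
    overall = pd.DataFrame({
        "group": [OVERALL_LABEL],
        "percent_anaemic": [100.0 * y.mean()],
        "n_anaemic": [int(y.sum())],
        "n_total": [len(y)],
    })
    return pd.concat([tab, overall], ignore_index=True)


def chi2_screen(data: pd.DataFrame, covariates: list[str],
                alpha: float = 0.20, outcome: str = "anaemic") -> pd.DataFrame:
    """Pearson chi-square screen of each categorical covariate vs the outcome.

    Returns the full p-value table with a ``retained`` flag (p <= alpha).
    The screen is advisory: model configuration may override inclusion.
    Covariates with a single observed level are excluded with a log entry.
    No continuity correction is applied (large-sample setting).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for cov in covariates:
        sub = data[[cov, outcome]].dropna()
        counts = pd.crosstab(sub[cov], sub[outcome])
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            logger.info("excluding %r from screen: single observed level", cov)
            continue
        stat, p, dof, _ = chi2_contingency(counts.to_numpy(), correction=False)
        rows.append({"covariate": cov, "statistic": stat, "dof": dof,
                     "p_value": p, "retained": p <= alpha})
    return pd.DataFrame(rows)
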