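"""Posterior summaries: DIC comparison, coefficient tables, smooth curves
with credible bands, and credible-interval spatial classification.

All intervals are equal-tailed posterior quantiles with the linear
order-statistic interpolation convention, matching common structured
additive regression software.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .basis import bspline_design
from .model import DesignBlocks, PosteriorDraws

__all__ = [
    "DICResult",
    "dic",
    "compare_models",
    "fixed_effect_table",
    "smooth_curve",
    "classify_spatial",
    "spatial_effect_draws",
]


@dataclasses.dataclass(frozen=True)
class DICResult:
    """Deviance information criterion: DIC = Dbar + pD.

    Dbar is the posterior mean deviance; the effective number of parameters
    pD is Dbar minus the deviance at the posterior-mean parameters.
    """

    dbar: float
    pd: float
    dic: float


def dic(deviance_draws: np.ndarray, deviance_at_mean: float) -> DICResult:
    """DIC from retained deviance draws and the deviance at the posterior mean.

    A negative pD (possible in badly mixing or misspecified fits) is reported
    with a warning rather than clipped.
    """
    deviance_draws = np.asarray(deviance_draws, dtype=float)
    if deviance_draws.size < 2:
        raise ValueError("need at least two deviance draws")
    dbar = float(deviance_draws.mean())
    p_d = dbar - float(deviance_at_mean)
    if p_d < 0:
        warnings.warn(
            f"effective number of parameters pD={p_d:.3f} is negative; "
            "check mixing / model adequacy", RuntimeWarning)
    return DICResult(dbar=dbar, pd=p_d, dic=dbar + p_d)


def compare_models(fits: list[tuple]) -> pd.DataFrame:
    """Rank fitted models by DIC (smallest = preferred).

    ``fits`` is a list of ``(label, DICResult, n_obs)`` triples; all fits
    must be on the same data (identical row counts).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ns = {n for _, _, n in fits}
    if len(ns) != 1:
        raise ValueError(f"fits are on differing datasets (row counts {sorted(ns)})")
    rows = [{"model": label, "deviance": d.dbar, "pD": d.pd, "DIC": d.dic}
            for label, d, _ in fits]
    tab = pd.DataFrame(rows).sort_values("DIC", kind="stable").reset_index(drop=True)
    tab["preferred"] = False
    tab.loc[0, "preferred"] = True
    return tab


def fixed_effect_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, SD, 10%/50%/90% quantiles per fixed-effect coefficient.

    The significance flag marks coefficients whose 95% equal-tailed interval
    excludes zero (5% alpha), even though the printed quantiles are the
    10%/90% pair.
    """
    B = draws.beta
    q = np.quantile(B, [0.10, 0.50, 0.90, 0.025, 0.975], axis=0)
    tab = pd.DataFrame({
        "mean": B.mean(axis=0),
        "sd": B.std(axis=0, ddof=1),
        "q10": q[0], "median": q[1], "q90": q[2],
        "significant": (q[3] > 0) | (q[4] < 0),
    }, index=pd.Index(draws.beta_names, name="coefficient"))
    return tab


def smooth_curve(
    draws: PosteriorDraws,
    blocks: DesignBlocks,
    name: str,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Posterior mean curve of a smooth term with pointwise 95% bands.

    The curve is evaluated on ``grid`` (defaults to an even grid over the
    knot range) under the same centering constraint used in the fit.
    """
    block = next((sb for sb in blocks.smooths if sb.name == name), None)
    if block is None:
        raise ValueError(f"no smooth term named {name!r} in this fit")
    if grid is None:
        grid = np.linspace(block.kv.lower, block.kv.upper, n_grid)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < block.kv.lower) or np.any(grid > block.kv.upper):
        raise ValueError(
            f"grid extends outside knot range "
            f"[{block.kv.lower}, {block.kv.upper}]")
    G = bspline_design(grid, block.kv) - block.col_means
    curves = draws.smooth_coefs[name] @ G.T  # (S, n_grid)
    lo, hi = np.quantile(curves, [0.025, 0.975], axis=0)
    return pd.DataFrame({
        "grid": grid,
        "mean": curves.mean(axis=0),
        "lower": lo,
        "upper": hi,
    })


def spatial_effect_draws(draws: PosteriorDraws, blocks: DesignBlocks) -> np.ndarray:
    """Per-draw spatial effect at each region centroid, shape (S, n_regions)."""
    sp = blocks.spatial
    if sp is None or draws.spatial_coefs is None:
        raise ValueError(
            "fit has no spatial term (M0/M1); spatial classification "
            "requires M2 or M3")
    return draws.spatial_coefs @ sp.Z.T


def classify_spatial(
    draws: PosteriorDraws,
    blocks: DesignBlocks,
    levels: tuple[float, ...] = (0.80, 0.95),
) -> pd.DataFrame:
    """Classify each region's spatial effect by equal-tailed credible interval.

    A region is ``positive`` at a level iff the interval's lower bound is
    above zero, ``negative`` iff the upper bound is below zero, else
    ``insignificant`` — the three-colour map convention (red / blue / light
    gray).  Intervals are nested, so significance at 95% implies
    significance at 80%.
    """
    eff = spatial_effect_draws(draws, blocks)
    out = {"region_id": blocks.spatial.basis.region_ids,
           "mean": eff.mean(axis=0)}
    frame = pd.DataFrame(out)
    for level in levels:
        if not 0 < level < 1:
            raise ValueError(f"level must be in (0,1), got {level}")
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(eff, [alpha, 1.0 - alpha], axis=0)
        tag = f"{int(round(level * 100))}"
        frame[f"lower{tag}"] = lo
        frame[f"upper{tag}"] = hi
        frame[f"category{tag}"] = np.select(
            [lo > 0, hi < 0], ["positive", "negative"], default="insignificant")
    return frame
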