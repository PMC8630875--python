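"""Geo-additive Bernoulli-logit models M0-M3 and their Gibbs sampler.

The linear predictor is

    logit(p) = intercept + z'beta + sum_j f_j(u_j) + f_spatial(region)

with effect-coded categorical fixed effects, P-spline smooths f_j under
random-walk priors, and a spatial term that is either a tensor-product
spline over region centroids or an intrinsic MRF over the neighbourhood
graph.  Inference is by Gibbs sampling with Polya-Gamma augmentation
(omega_i ~ PG(1, eta_i)), which makes every coefficient block conditionally
Gaussian and every smoothing variance conditionally inverse-gamma.

`GeoAdditiveLogistic` wraps the machinery as a scikit-learn style estimator;
`effect_code`, `assemble_design` and `fit_mcmc` are the underlying
module-level operations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from sklearn.base import BaseEstimator

from ._pg import random_polyagamma
from .basis import (
    KnotVector,
    PenaltyMatrix,
    SpatialBasis,
    bspline_design,
    build_knots,
    mrf_spatial_basis,
    tensor_spatial_basis,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "PosteriorDraws",
    "DesignBlocks",
    "effect_code",
    "assemble_design",
    "fit_mcmc",
    "diagnostics",
    "GeoAdditiveLogistic",
    "model_for_form",
]

_RIDGE = 1e-8  # flat-prior fallback precision for numerical stability

FORMS = ("M0", "M1", "M2", "M3")


def effect_code(levels: list[str], reference: str, value: str) -> np.ndarray:
    """Deviation (effect) coding of one categorical value.

    Non-reference level j maps to the indicator row for position j; the
    reference level maps to -1 in every column, so coefficients contrast
    levels against the grand mean.
    """
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among levels {levels}")
    coded_levels = [lv for lv in levels if lv != reference]
    row = np.zeros(len(coded_levels))
    if value == reference:
        row[:] = -1.0
        return row
    try:
        row[coded_levels.index(value)] = 1.0
    except ValueError:
        raise ValueError(
            f"unknown level {value!r}; expected one of {levels}"
        ) from None
    return row


def _effect_code_column(values: pd.Series, levels: list[str], reference: str,
                        name: str) -> tuple[np.ndarray, list[str]]:
    coded_levels = [lv for lv in levels if lv != reference]
    lut = {lv: effect_code(levels, reference, lv) for lv in levels}
    bad = set(values.unique()) - set(levels)
    if bad:
        raise ValueError(
            f"covariate {name!r} has unknown level(s) {sorted(bad)}; "
            f"expected {levels}"
        )
    X = np.stack([lut[v] for v in values])
    return X, [f"{name}[{lv}]" for lv in coded_levels]


@dataclasses.dataclass
class ModelSpec:
    """Configuration of one model form.

    ``fixed`` maps covariate name to its ordered levels with the reference
    level first; ``smooths`` maps continuous covariate name to basis settings.
    M0 has neither smooths nor spatial term, M1 adds the smooths, M2 the
    spatial term, M3 both.
    """

    form: str
    fixed: dict[str, list[str]]
    smooths: dict[str, dict] = dataclasses.field(default_factory=dict)
    spatial: str | None = None  # None | "tensor" | "mrf"
    spatial_segments: int = 8
    spatial_degree: int = 3
    knn_k: int = 4
    a: float = 0.001
    b: float = 0.001

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {self.form!r}")
        wants_smooth = self.form in ("M1", "M3")
        wants_spatial = self.form in ("M2", "M3")
        if wants_smooth != bool(self.smooths):
            raise ValueError(f"form {self.form} and smooths specification disagree")
        if wants_spatial != (self.spatial is not None):
            raise ValueError(f"form {self.form} and spatial specification disagree")


@dataclasses.dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 4000
    n_burnin: int = 1000
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin


@dataclasses.dataclass
class FixedBlock:
    X: np.ndarray
    names: list[str]


@dataclasses.dataclass
class SmoothBlock:
    name: str
    kv: KnotVector
    X: np.ndarray  # centered basis, n x d
    col_means: np.ndarray
    penalty: PenaltyMatrix


@dataclasses.dataclass
class SpatialBlock:
    basis: SpatialBasis
    Z: np.ndarray  # centered region-level design, R x d
    col_means: np.ndarray
    region_index: np.ndarray  # (n,) position of each row's region


@dataclasses.dataclass
class DesignBlocks:
    fixed: FixedBlock
    smooths: list[SmoothBlock]
    spatial: SpatialBlock | None
    n_obs: int
    n_dropped: int
    row_mask: np.ndarray  # boolean mask of retained rows in the input frame


def assemble_design(
    data: pd.DataFrame,
    spec: ModelSpec,
    geography=None,
    adjacency: np.ndarray | None = None,
    n_segments: int = 20,
    degree: int = 3,
    rw_order: int = 2,
    region_col: str = "region_id",
) -> DesignBlocks:
    """Build the fixed, smooth and spatial design blocks for one model.

    Penalized blocks are column-centered on the observed data so they are
    orthogonal to the global intercept; rows with missing values in any used
    covariate are dropped (complete-case) with a logged count.
    """
    used = list(spec.fixed) + list(spec.smooths)
    if spec.spatial is not None:
        used.append(region_col)
    missing_cols = [c for c in used if c not in data.columns]
    if missing_cols:
        raise ValueError(f"covariates missing from data: {missing_cols}")
    mask = data[used].notna().all(axis=1).to_numpy()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("dropping %d rows with missing covariate values", n_dropped)
    df = data.loc[mask]
    n = len(df)

    cols = [np.ones((n, 1))]
    names = ["intercept"]
    for cov, levels in spec.fixed.items():
        X, nm = _effect_code_column(df[cov], list(levels), list(levels)[0], cov)
        cols.append(X)
        names.extend(nm)
    fixed = FixedBlock(X=np.ascontiguousarray(np.hstack(cols)), names=names)

    smooths = []
    for cov, opts in spec.smooths.items():
        kv = build_knots(df[cov].to_numpy(),
                         opts.get("n_segments", n_segments),
                         opts.get("degree", degree), name=cov)
        B = bspline_design(df[cov].to_numpy(), kv)
        mu = B.mean(axis=0)
        smooths.append(SmoothBlock(
            name=cov, kv=kv, X=np.ascontiguousarray(B - mu), col_means=mu,
            penalty=_penalty_for(kv, opts.get("rw_order", rw_order)),
        ))

    spatial = None
    if spec.spatial is not None:
        if geography is None:
            raise ValueError("spatial model requires a geography")
        if spec.spatial == "tensor":
            sb = tensor_spatial_basis(geography.centroids, geography.region_ids,
                                      n_segments=spec.spatial_segments,
                                      degree=spec.spatial_degree)
        elif spec.spatial == "mrf":
            sb = mrf_spatial_basis(geography.centroids, geography.region_ids,
                                   adjacency=adjacency, k=spec.knn_k)
        else:
            raise ValueError(f"unknown spatial mode {spec.spatial!r}")
        rid_pos = {rid: i for i, rid in enumerate(sb.region_ids)}
        try:
            region_index = df[region_col].map(rid_pos).to_numpy(dtype=int)
        except (ValueError, TypeError):
            unknown = sorted(set(df[region_col]) - set(rid_pos))
            raise ValueError(f"regions absent from geography: {unknown}") from None
        counts = np.bincount(region_index, minlength=sb.design.shape[0])
        mu = counts @ sb.design / n  # child-weighted column means
        spatial = SpatialBlock(basis=sb, Z=np.ascontiguousarray(sb.design - mu),
                               col_means=mu, region_index=region_index)

    return DesignBlocks(fixed=fixed, smooths=smooths, spatial=spatial,
                        n_obs=n, n_dropped=n_dropped, row_mask=mask)


def _penalty_for(kv: KnotVector, rw_order: int) -> PenaltyMatrix:
    from .basis import difference_penalty
    return difference_penalty(kv.n_basis, rw_order)


@dataclasses.dataclass
class PosteriorDraws:
    """Retained MCMC draws of every coefficient block plus per-draw deviance."""

    beta: np.ndarray  # (S, p_fixed)
    beta_names: list[str]
    smooth_coefs: dict[str, np.ndarray]  # name -> (S, d)
    spatial_coefs: np.ndarray | None  # (S, d_spatial)
    tau2: dict[str, np.ndarray]  # block name -> (S,)
    deviance: np.ndarray  # (S,)
    deviance_at_mean: float
    eta_mean: np.ndarray
    n_obs: int
    config: McmcConfig

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def trace_frame(self) -> pd.DataFrame:
        """Tidy per-iteration traces of the scalar chains (fixed effects,
        smoothing variances, deviance) for plotting / convergence checks."""
        data = {name: self.beta[:, j]
                for j, name in enumerate(self.beta_names)}
        for k, v in self.tau2.items():
            data[f"tau2[{k}]"] = v
        data["deviance"] = self.deviance
        return pd.DataFrame(data)

    def save(self, path) -> None:
        """Columnar binary container (.npz) plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {"beta": self.beta, "deviance": self.deviance,
                  "eta_mean": self.eta_mean}
        for k, v in self.smooth_coefs.items():
            arrays[f"smooth__{k}"] = v
        if self.spatial_coefs is not None:
            arrays["spatial"] = self.spatial_coefs
        for k, v in self.tau2.items():
            arrays[f"tau2__{k}"] = v
        np.savez_compressed(path / "draws.npz", **arrays)
        manifest = {
            "beta_names": self.beta_names,
            "smooth_terms": list(self.smooth_coefs),
            "has_spatial": self.spatial_coefs is not None,
            "deviance_at_mean": self.deviance_at_mean,
            "n_obs": self.n_obs,
            "config": dataclasses.asdict(self.config),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        with np.load(path / "draws.npz") as z:
            arrays = {k: z[k] for k in z.files}
        return cls(
            beta=arrays["beta"], beta_names=manifest["beta_names"],
            smooth_coefs={k: arrays[f"smooth__{k}"]
                          for k in manifest["smooth_terms"]},
            spatial_coefs=arrays.get("spatial"),
            tau2={k.removeprefix("tau2__"): v for k, v in arrays.items()
                  if k.startswith("tau2__")},
            deviance=arrays["deviance"],
            deviance_at_mean=manifest["deviance_at_mean"],
            eta_mean=arrays["eta_mean"], n_obs=manifest["n_obs"],
            config=McmcConfig(**manifest["config"]),
        )


def _irls_init(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Ridge-penalized IRLS start for the fixed-effect block."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.maximum(mu * (1 - mu), 1e-6)
        H = X.T @ (X * w[:, None]) + _RIDGE * np.eye(p)
        g = X.T @ (y - mu) - _RIDGE * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _bernoulli_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # -2 log-likelihood; log(1 + e^eta) via logaddexp for stability
    return float(-2.0 * (y @ eta - np.logaddexp(0.0, eta).sum()))


def fit_mcmc(
    blocks: DesignBlocks,
    y: np.ndarray,
    cfg: McmcConfig,
    likelihood_weight: float = 1.0,
    fix_tau2: float | None = None,
    init_variance: float = 0.1,
    a: float = 0.001,
    b: float = 0.001,
) -> PosteriorDraws:
    """Polya-Gamma Gibbs sampler for the geo-additive logit model.

    Each sweep draws omega_i ~ PG(1, eta_i), then each coefficient block from
    its Gaussian full conditional with precision X'OmegaX + K/tau^2 (flat
    prior with a tiny ridge on the fixed block), then each smoothing variance
    from inverse-gamma(a + rank(K)/2, b + theta'Ktheta/2).  Deterministic for
    a given ``cfg.seed``.

    ``likelihood_weight=0`` with ``fix_tau2`` set is a test hook that turns
    the sweep into draws from the smoothing prior alone.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.shape[0] != blocks.n_obs:
        raise ValueError("outcome length does not match design rows")
    rng = np.random.default_rng(cfg.seed)
    n = blocks.n_obs
    lw = float(likelihood_weight)
    kappa = lw * (y - 0.5)
    a_hyp, b_hyp = float(a), float(b)

    # --- per-block state -------------------------------------------------
    Xf = blocks.fixed.X
    pf = Xf.shape[1]
    beta = _irls_init(Xf, y) if lw > 0 else np.zeros(pf)
    contrib_f = Xf @ beta

    sm_state = []
    for sb in blocks.smooths:
        d = sb.X.shape[1]
        sm_state.append({
            "block": sb, "theta": np.zeros(d), "contrib": np.zeros(n),
            "tau2": fix_tau2 if fix_tau2 is not None else init_variance,
        })
    sp = blocks.spatial
    if sp is not None:
        dsp = sp.Z.shape[1]
        sp_state = {"theta": np.zeros(dsp), "contrib": np.zeros(n),
                    "tau2": fix_tau2 if fix_tau2 is not None else init_variance}
        R = sp.Z.shape[0]
    eta = contrib_f.copy()

    S = cfg.n_retained
    out_beta = np.empty((S, pf))
    out_smooth = {st["block"].name: np.empty((S, st["block"].X.shape[1]))
                  for st in sm_state}
    out_spatial = np.empty((S, sp.Z.shape[1])) if sp is not None else None
    out_tau2 = {name: np.empty(S) for name in
                [st["block"].name for st in sm_state]
                + (["spatial"] if sp is not None else [])}
    out_dev = np.empty(S)
    eta_sum = np.zeros(n)

    def draw_gaussian(P: np.ndarray, b_vec: np.ndarray) -> np.ndarray:
        L = cholesky(P, lower=True)
        m = cho_solve((L, True), b_vec)
        z = rng.standard_normal(P.shape[0])
        return m + solve_triangular(L.T, z, lower=False)

    s_idx = 0
    separation_warned = False
    for it in range(cfg.n_iter):
        if lw > 0:
            omega = lw * random_polyagamma(eta, rng)
        else:
            omega = np.zeros(n)

        # fixed block
        eta_rest = eta - contrib_f
        r = kappa - omega * eta_rest
        A = Xf.T @ (Xf * omega[:, None])
        P = A + _RIDGE * np.eye(pf)
        beta = draw_gaussian(P, Xf.T @ r)
        contrib_f = Xf @ beta
        eta = eta_rest + contrib_f

        # smooth blocks
        for st in sm_state:
            sb = st["block"]
            eta_rest = eta - st["contrib"]
            r = kappa - omega * eta_rest
            A = sb.X.T @ (sb.X * omega[:, None])
            P = A + sb.penalty.matrix / st["tau2"] + _RIDGE * np.eye(A.shape[0])
            st["theta"] = draw_gaussian(P, sb.X.T @ r)
            st["contrib"] = sb.X @ st["theta"]
            eta = eta_rest + st["contrib"]
            if fix_tau2 is None:
                quad = st["theta"] @ sb.penalty.matrix @ st["theta"]
                g = rng.gamma(a_hyp + sb.penalty.rank / 2.0,
                              1.0 / (b_hyp + quad / 2.0))
                st["tau2"] = 1.0 / g

        # spatial block (region-aggregated cross-products)
        if sp is not None:
            eta_rest = eta - sp_state["contrib"]
            r = kappa - omega * eta_rest
            w_reg = np.bincount(sp.region_index, weights=omega, minlength=R)
            r_reg = np.bincount(sp.region_index, weights=r, minlength=R)
            A = sp.Z.T @ (sp.Z * w_reg[:, None])
            K = sp.basis.penalty.matrix
            P = A + K / sp_state["tau2"] + _RIDGE * np.eye(A.shape[0])
            sp_state["theta"] = draw_gaussian(P, sp.Z.T @ r_reg)
            sp_state["contrib"] = (sp.Z @ sp_state["theta"])[sp.region_index]
            eta = eta_rest + sp_state["contrib"]
            if fix_tau2 is None:
                quad = sp_state["theta"] @ K @ sp_state["theta"]
                g = rng.gamma(a_hyp + sp.basis.penalty.rank / 2.0,
                              1.0 / (b_hyp + quad / 2.0))
                sp_state["tau2"] = 1.0 / g

        if (lw > 0 and not separation_warned and it % 500 == 499
                and np.mean(np.abs(eta)) > 25.0):
            warnings.warn(
                "linear predictor is drifting to extreme values; possible "
                "perfect separation", RuntimeWarning)
            separation_warned = True

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            out_beta[s_idx] = beta
            for st in sm_state:
                out_smooth[st["block"].name][s_idx] = st["theta"]
                out_tau2[st["block"].name][s_idx] = st["tau2"]
            if sp is not None:
                out_spatial[s_idx] = sp_state["theta"]
                out_tau2["spatial"][s_idx] = sp_state["tau2"]
            out_dev[s_idx] = _bernoulli_deviance(y, eta)
            eta_sum += eta
            s_idx += 1

    eta_mean = eta_sum / S
    return PosteriorDraws(
        beta=out_beta, beta_names=list(blocks.fixed.names),
        smooth_coefs=out_smooth, spatial_coefs=out_spatial, tau2=out_tau2,
        deviance=out_dev,
        deviance_at_mean=_bernoulli_deviance(y, eta_mean),
        eta_mean=eta_mean, n_obs=n, config=cfg,
    )


def diagnostics(draws: PosteriorDraws, max_lag: int = 50) -> pd.DataFrame:
    """Per-parameter autocorrelations, effective sample size and trace access.

    Returns one row per fixed-effect coefficient and smoothing variance with
    lag-1/5/10 autocorrelation and the effective sample size; chains with
    zero variance are flagged as degenerate instead of reporting an ESS.
    """
    if draws.n_draws < 100:
        raise ValueError("need at least 100 retained draws for diagnostics")
    import arviz as az
    from statsmodels.tsa.stattools import acf

    series: dict[str, np.ndarray] = {
        name: draws.beta[:, j] for j, name in enumerate(draws.beta_names)
    }
    for name, t2 in draws.tau2.items():
        series[f"tau2[{name}]"] = t2
    series["deviance"] = draws.deviance

    rows = []
    nlags = min(max_lag, draws.n_draws - 2)
    for name, x in series.items():
        degenerate = float(np.var(x)) == 0.0
        if degenerate:
            rows.append({"param": name, "acf1": np.nan, "acf5": np.nan,
                         "acf10": np.nan, "ess": np.nan, "degenerate": True})
            continue
        rho = acf(x, nlags=nlags, fft=True)
        ess = float(az.ess(np.asarray(x)[None, :]))
        rows.append({
            "param": name, "acf1": rho[1],
            "acf5": rho[5] if nlags >= 5 else np.nan,
            "acf10": rho[10] if nlags >= 10 else np.nan,
            "ess": ess, "degenerate": False,
        })
    return pd.DataFrame(rows).set_index("param")


# ---------------------------------------------------------------------------
# scikit-learn style front end
# ---------------------------------------------------------------------------

def _default_covariates():
    from .simulate import CATEGORY_FREQS, CONTINUOUS_RANGES
    fixed = {cov: list(levels) for cov, levels in CATEGORY_FREQS.items()}
    smooths = {cov: {} for cov in CONTINUOUS_RANGES}
    return fixed, smooths


class GeoAdditiveLogistic(BaseEstimator):
    """Bayesian geo-additive logistic regression (scikit-learn interface).

    Parameters
    ----------
    form : str
        One of "M0" (fixed effects only), "M1" (+ P-spline smooths),
        "M2" (+ spatial term), "M3" (both).
    fixed : dict | None
        Categorical covariate -> ordered level list, reference level first.
        Defaults to the survey-style covariate set of the synthetic
        generator.
    smooths : dict | None
        Continuous covariate -> optional per-term basis overrides
        (``n_segments``, ``degree``, ``rw_order``).
    spatial : str
        "tensor" (tensor-product spline over centroids, the default) or
        "mrf" (intrinsic autoregression over the k-nearest-neighbour graph).
    n_segments, degree, rw_order
        Basis defaults for the 1-D smooths (20 equal segments, cubic,
        second-order random walk).
    spatial_segments, spatial_degree
        Marginal basis for the tensor spatial smooth (8 segments, cubic).
    knn_k : int
        Neighbour count for the MRF graph.
    a, b : float
        Inverse-gamma hyperparameters of every smoothing variance.
    n_iter, n_burnin, thin : int
        MCMC schedule.
    random_state : int | None
        Seed for the sampler.

    Attributes
    ----------
    draws_ : PosteriorDraws
    blocks_ : DesignBlocks
    dic_ : DICResult
    n_obs_ : int
    """

    def __init__(self, form="M3", fixed=None, smooths=None, spatial="tensor",
                 n_segments=20, degree=3, rw_order=2, spatial_segments=8,
                 spatial_degree=3, knn_k=4, a=0.001, b=0.001,
                 n_iter=4000, n_burnin=1000, thin=1, random_state=None):
        self.form = form
        self.fixed = fixed
        self.smooths = smooths
        self.spatial = spatial
        self.n_segments = n_segments
        self.degree = degree
        self.rw_order = rw_order
        self.spatial_segments = spatial_segments
        self.spatial_degree = spatial_degree
        self.knn_k = knn_k
        self.a = a
        self.b = b
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.thin = thin
        self.random_state = random_state

    def _build_spec(self) -> ModelSpec:
        fixed, smooths = _default_covariates()
        if self.fixed is not None:
            fixed = {k: list(v) for k, v in self.fixed.items()}
        if self.smooths is not None:
            smooths = {k: dict(v) for k, v in self.smooths.items()}
        use_smooths = self.form in ("M1", "M3")
        use_spatial = self.form in ("M2", "M3")
        return ModelSpec(
            form=self.form, fixed=fixed,
            smooths=smooths if use_smooths else {},
            spatial=(self.spatial if use_spatial else None),
            spatial_segments=self.spatial_segments,
            spatial_degree=self.spatial_degree,
            knn_k=self.knn_k, a=self.a, b=self.b,
        )

    def fit(self, X: pd.DataFrame, y=None, *, geography=None,
            adjacency=None):
        """Fit by MCMC.  ``y`` may be an array or the name of a column of X."""
        if isinstance(y, str):
            y_arr = X[y].to_numpy(dtype=float)
        elif y is None:
            raise ValueError("y (array or column name) is required")
        else:
            y_arr = np.asarray(y, dtype=float)
        spec = self._build_spec()
        blocks = assemble_design(
            X, spec, geography=geography, adjacency=adjacency,
            n_segments=self.n_segments, degree=self.degree,
            rw_order=self.rw_order)
        y_used = y_arr[blocks.row_mask]
        cfg = McmcConfig(n_iter=self.n_iter, n_burnin=self.n_burnin,
                         thin=self.thin,
                         seed=0 if self.random_state is None
                         else int(self.random_state))
        self.spec_ = spec
        self.geography_ = geography
        self.blocks_ = blocks
        self.y_ = y_used
        self.draws_ = fit_mcmc(blocks, y_used, cfg, a=self.a, b=self.b)
        from .summaries import dic
        self.dic_ = dic(self.draws_.deviance, self.draws_.deviance_at_mean)
        self.n_obs_ = blocks.n_obs
        return self

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise AttributeError("model is not fitted yet")

    def _eta_new(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        beta_mean = self.draws_.beta.mean(axis=0)
        spec = self.spec_
        cols = [np.ones((len(X), 1))]
        for cov, levels in spec.fixed.items():
            M, _ = _effect_code_column(X[cov], list(levels), list(levels)[0], cov)
            cols.append(M)
        eta = np.hstack(cols) @ beta_mean
        for sb in self.blocks_.smooths:
            theta = self.draws_.smooth_coefs[sb.name].mean(axis=0)
            B = bspline_design(X[sb.name].to_numpy(), sb.kv) - sb.col_means
            eta = eta + B @ theta
        sp = self.blocks_.spatial
        if sp is not None:
            theta = self.draws_.spatial_coefs.mean(axis=0)
            region_eff = sp.Z @ theta
            pos = {rid: i for i, rid in enumerate(sp.basis.region_ids)}
            idx = X["region_id"].map(pos)
            if idx.isna().any():
                raise ValueError("prediction rows reference unknown regions")
            eta = eta + region_eff[idx.to_numpy(dtype=int)]
        return eta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean anaemia probability for new children."""
        eta = self._eta_new(X)
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # convenience wrappers over the summaries module ----------------------
    def fixed_effect_table(self) -> pd.DataFrame:
        self._check_fitted()
        from .summaries import fixed_effect_table
        return fixed_effect_table(self.draws_)

    def smooth_curve(self, name: str, grid=None, n_grid: int = 100
                     ) -> pd.DataFrame:
        self._check_fitted()
        from .summaries import smooth_curve
        return smooth_curve(self.draws_, self.blocks_, name, grid,
                            n_grid=n_grid)

    def classify_spatial(self, levels=(0.80, 0.95)) -> pd.DataFrame:
        self._check_fitted()
        from .summaries import classify_spatial
        return classify_spatial(self.draws_, self.blocks_, levels)


def model_for_form(form: str, **overrides) -> GeoAdditiveLogistic:
    """A `GeoAdditiveLogistic` configured for model form M0-M3."""
    return GeoAdditiveLogistic(form=form, **overrides)
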