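"""Independent oracles used by the test suite.

Everything here is deliberately naive (recursions, nested loops, brute-force
sorts and integrations) and shares no code with the package implementation.
"""

import numpy as np


def cox_de_boor(x: float, knots: np.ndarray, degree: int, i: int) -> float:
    """Cox-de Boor recursion for one B-spline basis function N_{i,degree}."""
    if degree == 0:
        return 1.0 if knots[i] <= x < knots[i + 1] else 0.0
    left = 0.0
    den = knots[i + degree] - knots[i]
    if den > 0:
        left = (x - knots[i]) / den * cox_de_boor(x, knots, degree - 1, i)
    right = 0.0
    den = knots[i + degree + 1] - knots[i + 1]
    if den > 0:
        right = ((knots[i + degree + 1] - x) / den
                 * cox_de_boor(x, knots, degree - 1, i + 1))
    return left + right


def deboor_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    """Full design matrix via the recursion, one basis function at a time."""
    d = len(knots) - degree - 1
    return np.array([[cox_de_boor(xi, knots, degree, i) for i in range(d)]
                     for xi in x])


def brute_force_knn(centroids: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive great-circle pairwise sort, union-symmetrised."""
    n = centroids.shape[0]
    lon = np.radians(centroids[:, 0])
    lat = np.radians(centroids[:, 1])
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        d = []
        for j in range(n):
            if j == i:
                continue
            # haversine
            dlat, dlon = lat[j] - lat[i], lon[j] - lon[i]
            h = (np.sin(dlat / 2) ** 2
                 + np.cos(lat[i]) * np.cos(lat[j]) * np.sin(dlon / 2) ** 2)
            d.append((2 * np.arcsin(np.sqrt(h)), j))
        d.sort()
        for _, j in d[:k]:
            adj[i, j] = 1
    return np.maximum(adj, adj.T)


def grid_posterior_dic(y: np.ndarray, n_grid: int = 20001,
                       lim: float = 8.0) -> tuple[float, float, float]:
    """DIC of an intercept-only Bernoulli-logit model by grid integration.

    Posterior over the logit intercept theta under an (effectively) flat
    prior; returns (dbar, pd, dic).
    """
    theta = np.linspace(-lim, lim, n_grid)
    s, n = y.sum(), y.size
    loglik = s * theta - n * np.logaddexp(0.0, theta)
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    dev = -2.0 * loglik
    dbar = float(w @ dev)
    theta_bar = float(w @ theta)
    d_at_mean = float(-2.0 * (s * theta_bar - n * np.logaddexp(0.0, theta_bar)))
    pd = dbar - d_at_mean
    return dbar, pd, dbar + pd


def sort_quantile(x: np.ndarray, q: float) -> float:
    """Linear interpolation of order statistics (matching numpy's default)."""
    xs = np.sort(np.asarray(x, dtype=float))
    h = (xs.size - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, xs.size - 1)
    return float(xs[lo] + (h - lo) * (xs[hi] - xs[lo]))


def pg_series_sampler(z: float, n: int, rng: np.random.Generator,
                      n_terms: int = 2000) -> np.ndarray:
    """PG(1, z) via its infinite sum-of-exponentials representation,
    truncated at ``n_terms`` (truncation bias is O(1/n_terms))."""
    k = np.arange(1, n_terms + 1)
    denom = (k - 0.5) ** 2 + (z / (2 * np.pi)) ** 2
    out = np.empty(n)
    chunk = 2000
    for i in range(0, n, chunk):
        g = rng.exponential(size=(min(chunk, n - i), n_terms))
        out[i:i + g.shape[0]] = (g / denom).sum(axis=1) / (2 * np.pi**2)
    return out
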