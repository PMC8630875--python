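"""Building blocks for penalized smooth terms.

B-spline bases on equally spaced knots, random-walk difference penalties,
tensor-product bases over region centroids, and Markov-random-field (graph
Laplacian) precision matrices.  Every smooth term in the geo-additive model
is assembled from these primitives.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import BSpline
from scipy.sparse.csgraph import connected_components
from sklearn.metrics.pairwise import haversine_distances

__all__ = [
    "KnotVector",
    "PenaltyMatrix",
    "SpatialBasis",
    "build_knots",
    "bspline_design",
    "difference_penalty",
    "tensor_design",
    "kronecker_sum_penalty",
    "knn_adjacency",
    "mrf_precision",
    "tensor_spatial_basis",
    "mrf_spatial_basis",
]


@dataclasses.dataclass(frozen=True)
class KnotVector:
    """Equally spaced knot grid for a P-spline basis.

    The interior grid has ``n_segments`` equal segments on
    ``[lower, upper]``; the grid is extended by ``degree`` extra knots at the
    same spacing on each side (an open, not clamped, extension), so the basis
    has ``n_segments + degree`` functions and penalized coefficients stay
    exchangeable under a random-walk prior.
    """

    lower: float
    upper: float
    n_segments: int
    degree: int
    knots: np.ndarray

    @property
    def n_basis(self) -> int:
        """Number of basis functions d = s + l."""
        return self.n_segments + self.degree

    @property
    def spacing(self) -> float:
        return (self.upper - self.lower) / self.n_segments

    @property
    def interior_knots(self) -> np.ndarray:
        """The s + 1 knots spanning [lower, upper]."""
        return self.knots[self.degree : self.degree + self.n_segments + 1]


@dataclasses.dataclass(frozen=True)
class PenaltyMatrix:
    """Difference penalty K = D'D of a random-walk prior (or a graph Laplacian).

    ``rank`` is d - order for a walk of the given order; the polynomial null
    space of degree < order is annihilated.  For an MRF Laplacian ``order`` is
    1 and ``rank`` is n minus the number of connected graph components.
    """

    order: int
    matrix: np.ndarray
    rank: int

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def build_knots(
    values: np.ndarray,
    n_segments: int = 20,
    degree: int = 3,
    name: str | None = None,
) -> KnotVector:
    """Equally spaced knots covering the observed range of ``values``.

    Parameters
    ----------
    values
        Observed covariate values; the knot range is [min, max].
    n_segments
        Number of equal interior segments (s).
    degree
        Spline degree (l); the implied basis dimension is d = s + l.
    name
        Covariate name used in error messages.

    Raises
    ------
    ValueError
        If the covariate is degenerate (min == max) or inputs are invalid.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError(f"no values supplied for covariate {name!r}")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    lower, upper = float(np.min(values)), float(np.max(values))
    if not lower < upper:
        raise ValueError(
            f"degenerate covariate {name!r}: min == max == {lower!r}; "
            "cannot place knots"
        )
    h = (upper - lower) / n_segments
    idx = np.arange(-degree, n_segments + degree + 1)
    knots = lower + h * idx
    return KnotVector(lower=lower, upper=upper, n_segments=n_segments,
                      degree=degree, knots=knots)


def bspline_design(x: np.ndarray, kv: KnotVector) -> np.ndarray:
    """Evaluate the B-spline basis at ``x``; rows are a partition of unity.

    ``x`` must lie inside ``[kv.lower, kv.upper]`` (right-closed at the final
    knot); there is no silent extrapolation.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x < kv.lower) or np.any(x > kv.upper):
        bad = x[(x < kv.lower) | (x > kv.upper)]
        raise ValueError(
            f"{bad.size} value(s) outside knot range "
            f"[{kv.lower}, {kv.upper}]: first offending value {bad[0]!r}"
        )
    # BSpline.design_matrix is right-open at the last interior knot; map the
    # covariate maximum into the final interval so the boundary is included.
    xe = np.where(x == kv.upper, np.nextafter(kv.upper, kv.lower), x)
    dm = BSpline.design_matrix(xe, kv.knots, kv.degree, extrapolate=False)
    return dm.toarray()


def difference_penalty(d: int, order: int) -> PenaltyMatrix:
    """Random-walk penalty K = D'D with D the order-th forward difference.

    Only first- and second-order walks are supported (RW1 penalizes deviations
    from a constant, RW2 from a straight line).
    """
    if order not in (1, 2):
        raise ValueError(f"random-walk order must be 1 or 2, got {order}")
    if d <= order:
        raise ValueError(f"basis dimension d={d} must exceed order={order}")
    D = np.diff(np.eye(d), n=order, axis=0)
    return PenaltyMatrix(order=order, matrix=D.T @ D, rank=d - order)


def tensor_design(B1: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product: row r is B1[r] (x) B2[r].

    With partition-of-unity marginals each tensor row again sums to one.
    """
    B1 = np.asarray(B1, dtype=float)
    B2 = np.asarray(B2, dtype=float)
    if B1.shape[0] != B2.shape[0]:
        raise ValueError(
            f"marginal bases must have equal row counts, got "
            f"{B1.shape[0]} and {B2.shape[0]}"
        )
    out = np.einsum("ri,rj->rij", B1, B2)
    return out.reshape(B1.shape[0], B1.shape[1] * B2.shape[1])


def kronecker_sum_penalty(K1: PenaltyMatrix, K2: PenaltyMatrix) -> PenaltyMatrix:
    """Kronecker-sum penalty K1 (x) I + I (x) K2 for a tensor-product smooth.

    Its null space is the tensor of the marginal null spaces; with RW1
    marginals only the constant surface is unpenalized.
    """
    d1, d2 = K1.dim, K2.dim
    M = np.kron(K1.matrix, np.eye(d2)) + np.kron(np.eye(d1), K2.matrix)
    # null(Ksum) = null(K1) (x) null(K2) for nonnegative-definite marginals
    null_dim = (d1 - K1.rank) * (d2 - K2.rank)
    return PenaltyMatrix(order=max(K1.order, K2.order), matrix=M,
                         rank=d1 * d2 - null_dim)


def knn_adjacency(
    centroids: np.ndarray,
    k: int = 4,
    region_ids: list | None = None,
) -> np.ndarray:
    """Symmetrised k-nearest-neighbour adjacency over region centroids.

    Distances are great-circle (haversine) on (longitude, latitude) in decimal
    degrees; each region is linked to its k nearest and the relation is
    symmetrised by union.  Ties in distance are broken by region order.
    """
    centroids = np.asarray(centroids, dtype=float)
    n = centroids.shape[0]
    if region_ids is None:
        region_ids = list(range(n))
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} regions, got {n}")
    # haversine expects (lat, lon) in radians
    latlon = np.radians(centroids[:, ::-1])
    dist = haversine_distances(latlon)
    dup = [
        (region_ids[i], region_ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if dist[i, j] == 0.0 and np.allclose(centroids[i], centroids[j])
    ]
    if dup:
        raise ValueError(f"duplicate centroids for region pairs: {dup}")
    adj = np.zeros((n, n), dtype=int)
    order = np.arange(n)
    for i in range(n):
        # stable tie-break: sort by (distance, region order), skip self
        ranking = np.lexsort((order, dist[i]))
        nearest = [j for j in ranking if j != i][:k]
        adj[i, nearest] = 1
    adj = np.maximum(adj, adj.T)  # symmetrise by union
    return adj


def mrf_precision(adjacency: np.ndarray) -> PenaltyMatrix:
    """Graph Laplacian precision of a Markov-random-field prior.

    Diagonal holds neighbour counts, off-diagonals are -1 for neighbours; row
    sums are zero and the rank is n minus the number of connected components.
    """
    A = np.asarray(adjacency)
    if A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    A = (A > 0).astype(float)
    L = np.diag(A.sum(axis=1)) - A
    n_comp, _ = connected_components(A, directed=False)
    return PenaltyMatrix(order=1, matrix=L, rank=A.shape[0] - n_comp)


@dataclasses.dataclass(frozen=True)
class SpatialBasis:
    """Region-level spatial design and penalty.

    In ``tensor`` mode the design row for region i is the row-wise Kronecker
    product of two marginal B-spline bases evaluated at the centroid
    (longitude, latitude), penalized by the Kronecker sum of the marginal
    random-walk penalties.  In ``mrf`` mode the design is the identity over
    regions and the penalty is the neighbourhood-graph Laplacian.
    """

    region_ids: list
    centroids: np.ndarray
    design: np.ndarray
    penalty: PenaltyMatrix
    mode: str
    marginal_knots: tuple[KnotVector, KnotVector] | None = None


def tensor_spatial_basis(
    centroids: np.ndarray,
    region_ids: list,
    n_segments: int = 8,
    degree: int = 3,
    rw_order: int = 1,
) -> SpatialBasis:
    """Tensor-product spline basis over centroid coordinates."""
    centroids = np.asarray(centroids, dtype=float)
    kv1 = build_knots(centroids[:, 0], n_segments, degree, name="longitude")
    kv2 = build_knots(centroids[:, 1], n_segments, degree, name="latitude")
    B1 = bspline_design(centroids[:, 0], kv1)
    B2 = bspline_design(centroids[:, 1], kv2)
    design = tensor_design(B1, B2)
    K1 = difference_penalty(kv1.n_basis, rw_order)
    K2 = difference_penalty(kv2.n_basis, rw_order)
    return SpatialBasis(
        region_ids=list(region_ids), centroids=centroids, design=design,
        penalty=kronecker_sum_penalty(K1, K2), mode="tensor",
        marginal_knots=(kv1, kv2),
    )


def mrf_spatial_basis(
    centroids: np.ndarray,
    region_ids: list,
    adjacency: np.ndarray | None = None,
    k: int = 4,
) -> SpatialBasis:
    """MRF (intrinsic autoregressive) basis: identity design, Laplacian penalty.

    If no adjacency is supplied the k-nearest-neighbour graph over the
    centroids is used (k = 4 by default).
    """
    centroids = np.asarray(centroids, dtype=float)
    if adjacency is None:
        adjacency = knn_adjacency(centroids, k=k, region_ids=region_ids)
    penalty = mrf_precision(adjacency)
    if penalty.dim != len(region_ids):
        raise ValueError("adjacency size does not match number of regions")
    return SpatialBasis(
        region_ids=list(region_ids), centroids=centroids,
        design=np.eye(len(region_ids)), penalty=penalty, mode="mrf",
    )
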