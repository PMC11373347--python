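"""Weighted correlation-network statistics for model-vs-reference scoring.

The network convention is the unsigned WGCNA one: edge weight between two
variables is the squared Pearson correlation, diagonal excluded.  On top of
that adjacency the module computes the weighted degree, the Zhang-Horvath
weighted clustering coefficient, the topological overlap measure (TOM) and
its dendrogram, plus the scalar comparison metrics (R_mx, R_avg, CR)
summarizing how close a reconstructed or simulated dataset sits to its
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import ks_2samp

from .matrix import ExpressionMatrix, ValidationError

__all__ = [
    "AdjacencyMatrix",
    "ComparisonMetrics",
    "adjacency",
    "weighted_degree",
    "clustering_coefficient",
    "tom",
    "compare_structures",
    "dendrogram",
    "dendrogram_to_nested",
    "topology_ks",
]


@dataclass
class AdjacencyMatrix:
    """Symmetric matrix of squared correlations with zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("adjacency must be symmetric")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ComparisonMetrics:
    """Scalar scores: max/mean cross-r^2 and correlation-matrix RMSE."""

    r_max: float
    r_avg: float
    cr_rmse: float
    v_explained: float | None = None

    def as_dict(self) -> dict:
        d = {"r_max": self.r_max, "r_avg": self.r_avg, "cr_rmse": self.cr_rmse}
        if self.v_explained is not None:
            d["v_explained"] = self.v_explained
        return d


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, (ExpressionMatrix, AdjacencyMatrix)) else np.asarray(X, float)


def adjacency(X, block_size: int = 2048) -> AdjacencyMatrix:
    """Unsigned network adjacency a_ij = cor(X_i, X_j)^2, diagonal zeroed.

    Computed block-wise so the full correlation matrix of ~10^4 variables
    fits comfortably in memory.
    """
    values = _values(X)
    var = values.var(axis=0, ddof=1)
    if (var <= 0).any():
        raise ValidationError(
            f"zero-variance variables at indices {np.flatnonzero(var <= 0).tolist()}"
        )
    n, m = values.shape
    Z = (values - values.mean(axis=0)) / (values.std(axis=0, ddof=1) * np.sqrt(n - 1))
    A = np.empty((m, m))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        A[start:stop] = (Z[:, start:stop].T @ Z) ** 2
    return AdjacencyMatrix(values=A)


def weighted_degree(A: AdjacencyMatrix) -> np.ndarray:
    """Weighted connectivity k_i = sum_{j != i} a_ij."""
    return _values(A).sum(axis=1)


def clustering_coefficient(A: AdjacencyMatrix) -> np.ndarray:
    """Zhang-Horvath weighted clustering coefficient per node.

    cc_i = sum_{j != l, both != i} a_ij a_jl a_li / ((sum_j a_ij)^2 - sum_j a_ij^2),
    zero where the denominator vanishes.  Values lie in [0, 1] for weights
    in [0, 1].
    """
    a = _values(A)
    k = a.sum(axis=1)
    numer = np.einsum("ij,jl,li->i", a, a, a)  # = diag(A^3): ordered (j, l) pairs
    denom = k**2 - (a**2).sum(axis=1)
    cc = np.zeros_like(k)
    ok = denom > 0
    cc[ok] = numer[ok] / denom[ok]
    return np.clip(cc, 0.0, 1.0)


def tom(A: AdjacencyMatrix) -> np.ndarray:
    """Unsigned topological overlap: shared-neighbor weight plus the direct edge.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with unit diagonal.
    """
    a = _values(A)
    k = a.sum(axis=1)
    L = a @ a  # (L)_ij includes no diagonal terms since diag(a) = 0
    numer = L + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    T = numer / denom
    np.fill_diagonal(T, 1.0)
    return T


def compare_structures(X_ref, X_query, v_explained: float | None = None) -> ComparisonMetrics:
    """Score a reconstruction/simulation against its reference dataset.

    ``r_max`` / ``r_avg`` are the maximum and mean of the squared Pearson
    correlation over all reference x query variable pairs: near (1, high)
    for a reconstruction, near the sampling-noise floor ~1/(n-1) for an
    independent simulation.  ``cr_rmse`` is the RMSE between the two
    correlation matrices over unordered off-diagonal pairs — the structural
    fidelity score that should be small for both.
    """
    ref = _values(X_ref)
    qry = _values(X_query)
    if ref.shape[1] != qry.shape[1]:
        raise ValidationError(
            f"variable count mismatch: {ref.shape[1]} vs {qry.shape[1]}"
        )

    def _std(v):
        z = v - v.mean(axis=0)
        s = np.sqrt((z**2).sum(axis=0))
        s[s == 0] = np.inf  # constant column correlates with nothing
        return z / s

    zr, zq = _std(ref), _std(qry)
    if ref.shape[0] == qry.shape[0]:
        cross = zr.T @ zq
        r2 = cross**2
        r_max, r_avg = float(r2.max()), float(r2.mean())
    else:  # cross-correlation undefined across different sample counts
        r_max = r_avg = float("nan")
    cr = np.corrcoef(ref, rowvar=False)
    cq = np.corrcoef(qry, rowvar=False)
    iu = np.triu_indices(ref.shape[1], k=1)
    cr_rmse = float(np.sqrt(np.mean((cr[iu] - cq[iu]) ** 2)))
    return ComparisonMetrics(r_max=r_max, r_avg=r_avg, cr_rmse=cr_rmse, v_explained=v_explained)


def dendrogram(D: np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerative merge tree of a dissimilarity matrix (e.g. 1 - TOM).

    Returns the scipy linkage matrix; :func:`dendrogram_to_nested` exports a
    portable nested representation.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("dissimilarity must be a square matrix")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method=method)


def dendrogram_to_nested(Z: np.ndarray, labels: list[str] | None = None):
    """Convert a linkage matrix to nested [left, right, height] lists."""
    n = Z.shape[0] + 1
    nodes: dict[int, object] = {
        i: (labels[i] if labels else i) for i in range(n)
    }
    for step, (a, b, h, _) in enumerate(Z):
        nodes[n + step] = [nodes[int(a)], nodes[int(b)], float(h)]
    return nodes[n + Z.shape[0] - 1]


def topology_ks(ref_stat: np.ndarray, query_stat: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov distance between topology distributions."""
    return float(ks_2samp(ref_stat, query_stat).statistic)
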