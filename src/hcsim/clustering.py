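"""Variable clustering for the hierarchical decomposition.

Two stages, per the HCR design:

* the *adaptive* stage: Markov clustering (MCL) on the squared Pearson
  correlation between variables, followed by relegation of very small
  clusters to a noise subset ``C0`` (label 0);
* the *separator* stage: complete-linkage agglomeration on the residual
  correlation distance ``1 - cor(E_i, E_j)^2``, cutting at the number of
  sub-clusters that maximizes the normalized entropy of the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix, ValidationError

__all__ = [
    "SimilarityMatrix",
    "Partition",
    "SplitCandidate",
    "correlation_similarity",
    "mcl",
    "designate_noise",
    "normalized_entropy",
    "separator_split",
]


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of squared Pearson correlations, entries in [0, 1]."""

    values: np.ndarray
    diagonal_policy: str = "one"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")
        v = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(v, 1.0 if self.diagonal_policy == "one" else 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Partition:
    """Integer cluster label per variable; label 0 is the noise subset C0."""

    labels: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a 1-d integer array")
        if (self.labels < 0).any():
            raise ValidationError("labels must be non-negative")

    @property
    def n_clusters(self) -> int:
        """Count of proper (non-noise) clusters."""
        return len(set(self.labels[self.labels > 0]))

    @property
    def noise_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def cluster_labels(self) -> list[int]:
        """Sorted proper cluster labels."""
        return sorted(set(self.labels[self.labels > 0]))

    def sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in self.cluster_labels()}


@dataclass
class SplitCandidate:
    """One candidate cut of a cluster into ``n_g`` sub-clusters."""

    n_g: int
    sizes: list[int]
    normalized_entropy: float
    sub_labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def correlation_similarity(
    X: ExpressionMatrix | np.ndarray, diagonal_policy: str = "one"
) -> SimilarityMatrix:
    """Squared Pearson correlation between all variable pairs.

    Raises if any variable has zero sample variance, naming the offenders:
    a constant column has no defined correlation and must be removed (or
    routed to the noise subset) upstream.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    var = values.var(axis=0, ddof=1)
    if (var <= 0).any():
        bad_idx = np.flatnonzero(var <= 0)
        if isinstance(X, ExpressionMatrix):
            names = [X.variable_ids[i] for i in bad_idx]
        else:
            names = [str(i) for i in bad_idx]
        raise ValidationError(f"zero-variance variables: {names}")
    r = np.corrcoef(values, rowvar=False)
    return SimilarityMatrix(values=r * r, diagonal_policy=diagonal_policy)


def mcl(
    S: SimilarityMatrix,
    inflation: float = 2.0,
    max_iter: int = 100,
    prune_threshold: float = 1e-5,
    conv_tol: float = 1e-8,
) -> Partition:
    """Markov clustering of the similarity graph.

    Alternates *expansion* (squaring the column-stochastic transition
    matrix) and *inflation* (elementwise power followed by column
    re-normalization), pruning entries below ``prune_threshold``, until the
    matrix stabilizes.  Self-loops are set to the maximum off-diagonal entry
    of each column before normalization, the usual regularization that keeps
    odd-length cycles from oscillating.

    Clusters are read off the converged matrix: rows whose diagonal entry is
    nonzero are attractors; attractors whose basins overlap form one cluster;
    every remaining node joins the cluster of the lowest-index attractor
    whose basin contains it, and nodes in no basin become singletons.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    A = S.values.copy()
    n = A.shape[0]
    np.fill_diagonal(A, 0.0)
    offmax = A.max(axis=0)
    # isolated columns keep a unit self-loop so the column remains stochastic
    np.fill_diagonal(A, np.where(offmax > 0, offmax, 1.0))
    M = A / A.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        M_new = M @ M
        M_new = np.power(M_new, inflation)
        M_new[M_new < prune_threshold] = 0.0
        colsum = M_new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M_new /= colsum
        delta = np.abs(M_new - M).max()
        M = M_new
        if delta < conv_tol:
            converged = True
            break

    labels = _read_clusters(M, prune_threshold)
    return Partition(labels=labels, converged=converged)


def _read_clusters(M: np.ndarray, tau: float) -> np.ndarray:
    n = M.shape[0]
    B = M > tau
    attractors = np.flatnonzero(np.diag(B))
    if attractors.size == 0:  # pathological: treat every node as its own cluster
        return np.arange(1, n + 1)
    # union attractors whose basins (rows) overlap
    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rows = {int(a): np.flatnonzero(B[a]) for a in attractors}
    owner: dict[int, int] = {}
    for a in attractors:
        for j in rows[int(a)]:
            j = int(j)
            if j in owner:
                ra, rb = find(int(a)), find(owner[j])
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
            else:
                owner[j] = int(a)
    labels = np.zeros(n, dtype=int)
    roots: dict[int, int] = {}
    next_label = 1
    for a in sorted(attractors):
        r = find(int(a))
        if r not in roots:
            roots[r] = next_label
            next_label += 1
    for a in sorted(attractors):
        lab = roots[find(int(a))]
        for j in rows[int(a)]:
            if labels[j] == 0:
                labels[j] = lab
    for j in range(n):
        if labels[j] == 0:
            labels[j] = next_label
            next_label += 1
    return labels


def designate_noise(
    p: Partition, min_size: int = 3, rel_frac: float = 0.0
) -> Partition:
    """Relabel clusters much smaller than the rest as the noise subset C0.

    A cluster is noise when its size falls below
    ``max(min_size, rel_frac * m)`` where ``m`` is the median cluster size
    *experienced by a variable* (the membership-weighted median over
    non-singleton clusters), so a handful of small clusters cannot drag the
    reference size down.  Surviving clusters are renumbered 1..n by
    decreasing size (ties broken by the lowest member index).
    """
    sizes = p.sizes()
    if not sizes:
        raise ValidationError("partition has no proper clusters")
    per_variable = [s for s in sizes.values() if s > 1 for _ in range(s)]
    med = float(np.median(per_variable)) if per_variable else 1.0
    threshold = max(min_size, rel_frac * med)
    keep = {c for c, s in sizes.items() if s >= threshold}
    if not keep:
        raise ValidationError(
            "every cluster fell below the noise threshold; lower min_size/rel_frac"
        )
    order = sorted(
        keep, key=lambda c: (-sizes[c], int(p.members(c).min()))
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    new = np.zeros_like(p.labels)
    for c, lab in relabel.items():
        new[p.labels == c] = lab
    return Partition(labels=new, converged=p.converged)


def normalized_entropy(sizes: list[int] | np.ndarray) -> float:
    """Shannon entropy of the split proportions, normalized by log(n_g).

    Equals 1 exactly when all sub-cluster sizes are equal; penalizes the
    one-big-cluster-plus-crumbs splits agglomerative methods tend to produce.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size < 2:
        raise ValueError("a split needs at least 2 sub-clusters")
    if (sizes <= 0).any():
        raise ValueError("sub-cluster sizes must be positive")
    p = sizes / sizes.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(sizes.size))


def separator_split(
    E: np.ndarray,
    n_range: tuple[int, int] = (2, 7),
    original: np.ndarray | None = None,
) -> Partition:
    """Subdivide one cluster's residuals into sub-clusters.

    Builds a complete-linkage dendrogram on ``d_ij = 1 - cor(E_i, E_j)^2``,
    cuts it at every ``n_g`` in ``n_range``, and keeps the cut with maximal
    normalized entropy (exact ties go to the largest ``n_g``, the finest
    balanced split).  Residual columns
    with vanishing variance are excluded from the distance computation and
    attached afterwards to the sub-cluster of their most-correlated peer in
    ``original`` (the pre-decomposition data), avoiding NaN distances.

    Returns a complete partition of the cluster (labels 1..n_g, no noise
    label).  A cluster smaller than the minimum requested cut comes back as
    the trivial single-cluster partition with ``converged=False`` flagging
    that no split was performed.
    """
    E = np.asarray(E, dtype=float)
    m = E.shape[1]
    lo, hi = int(n_range[0]), int(n_range[1])
    if lo < 2:
        raise ValueError("n_range must start at 2 or more")
    if m < lo:
        return Partition(labels=np.ones(m, dtype=int), converged=False)

    var = E.var(axis=0, ddof=1)
    active = np.flatnonzero(var > 1e-12)
    degenerate = np.flatnonzero(var <= 1e-12)
    if active.size < lo:
        return Partition(labels=np.ones(m, dtype=int), converged=False)

    r = np.corrcoef(E[:, active], rowvar=False)
    d = 1.0 - r * r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)

    hi_eff = min(hi, active.size)
    if np.all(d < 1e-15):
        # all residuals mutually |cor|=1: any cut is degenerate; take the
        # most even split at the smallest n_g, by member order
        labels_active = (np.arange(active.size) * lo // active.size) + 1
    else:
        Z = linkage(squareform(d, checks=False), method="complete")
        best: SplitCandidate | None = None
        for n_g in range(lo, hi_eff + 1):
            cut = fcluster(Z, t=n_g, criterion="maxclust")
            got = len(set(cut))
            if got < 2:
                continue
            sizes = np.bincount(cut)[1:]
            sizes = sizes[sizes > 0]
            h = normalized_entropy(sizes)
            # ties break to the larger n_g: an even 2-cut of 4 equal
            # sub-modules ties the true 4-cut at entropy 1, and only the
            # finer split resolves the structure within the level budget
            if best is None or h > best.normalized_entropy - 1e-12:
                best = SplitCandidate(
                    n_g=got, sizes=sizes.tolist(), normalized_entropy=h,
                    sub_labels=cut,
                )
        if best is None:
            return Partition(labels=np.ones(m, dtype=int), converged=False)
        labels_active = _relabel_contiguous(best.sub_labels)

    labels = np.zeros(m, dtype=int)
    labels[active] = labels_active
    if degenerate.size:
        ref = original if original is not None else E
        for j in degenerate:
            # attach to the sub-cluster of the most-correlated active peer
            x = ref[:, j]
            if x.var(ddof=1) <= 0:
                peer = active[0]
            else:
                cors = np.array(
                    [abs(np.corrcoef(x, ref[:, a])[0, 1]) for a in active]
                )
                cors = np.nan_to_num(cors, nan=-1.0)
                peer = active[int(np.argmax(cors))]
            labels[j] = labels[peer]
    return Partition(labels=labels, converged=True)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K in order of first appearance (deterministic)."""
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out
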