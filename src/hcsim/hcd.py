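"""Hierarchical clustering-based reconstruction (HCR).

Each variable is approximated as a linear combination of the leading
principal components of the clusters it belongs to, across nested levels of
a hierarchical partition: a k-th order reconstruction per cluster, with the
residuals of one level clustered and decomposed at the next.  Because every
level's scores are orthogonal (in sample space) to the residual they leave
behind, variance decomposes exactly per variable:

    Var(X_i) = Var(X_i^R) + Var(E_i^g)

which doubles as the convergence ledger: total explained variance is
V_E = sum_i Var(X_i^R) / sum_i Var(X_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .clustering import (
    Partition,
    correlation_similarity,
    designate_noise,
    mcl,
    separator_split,
)
from .matrix import ExpressionMatrix, ValidationError

__all__ = [
    "ClusterPCA",
    "Level",
    "HCDModel",
    "ClusteringConfig",
    "InsufficientVarianceError",
    "cluster_pca",
    "hcr_fit",
    "fit_decomposition",
    "reconstruct",
    "add_variance_matching_noise",
    "variance_explained",
    "pc_count_summary",
]

SCHEMA_VERSION = 1


class InsufficientVarianceError(ValueError):
    """Raised when the noiseless part of the data cannot supply f_E of V_X."""

    def __init__(self, required: float, available: float):
        self.required = float(required)
        self.available = float(available)
        super().__init__(
            f"target explained variance f_E*V_X = {required:.6g} exceeds the "
            f"variance of the non-noise clusters V = {available:.6g}; lower "
            "f_E or relax the noise designation"
        )


@dataclass
class ClusterPCA:
    """Leading principal components of one cluster at one hierarchy level.

    ``scores`` (n_samples x n_pcs) are the PCs themselves; ``loadings``
    (n_pcs x n_members) map them back onto the member variables, so
    ``scores @ loadings`` is the best rank-``n_pcs`` approximation of the
    centered cluster submatrix.
    """

    cluster_id: int
    level: int
    member_indices: np.ndarray
    n_pcs_used: int
    scores: np.ndarray
    loadings: np.ndarray
    center: np.ndarray
    pc_variances: np.ndarray

    def reconstruction(self) -> np.ndarray:
        return self.center[None, :] + self.scores @ self.loadings


@dataclass
class Level:
    """One hierarchy level: a partition plus the per-cluster decompositions."""

    partition: Partition
    clusters: list[ClusterPCA] = field(default_factory=list)
    v_explained_after: float = 0.0


@dataclass
class HCDModel:
    """The full hierarchical clustering-based decomposition of a dataset."""

    variable_ids: list[str]
    n_samples: int
    k: int
    f_E: float
    levels: list[Level]
    global_center: np.ndarray
    original_variances: np.ndarray
    residual_variances: np.ndarray
    noise_indices: np.ndarray
    schema_version: int = SCHEMA_VERSION

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def validate(self, rtol: float = 1e-8) -> None:
        """Check the nesting and variance-conservation invariants."""
        for lo, hi in zip(self.levels, self.levels[1:]):
            for c in hi.partition.cluster_labels():
                members = hi.partition.members(c)
                parents = set(lo.partition.labels[members])
                if len(parents) != 1:
                    raise ValidationError(
                        f"cluster {c} at a deeper level spans parents {parents}"
                    )
        recon_var = self.original_variances - self.residual_variances
        if (recon_var < -rtol * self.original_variances.max()).any():
            raise ValidationError("negative reconstructed variance in ledger")


@dataclass
class ClusteringConfig:
    """Knobs for the adaptive (MCL + noise rule) and separator stages."""

    inflation: float = 2.0
    max_iter: int = 100
    prune_threshold: float = 1e-5
    conv_tol: float = 1e-8
    noise_min_size: int = 3
    noise_rel_frac: float = 0.0
    n_range: tuple[int, int] = (2, 7)
    # drop similarity edges indistinguishable from the null before MCL:
    # threshold = (1 - edge_alpha) quantile of r^2 under independence,
    # Beta(1/2, (n-2)/2).  None keeps the dense graph.
    edge_alpha: float | None = 1e-3


def cluster_pca(Xc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Leading-``k`` PCA of one cluster submatrix via SVD.

    Returns ``(center, scores, loadings, pc_variances)`` with
    ``n_pcs = min(k, n_members, n_samples - 1)``.  Each PC's sign is fixed
    so that its largest-|loading| coefficient is positive, making the
    decomposition reproducible across linear-algebra backends.
    """
    Xc = np.asarray(Xc, dtype=float)
    n, m = Xc.shape
    if n < 2:
        raise ValidationError("cluster PCA needs at least 2 samples")
    if k < 1:
        raise ValueError("k must be >= 1")
    center = Xc.mean(axis=0)
    Z = Xc - center
    if np.allclose(Z, 0.0, atol=1e-300):
        raise ValidationError("all-constant cluster submatrix")
    n_pcs = min(k, m, n - 1)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    U, s, Vt = U[:, :n_pcs], s[:n_pcs], Vt[:n_pcs]
    scores = U * s
    loadings = Vt
    for p in range(n_pcs):
        j = int(np.argmax(np.abs(loadings[p])))
        if loadings[p, j] < 0:
            loadings[p] *= -1.0
            scores[:, p] *= -1.0
    pc_variances = s**2 / (n - 1)
    return center, scores, loadings, pc_variances


def hcr_fit(
    X: ExpressionMatrix,
    f_E: float = 0.5,
    k: int = 5,
    g_max: int = 3,
    clustering: ClusteringConfig | None = None,
    seed: int = 0,
    initial_partition: Partition | None = None,
    full_explain_tol: float = 1e-6,
    verbose: bool = False,
) -> HCDModel:
    """Fit the hierarchical decomposition.

    Level 1 comes from the adaptive stage (MCL on squared correlation, then
    noise designation) unless ``initial_partition`` supplies a precomputed
    one.  Each subsequent level subdivides every cluster that still has
    unexplained variance, using the separator stage on its residuals, and
    decomposes the residual submatrix with up to ``k`` PCs.  Fitting stops
    once total explained variance reaches ``f_E`` or ``g_max`` levels are
    used.  Clusters whose residual variance fraction drops below
    ``full_explain_tol`` are frozen: carried forward intact, neither re-fit
    nor subdivided.
    """
    if not 0 < f_E <= 1:
        raise ValueError("f_E must lie in (0, 1]")
    if k < 1 or g_max < 1:
        raise ValueError("k and g_max must be >= 1")
    cfg = clustering or ClusteringConfig()
    values = X.values
    n, N = values.shape
    var0 = values.var(axis=0, ddof=1)
    V_X = float(var0.sum())

    if initial_partition is not None:
        if len(initial_partition.labels) != N:
            raise ValidationError("initial partition length mismatch")
        p1 = initial_partition
    else:
        nz = np.flatnonzero(var0 > 0)
        if nz.size == 0:
            raise ValidationError("all variables are constant")
        S = correlation_similarity(values[:, nz])
        if cfg.edge_alpha is not None:
            from scipy.stats import beta as _beta

            thr = float(_beta.ppf(1.0 - cfg.edge_alpha, 0.5, (n - 2) / 2.0))
            pruned = S.values.copy()
            pruned[pruned < thr] = 0.0
            S = type(S)(values=pruned, diagonal_policy=S.diagonal_policy)
        raw = mcl(
            S,
            inflation=cfg.inflation,
            max_iter=cfg.max_iter,
            prune_threshold=cfg.prune_threshold,
            conv_tol=cfg.conv_tol,
        )
        raw = designate_noise(raw, cfg.noise_min_size, cfg.noise_rel_frac)
        labels = np.zeros(N, dtype=int)
        labels[nz] = raw.labels  # constant columns stay in C0
        p1 = Partition(labels=labels, converged=raw.converged)

    if p1.n_clusters == 0:
        raise ValidationError("initial partition contains no proper clusters")
    noise_idx = p1.noise_indices
    V_proper = float(var0.sum() - var0[noise_idx].sum())
    if f_E * V_X > V_proper + 1e-12:
        raise InsufficientVarianceError(f_E * V_X, V_proper)

    E = values.copy().astype(float)
    E -= E.mean(axis=0)  # residual cascade starts from the centered data
    global_center = values.mean(axis=0)

    levels: list[Level] = []
    partition = p1
    frozen: set[int] = set()
    for level_idx in range(1, g_max + 1):
        clusters: list[ClusterPCA] = []
        for c in partition.cluster_labels():
            if c in frozen:
                continue
            members = partition.members(c)
            sub = E[:, members]
            if sub.var(axis=0, ddof=1).sum() <= full_explain_tol * max(
                var0[members].sum(), 1e-300
            ):
                frozen.add(c)
                continue
            center, scores, loadings, pc_var = cluster_pca(sub, k)
            # at level 1 the center is the (already removed) residual mean ~ 0
            clusters.append(
                ClusterPCA(
                    cluster_id=int(c),
                    level=level_idx,
                    member_indices=members,
                    n_pcs_used=scores.shape[1],
                    scores=scores,
                    loadings=loadings,
                    center=center,
                    pc_variances=pc_var,
                )
            )
            E[:, members] = sub - (center[None, :] + scores @ loadings)
        res_var = E.var(axis=0, ddof=1)
        res_var[noise_idx] = var0[noise_idx]
        v_e = 1.0 - float(res_var.sum()) / V_X if V_X > 0 else 0.0
        levels.append(
            Level(partition=partition, clusters=clusters, v_explained_after=v_e)
        )
        if verbose:
            print(f"[hcr] level {level_idx}: V_E = {v_e:.4f}")
        if v_e >= f_E or level_idx == g_max:
            break
        partition, frozen = _next_partition(
            partition, frozen, E, values, var0, full_explain_tol, cfg.n_range
        )

    res_var = E.var(axis=0, ddof=1)
    res_var[noise_idx] = var0[noise_idx]
    model = HCDModel(
        variable_ids=list(X.variable_ids),
        n_samples=n,
        k=k,
        f_E=f_E,
        levels=levels,
        global_center=global_center,
        original_variances=var0,
        residual_variances=res_var,
        noise_indices=noise_idx,
    )
    model.validate()
    return model


def _next_partition(
    partition: Partition,
    frozen: set[int],
    E: np.ndarray,
    values: np.ndarray,
    var0: np.ndarray,
    tol: float,
    n_range: tuple[int, int],
) -> tuple[Partition, set[int]]:
    """Subdivide every active cluster with unexplained variance left."""
    new_labels = np.zeros_like(partition.labels)
    new_frozen: set[int] = set()
    next_label = 1
    for c in partition.cluster_labels():
        members = partition.members(c)
        residual = E[:, members]
        explained_out = residual.var(axis=0, ddof=1).sum() <= tol * max(
            var0[members].sum(), 1e-300
        )
        if c in frozen or explained_out or members.size < 2:
            new_labels[members] = next_label
            if c in frozen or explained_out:
                new_frozen.add(next_label)
            next_label += 1
            continue
        split = separator_split(residual, n_range, original=values[:, members])
        for sub in split.cluster_labels():
            new_labels[members[split.members(sub)]] = next_label
            next_label += 1
    return Partition(labels=new_labels), new_frozen


def fit_decomposition(
    X: ExpressionMatrix,
    level_partitions: list[Partition],
    k: int,
    full_explain_tol: float = 1e-6,
) -> HCDModel:
    """Fit the decomposition along a user-supplied nested hierarchy.

    ``level_partitions`` give the global labels per level (0 = noise subset,
    which must be identical across levels and is taken from level 1); every
    deeper cluster must nest inside one parent.  This is the workhorse
    behind :func:`hcr_fit` once the partitions are chosen, exposed so a
    known hierarchy (e.g. curated gene modules) can be decomposed directly.
    """
    if not level_partitions:
        raise ValueError("need at least one level partition")
    values = X.values
    n, N = values.shape
    var0 = values.var(axis=0, ddof=1)
    V_X = float(var0.sum())
    noise_idx = level_partitions[0].noise_indices
    global_center = values.mean(axis=0)
    E = values - global_center
    levels: list[Level] = []
    frozen_members: list[np.ndarray] = []
    for level_idx, partition in enumerate(level_partitions, start=1):
        if len(partition.labels) != N:
            raise ValidationError("partition length mismatch")
        clusters = []
        for c in partition.cluster_labels():
            members = partition.members(c)
            sub = E[:, members]
            if sub.var(axis=0, ddof=1).sum() <= full_explain_tol * max(
                var0[members].sum(), 1e-300
            ):
                continue
            center, scores, loadings, pc_var = cluster_pca(sub, k)
            clusters.append(
                ClusterPCA(
                    cluster_id=int(c),
                    level=level_idx,
                    member_indices=members,
                    n_pcs_used=scores.shape[1],
                    scores=scores,
                    loadings=loadings,
                    center=center,
                    pc_variances=pc_var,
                )
            )
            E[:, members] = sub - (center[None, :] + scores @ loadings)
        res_var = E.var(axis=0, ddof=1)
        res_var[noise_idx] = var0[noise_idx]
        v_e = 1.0 - float(res_var.sum()) / V_X if V_X > 0 else 0.0
        levels.append(Level(partition=partition, clusters=clusters, v_explained_after=v_e))
    res_var = E.var(axis=0, ddof=1)
    res_var[noise_idx] = var0[noise_idx]
    model = HCDModel(
        variable_ids=list(X.variable_ids),
        n_samples=n,
        k=k,
        f_E=1.0,
        levels=levels,
        global_center=global_center,
        original_variances=var0,
        residual_variances=res_var,
        noise_indices=noise_idx,
    )
    model.validate()
    return model


def reconstruct(model: HCDModel, up_to_level: int | None = None) -> np.ndarray:
    """The k-th order reconstruction X^R = sum of per-level PC contributions.

    Noise-subset (C0) variables carry no PCs; they are returned as their
    mean (zero signal).  ``up_to_level`` truncates the hierarchy.
    """
    g = model.n_levels if up_to_level is None else int(up_to_level)
    if not 1 <= g <= model.n_levels:
        raise ValueError(
            f"up_to_level must be in [1, {model.n_levels}], got {up_to_level}"
        )
    out = np.tile(model.global_center, (model.n_samples, 1))
    for level in model.levels[:g]:
        for cp in level.clusters:
            out[:, cp.member_indices] += cp.center[None, :] + cp.scores @ cp.loadings
    return out


def add_variance_matching_noise(
    XR: np.ndarray, model: HCDModel, seed: int = 0
) -> np.ndarray:
    """Add independent Gaussian noise restoring each variable's variance.

    The noise variance for variable i is its residual variance
    Var(E_i^g) = Var(X_i) - Var(X_i^R); C0 variables receive their full
    original variance.  Variables that are fully explained (zero residual)
    are returned unchanged.
    """
    XR = np.asarray(XR, dtype=float)
    v = np.clip(model.residual_variances, 0.0, None).copy()
    v[v < 1e-12] = 0.0
    rng = substream(seed, "variance-matching-noise")
    noise = rng.standard_normal(XR.shape) * np.sqrt(v)[None, :]
    return XR + noise


def variance_explained(model: HCDModel) -> float:
    """Total explained variance V_E = sum Var(X^R_i) / sum Var(X_i)."""
    tot = float(model.original_variances.sum())
    if tot <= 0:
        return 0.0
    return 1.0 - float(model.residual_variances.sum()) / tot


def pc_count_summary(model: HCDModel) -> dict[str, int]:
    """PC accounting: total PCs stored, and the per-variable maximum.

    With k PCs per cluster over g levels, a variable belonging to one
    cluster at each level is a combination of at most g*k PCs; the total is
    the sum of PCs over all (sub)clusters actually decomposed.
    """
    total = sum(cp.n_pcs_used for lv in model.levels for cp in lv.clusters)
    per_var = np.zeros(model.n_variables, dtype=int)
    for lv in model.levels:
        for cp in lv.clusters:
            per_var[cp.member_indices] += cp.n_pcs_used
    return {
        "total_pcs": int(total),
        "max_pcs_per_variable": int(per_var.max(initial=0)),
    }
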