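"""Hierarchical clustering-based simulation (HCS).

A fitted decomposition expresses every variable as a linear combination of
cluster PCs.  HCS draws a *new, independent* set of PCs whose correlation
matrix equals that of the originals, pushes them through the same
coefficients, and finally adds per-variable Gaussian noise restoring each
variable's original variance.  Two variants:

* ``normal`` — HCS(n): synthetic PCs are Gaussian with the original PCs'
  variances;
* ``fitted`` — HCS(f): each PC's marginal follows a metalog fitted to the
  original scores, coupled through a Gaussian copula (correlate first, then
  transform each margin by Phi followed by the metalog quantile).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from scipy.stats import norm

import numpy as np

from ._rng import substream
from .hcd import HCDModel, add_variance_matching_noise
from .metalog import MetalogFit, metalog_fit, metalog_quantile

__all__ = [
    "PCCorrelationModel",
    "SimulationResult",
    "pc_correlation_model",
    "fit_pc_marginals",
    "simulate_pcs",
    "hcs_simulate",
    "simulated_population_covariance",
    "model_fingerprint",
]


@dataclass
class PCCorrelationModel:
    """Correlation structure of all retained PCs, with a PD factorization.

    ``factor`` is lower-triangular with factor @ factor.T equal to the
    (possibly repaired) correlation matrix; ``repair_log`` records the
    eigenvalue floor applied when the raw matrix was not positive definite
    (inevitable when the PC count exceeds n_samples - 1).
    """

    pc_ids: list[tuple[int, int, int]]
    correlation: np.ndarray
    factor: np.ndarray
    pc_sds: np.ndarray
    repair_log: dict = field(default_factory=dict)

    @property
    def n_pcs(self) -> int:
        return len(self.pc_ids)


@dataclass
class SimulationResult:
    values: np.ndarray
    variant: str
    noise_added: bool
    seed: int
    model_fingerprint: str
    variable_ids: list[str] = field(default_factory=list)


def model_fingerprint(model: HCDModel) -> str:
    """Stable checksum of the model's numeric payload."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(model.global_center).tobytes())
    h.update(np.ascontiguousarray(model.residual_variances).tobytes())
    for lv in model.levels:
        for cp in lv.clusters:
            h.update(np.ascontiguousarray(cp.loadings).tobytes())
    return h.hexdigest()[:16]


def pc_correlation_model(model: HCDModel, eig_floor: float = 1e-10) -> PCCorrelationModel:
    """Pearson correlations between all retained PC score vectors.

    Within one cluster at one level the PCs are orthogonal by construction,
    but PCs of different clusters (and of the same cluster across levels)
    may correlate — that is precisely the structure the simulation must
    carry over.  The matrix is repaired to positive definite by flooring
    eigenvalues at ``eig_floor`` and rescaling to unit diagonal, then
    Cholesky-factorized.
    """
    scores, pc_ids, sds = [], [], []
    for lv in model.levels:
        for cp in lv.clusters:
            for p in range(cp.n_pcs_used):
                scores.append(cp.scores[:, p])
                pc_ids.append((cp.level, cp.cluster_id, p))
                sds.append(np.sqrt(cp.pc_variances[p]))
    if not scores:
        raise ValueError("model contains no PCs")
    S = np.column_stack(scores)
    M = S.shape[1]
    repair: dict = {}
    if M > model.n_samples - 1:
        repair["rank_deficient"] = True
    if M == 1:
        R = np.ones((1, 1))
    else:
        R = np.corrcoef(S, rowvar=False)
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() < eig_floor:
        repair["eig_floor"] = eig_floor
        repair["min_eigenvalue_before"] = float(w.min())
        w = np.maximum(w, eig_floor)
        R_rep = (V * w) @ V.T
        d = np.sqrt(np.diag(R_rep))
        R_rep = R_rep / np.outer(d, d)
        np.fill_diagonal(R_rep, 1.0)
    else:
        R_rep = R
    factor = np.linalg.cholesky(R_rep)
    return PCCorrelationModel(
        pc_ids=pc_ids,
        correlation=R_rep,
        factor=factor,
        pc_sds=np.asarray(sds),
        repair_log=repair,
    )


def fit_pc_marginals(
    model: HCDModel, n_terms: int = 5
) -> dict[tuple[int, int, int], MetalogFit]:
    """Metalog fit of every PC's marginal, keyed by (level, cluster, pc)."""
    fits: dict[tuple[int, int, int], MetalogFit] = {}
    for lv in model.levels:
        for cp in lv.clusters:
            for p in range(cp.n_pcs_used):
                try:
                    fits[(cp.level, cp.cluster_id, p)] = metalog_fit(
                        cp.scores[:, p], n_terms=n_terms
                    )
                except ValueError:
                    pass  # too few distinct values: normal fallback downstream
    return fits


def simulate_pcs(
    pcm: PCCorrelationModel,
    variant: str = "normal",
    fits: dict[tuple[int, int, int], MetalogFit] | None = None,
    n: int = 100,
    seed: int = 0,
    normal_fallback: bool = True,
) -> np.ndarray:
    """Draw n rows of synthetic PCs with the reference correlation matrix.

    Standard normals are correlated through the Cholesky factor.  Under
    ``normal`` each column is scaled to the source PC's standard deviation;
    under ``fitted`` each column passes through the standard normal CDF and
    the PC's metalog quantile (Gaussian-copula coupling), so the marginal
    matches the fitted shape while rank correlations are preserved.
    """
    if variant not in ("normal", "fitted"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = substream(seed, "simulate-pcs")
    Z = rng.standard_normal((n, pcm.n_pcs)) @ pcm.factor.T
    if variant == "normal":
        return Z * pcm.pc_sds[None, :]
    out = np.empty_like(Z)
    for j, pc_id in enumerate(pcm.pc_ids):
        fit = None if fits is None else fits.get(pc_id)
        if fit is None or not fit.feasible:
            if not normal_fallback:
                raise ValueError(f"no feasible metalog fit for PC {pc_id}")
            out[:, j] = Z[:, j] * pcm.pc_sds[j]
            continue
        u = np.clip(norm.cdf(Z[:, j]), 1e-12, 1 - 1e-12)
        out[:, j] = metalog_quantile(fit, u)
    return out


def hcs_simulate(
    model: HCDModel,
    variant: str = "normal",
    n: int | None = None,
    seed: int = 0,
    add_noise: bool = True,
    fits: dict[tuple[int, int, int], MetalogFit] | None = None,
    metalog_terms: int = 5,
) -> SimulationResult:
    """Simulate a new dataset from a fitted decomposition.

    Synthetic variables are built with the model's own coefficients,
    X^S_j = center_j + sum_i beta_ji PC^S_i, from synthetic PCs only — no
    original sample enters the draw, so the output is independent of the
    reference data while sharing its correlation structure.  C0 (noise
    subset) variables carry no PCs: they are their mean, plus full-variance
    noise when ``add_noise`` is set.
    """
    if n is None:
        n = model.n_samples
    if n < 2:
        raise ValueError("need at least 2 simulated samples")
    pcm = pc_correlation_model(model)
    if variant == "fitted" and fits is None:
        fits = fit_pc_marginals(model, n_terms=metalog_terms)
    P = simulate_pcs(pcm, variant=variant, fits=fits, n=n, seed=seed)
    col_of = {pc_id: j for j, pc_id in enumerate(pcm.pc_ids)}
    out = np.tile(model.global_center, (n, 1))
    for lv in model.levels:
        for cp in lv.clusters:
            idx = [col_of[(cp.level, cp.cluster_id, p)] for p in range(cp.n_pcs_used)]
            out[:, cp.member_indices] += cp.center[None, :] + P[:, idx] @ cp.loadings
    if add_noise:
        out = add_variance_matching_noise(out, model, seed=seed)
    return SimulationResult(
        values=out,
        variant=variant,
        noise_added=add_noise,
        seed=seed,
        model_fingerprint=model_fingerprint(model),
        variable_ids=list(model.variable_ids),
    )


def simulated_population_covariance(
    model: HCDModel, pcm: PCCorrelationModel | None = None, add_noise: bool = True
) -> np.ndarray:
    """Closed-form covariance of the HCS(n) output.

    With B the (n_pcs x n_variables) coefficient matrix, D the PC standard
    deviations and R the PC correlation matrix, the simulated covariance is
    B.T D R D B, plus the diagonal of residual variances when noise is on.
    Used to verify the sampler against direct matrix algebra.
    """
    if pcm is None:
        pcm = pc_correlation_model(model)
    Nv = model.n_variables
    B = np.zeros((pcm.n_pcs, Nv))
    col_of = {pc_id: j for j, pc_id in enumerate(pcm.pc_ids)}
    for lv in model.levels:
        for cp in lv.clusters:
            for p in range(cp.n_pcs_used):
                B[col_of[(cp.level, cp.cluster_id, p)], cp.member_indices] = cp.loadings[p]
    D = np.diag(pcm.pc_sds)
    cov = B.T @ D @ pcm.correlation @ D @ B
    if add_noise:
        cov = cov + np.diag(np.clip(model.residual_variances, 0.0, None))
    return cov
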