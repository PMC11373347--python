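"""Metalog quantile-parameterized distributions for PC marginals.

The metalog family expresses the quantile function directly as a linear
combination of basis terms in the cumulative probability y:

    M(y) = a1 + a2 L + a3 (y - 1/2) L + a4 (y - 1/2) + a5 (y - 1/2)^2 + ...

with L = ln(y / (1 - y)).  Terms alternate between powers of (y - 1/2) and
the same powers multiplied by L.  The 2-term metalog is exactly the
logistic distribution with location a1 and scale a2.  Coefficients come
from ordinary least squares of empirical quantiles on the basis, which is
what makes the family attractive here: a linear fit that can still capture
skewed, heavy-tailed and multimodal shapes — typical for the principal
components of expression clusters.

Only the unbounded form is implemented; PC scores are unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream

__all__ = [
    "MetalogFit",
    "metalog_basis",
    "metalog_fit",
    "metalog_quantile",
    "metalog_sample",
]

_FEASIBILITY_GRID = np.linspace(0.001, 0.999, 999)


@dataclass
class MetalogFit:
    coefficients: np.ndarray
    n_terms: int
    feasible: bool
    fit_residual: float

    @property
    def a(self) -> np.ndarray:
        return self.coefficients


def metalog_basis(y: np.ndarray, n_terms: int) -> np.ndarray:
    """Design matrix of the first ``n_terms`` metalog basis functions at y."""
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must lie strictly inside (0, 1)")
    if n_terms < 2:
        raise ValueError("metalog needs at least 2 terms")
    L = np.log(y / (1.0 - y))
    c = y - 0.5
    cols = [np.ones_like(y), L]
    if n_terms >= 3:
        cols.append(c * L)
    if n_terms >= 4:
        cols.append(c)
    # higher terms: powers of (y - 1/2), alternating bare and logit-scaled
    power = 2
    j = 5
    while j <= n_terms:
        cols.append(c**power)
        j += 1
        if j <= n_terms:
            cols.append(c**power * L)
            j += 1
        power += 1
    return np.column_stack(cols)


def metalog_fit(samples: np.ndarray, n_terms: int = 5) -> MetalogFit:
    """Fit a metalog to a sample by OLS in quantile space.

    Sorted observations are paired with plotting positions
    y_i = (i - 0.5)/n and regressed on the basis.  Feasibility (a strictly
    increasing quantile function on a 999-point grid) is checked; if the fit
    is infeasible the term count steps down until a feasible fit is found,
    or a 2-term fit flagged infeasible is returned as a last resort.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if np.unique(x).size < max(n_terms + 2, 3):
        raise ValueError(
            f"need at least {n_terms + 2} distinct values to fit {n_terms} terms"
        )
    y = (np.arange(1, n + 1) - 0.5) / n
    for m in range(n_terms, 1, -1):
        B = metalog_basis(y, m)
        coef, *_ = np.linalg.lstsq(B, x, rcond=None)
        resid = float(np.sum((B @ coef - x) ** 2))
        fit = MetalogFit(
            coefficients=coef, n_terms=m, feasible=_is_feasible(coef, m),
            fit_residual=resid,
        )
        if fit.feasible:
            return fit
    return fit  # 2-term fit, flagged infeasible


def _is_feasible(coef: np.ndarray, n_terms: int) -> bool:
    q = metalog_basis(_FEASIBILITY_GRID, n_terms) @ coef
    return bool(np.all(np.diff(q) > 0))


def metalog_quantile(fit: MetalogFit, y: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the closed-form quantile function M(y), 0 < y < 1."""
    arr = np.asarray(y, dtype=float)
    out = metalog_basis(np.atleast_1d(arr), fit.n_terms) @ fit.coefficients
    return float(out[0]) if arr.ndim == 0 else out


def metalog_sample(fit: MetalogFit, n: int, seed: int = 0) -> np.ndarray:
    """Inverse-transform sampling: M(U) for n uniform variates."""
    if not fit.feasible:
        raise ValueError(
            "metalog fit is infeasible (non-monotone quantile); use the "
            "normal fallback for this PC"
        )
    rng = substream(seed, "metalog-sample")
    u = rng.uniform(0.0, 1.0, size=n)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return metalog_basis(u, fit.n_terms) @ fit.coefficients
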