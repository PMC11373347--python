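"""Hierarchically block-correlated expression-like data with known truth.

Every variable in a child block is a mix of its parent-block latent factor,
its child-block latent factor, and idiosyncratic noise:

    X = sqrt(p) * F_parent + sqrt(c) * F_child + sqrt(1 - p - c) * eps

with all factors standardized, so ``p`` and ``c`` are the variance shares
of each layer and ``p + c`` is the variable's signal fraction.  Parent
factors can be mutually correlated; extra pure-noise variables emulate the
C0 subset.  The population correlation matrix is available in closed form,
which makes the generator usable as ground truth for every other module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from ._rng import substream
from .clustering import Partition
from .matrix import ExpressionMatrix

__all__ = [
    "ChildSpec",
    "ParentSpec",
    "BlockSpec",
    "GroundTruth",
    "default_block_spec",
    "generate_hierarchical_blocks",
    "population_correlation",
    "ground_truth_ari",
]


@dataclass
class ChildSpec:
    size: int
    child_factor_variance_share: float


@dataclass
class ParentSpec:
    parent_factor_variance_share: float
    children: list[ChildSpec] = field(default_factory=list)
    size: int = 0  # used only when the parent has no children

    @property
    def n_variables(self) -> int:
        return sum(c.size for c in self.children) if self.children else self.size


@dataclass
class BlockSpec:
    parent_blocks: list[ParentSpec]
    n_noise_variables: int = 0
    n_samples: int = 100
    marginal: str = "normal"
    cross_parent_correlation: float = 0.0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not 0 <= self.cross_parent_correlation < 1:
            raise ValueError("cross_parent_correlation must be in [0, 1)")
        if self.marginal not in ("normal", "lognormal", "mixture"):
            raise ValueError(f"unknown marginal {self.marginal!r}")
        for p in self.parent_blocks:
            ps = p.parent_factor_variance_share
            if not 0 <= ps <= 1:
                raise ValueError("parent share outside [0, 1]")
            for c in p.children:
                if c.size < 1:
                    raise ValueError("child block sizes must be >= 1")
                if not 0 <= c.child_factor_variance_share <= 1:
                    raise ValueError("child share outside [0, 1]")
                if ps + c.child_factor_variance_share > 1 + 1e-12:
                    raise ValueError("parent + child shares exceed 1")
            if not p.children and p.size < 1:
                raise ValueError("childless parent block needs size >= 1")

    @property
    def n_variables(self) -> int:
        return sum(p.n_variables for p in self.parent_blocks) + self.n_noise_variables

    @classmethod
    def from_json(cls, path: str | Path) -> "BlockSpec":
        with open(path) as fh:
            doc = json.load(fh)
        parents = [
            ParentSpec(
                parent_factor_variance_share=p["parent_factor_variance_share"],
                children=[
                    ChildSpec(c["size"], c["child_factor_variance_share"])
                    for c in p.get("children", [])
                ],
                size=p.get("size", 0),
            )
            for p in doc["parent_blocks"]
        ]
        return cls(
            parent_blocks=parents,
            n_noise_variables=doc.get("n_noise_variables", 0),
            n_samples=doc.get("n_samples", 100),
            marginal=doc.get("marginal", "normal"),
            cross_parent_correlation=doc.get("cross_parent_correlation", 0.0),
        )


@dataclass
class GroundTruth:
    level1: Partition
    level2: Partition
    signal_fraction: np.ndarray


def default_block_spec(n_samples: int = 500) -> BlockSpec:
    """The standard two-level test fixture: 3 parents, 11 children, 0.7 signal.

    Three parent modules with {3, 4, 4} child sub-modules of 12 variables
    each (132 signal variables), parent/child variance shares 0.4/0.3, plus
    8 pure-noise variables — mirroring the shape of the worked hierarchy
    (3 first-level and 11 second-level clusters) at a size that keeps every
    test fast.
    """
    def parent(n_children: int) -> ParentSpec:
        return ParentSpec(
            parent_factor_variance_share=0.4,
            children=[ChildSpec(size=12, child_factor_variance_share=0.3)
                      for _ in range(n_children)],
        )

    return BlockSpec(
        parent_blocks=[parent(3), parent(4), parent(4)],
        n_noise_variables=8,
        n_samples=n_samples,
        marginal="normal",
        cross_parent_correlation=0.0,
    )


def _standardize(col: np.ndarray) -> np.ndarray:
    return (col - col.mean()) / col.std(ddof=0)


def generate_hierarchical_blocks(
    spec: BlockSpec, seed: int = 0
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one dataset from the spec; deterministic per seed.

    Latent factors are Gaussian, standardized in-sample so the configured
    variance shares are exact up to the idiosyncratic draw.  Non-normal
    marginals are applied last as a monotone transform per column, which
    perturbs Pearson correlations but preserves rank structure exactly.
    """
    spec.validate()
    rng = substream(seed, "synthdata")
    n = spec.n_samples
    P = len(spec.parent_blocks)

    rho = spec.cross_parent_correlation
    shared = rng.standard_normal(n)
    parent_factors = np.column_stack([
        _standardize(
            np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
        )
        for _ in range(P)
    ])

    cols, l1, l2, sig = [], [], [], []
    child_label = 0
    for p_idx, parent in enumerate(spec.parent_blocks):
        ps = parent.parent_factor_variance_share
        blocks = parent.children or [ChildSpec(parent.size, 0.0)]
        for child in blocks:
            child_label += 1
            cs = child.child_factor_variance_share
            f_child = _standardize(rng.standard_normal(n)) if cs > 0 else np.zeros(n)
            for _ in range(child.size):
                eps = rng.standard_normal(n)
                x = (
                    np.sqrt(ps) * parent_factors[:, p_idx]
                    + np.sqrt(cs) * f_child
                    + np.sqrt(max(1.0 - ps - cs, 0.0)) * eps
                )
                cols.append(x)
                l1.append(p_idx + 1)
                l2.append(child_label)
                sig.append(ps + cs)
    for _ in range(spec.n_noise_variables):
        cols.append(rng.standard_normal(n))
        l1.append(0)
        l2.append(0)
        sig.append(0.0)

    values = np.column_stack(cols)
    values = _apply_marginal(values, spec.marginal)
    X = ExpressionMatrix(values=values)
    truth = GroundTruth(
        level1=Partition(labels=np.array(l1)),
        level2=Partition(labels=np.array(l2)),
        signal_fraction=np.array(sig),
    )
    return X, truth


def _apply_marginal(values: np.ndarray, marginal: str) -> np.ndarray:
    if marginal == "normal":
        return values
    if marginal == "lognormal":
        return np.exp(values)
    # monotone map with a plateau in the middle: bimodal marginal density
    return values + 2.5 * np.tanh(2.5 * values)


def population_correlation(spec: BlockSpec) -> np.ndarray:
    """Closed-form population correlation of the generated (normal) data."""
    spec.validate()
    N = spec.n_variables
    rho = spec.cross_parent_correlation
    parent_of = np.zeros(N, dtype=int)
    child_of = np.zeros(N, dtype=int)
    p_share = np.zeros(N)
    c_share = np.zeros(N)
    i = 0
    child_label = 0
    for p_idx, parent in enumerate(spec.parent_blocks, start=1):
        blocks = parent.children or [ChildSpec(parent.size, 0.0)]
        for child in blocks:
            child_label += 1
            for _ in range(child.size):
                parent_of[i] = p_idx
                child_of[i] = child_label
                p_share[i] = parent.parent_factor_variance_share
                c_share[i] = child.child_factor_variance_share
                i += 1
    same_parent = (parent_of[:, None] == parent_of[None, :]) & (parent_of[:, None] > 0)
    same_child = (child_of[:, None] == child_of[None, :]) & (child_of[:, None] > 0)
    signal = (parent_of[:, None] > 0) & (parent_of[None, :] > 0)
    sp = np.sqrt(np.outer(p_share, p_share))
    sc = np.sqrt(np.outer(c_share, c_share))
    C = np.where(same_parent, sp, np.where(signal, sp * rho, 0.0))
    C = C + np.where(same_child, sc, 0.0)
    np.fill_diagonal(C, 1.0)
    return C


def ground_truth_ari(partition: Partition, truth: Partition) -> float:
    """Adjusted Rand index between a recovered and a planted partition."""
    a, b = partition.labels, truth.labels
    if a.shape != b.shape:
        raise ValueError("partitions cover different variable sets")
    return float(adjusted_rand_score(b, a))
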