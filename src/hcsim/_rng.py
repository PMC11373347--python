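"""Deterministic per-stage random-number substreams.

Every randomized stage of the pipeline draws from a generator derived from
(user seed, stage name), so each stage is independently reproducible and
changing one stage's draws never perturbs another's.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, stage: str) -> int:
    """Derive a 31-bit child seed from a user seed and a stage label."""
    digest = hashlib.sha256(f"{int(seed)}|{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream(seed: int, stage: str) -> np.random.Generator:
    """A Generator seeded deterministically from (seed, stage)."""
    return np.random.default_rng(substream_seed(seed, stage))
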