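"""Seed derivation: one base seed fans out into independent streams."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(base_seed: int, *parts) -> int:
    """Deterministic child seed (< 2**31) from a base seed and labels."""
    h = hashlib.sha256(repr((int(base_seed),) + parts).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2 ** 31)


def spawn(base_seed: int, *parts) -> np.random.Generator:
    return np.random.default_rng(derive_seed(base_seed, *parts))
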