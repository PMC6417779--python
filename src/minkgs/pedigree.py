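"""Pedigree container.

Animals are rows 0..n-1 in birth order; unknown parents are coded -1.
Sex uses 0 = male, 1 = female.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MALE, FEMALE = 0, 1
UNKNOWN = -1


@dataclass
class Pedigree:
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.generation = np.asarray(self.generation, dtype=np.int32)

    @property
    def n(self) -> int:
        return len(self.sire)

    def validate(self) -> None:
        idx = np.arange(self.n)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            known = par >= 0
            if np.any(par[known] >= idx[known]):
                raise ValueError(f"{name} does not precede offspring")
            if np.any(par < UNKNOWN):
                raise ValueError(f"negative {name} code other than -1")
        if np.any(self.sex[self.sire[self.sire >= 0]] != MALE):
            raise ValueError("a recorded sire is not male")
        if np.any(self.sex[self.dam[self.dam >= 0]] != FEMALE):
            raise ValueError("a recorded dam is not female")

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def truncate(self, n: int) -> "Pedigree":
        """First n animals (valid because parents precede offspring)."""
        return Pedigree(self.sire[:n], self.dam[:n], self.sex[:n],
                        self.generation[:n])


def concat(parts: list[Pedigree]) -> Pedigree:
    return Pedigree(np.concatenate([p.sire for p in parts]),
                    np.concatenate([p.dam for p in parts]),
                    np.concatenate([p.sex for p in parts]),
                    np.concatenate([p.generation for p in parts]))
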