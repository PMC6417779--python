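"""Additive trait model on recruited QTL.

Allelic effects are sampled from a gamma distribution (shape 0.40 by
default) with random sign, one draw per allele per QTL, then jointly
rescaled so that the empirical variance of true breeding values in a
calibration population equals the target heritability (phenotypic
variance is fixed at 1, so sigma_a^2 = h2 and sigma_e^2 = 1 - h2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

GAMMA_SHAPE = 0.40
MAX_ALLELES = 4


@dataclass
class TraitModel:
    qtl_loci: np.ndarray        # locus indices into the working map
    effects: np.ndarray         # (n_qtl, MAX_ALLELES), scaled allelic effects
    h2: float
    sigma_p2: float = 1.0

    @property
    def sigma_a2(self) -> float:
        return self.h2 * self.sigma_p2

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h2) * self.sigma_p2

    def tbv(self, haps: np.ndarray) -> np.ndarray:
        """True breeding values: per individual, the sum over QTL of the
        effects of the maternal and paternal alleles."""
        out = np.empty(haps.shape[0])
        _kernels.tbv_kernel(haps, self.qtl_loci, self.effects, out)
        return out

    def phenotypes(self, tbv: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return tbv + rng.normal(0.0, np.sqrt(self.sigma_e2), size=len(tbv))


def sample_raw_effects(n_qtl: int, rng: np.random.Generator,
                       shape: float = GAMMA_SHAPE) -> np.ndarray:
    """Unscaled allelic effects: gamma(shape) magnitude, sign +/- with
    probability 1/2, independently per (QTL, allele)."""
    mag = rng.gamma(shape, 1.0, size=(n_qtl, MAX_ALLELES))
    sign = rng.choice([-1.0, 1.0], size=(n_qtl, MAX_ALLELES))
    return mag * sign


def build_trait(calibration_haps: np.ndarray, qtl_loci: np.ndarray, h2: float,
                rng: np.random.Generator, shape: float = GAMMA_SHAPE,
                raw_effects: np.ndarray | None = None) -> TraitModel:
    """Sample (or reuse) raw allelic effects and calibrate their scale so
    that Var(TBV) over ``calibration_haps`` equals ``h2``.

    Raises if the QTL genotypes carry no variance before scaling.
    """
    qtl_loci = np.asarray(qtl_loci, dtype=np.int64)
    if raw_effects is None:
        raw_effects = sample_raw_effects(len(qtl_loci), rng, shape)
    model = TraitModel(qtl_loci, np.ascontiguousarray(raw_effects, dtype=np.float64), h2)
    v = float(np.var(model.tbv(calibration_haps)))
    if v <= 0.0:
        raise ValueError("zero genetic variance in the calibration population")
    model.effects = model.effects * np.sqrt(h2 / v)
    return model
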