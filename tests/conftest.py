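"""Shared fixtures: micro-scale configurations and simulated populations.

Everything is generated programmatically from fixed seeds; the micro
configuration shrinks every phase of the simulation while keeping its
structure (three phases, two-sex selection, marker/QTL recruitment).
"""

import numpy as np
import pytest

from minkgs.simulate import SimConfig
from minkgs.scenario import branch_recent, simulate_base


def micro_config(**overrides) -> SimConfig:
    base = dict(
        n_hist_generations=40, hist_size=80, bottleneck_generations=10,
        bottleneck_final=40, expand_founders=15, expand_generations=4,
        expand_final=600,
        recent_sires=10, recent_dams=40, recent_generations=10,
        n_chromosomes=3, genome_length_cm=150.0,
        n_markers=300, n_qtl=100, n_marker_candidates=1200,
        n_qtl_candidates=400, h2=0.5, selection_design="phenotypic",
        store_haplotypes_from=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def micro_base():
    cfg = micro_config()
    return simulate_base(cfg, np.random.default_rng(101)), cfg


@pytest.fixture(scope="session")
def micro_recent(micro_base):
    base, cfg = micro_base
    return branch_recent(base, cfg, np.random.default_rng(202)), cfg


@pytest.fixture(scope="session")
def micro_recent_ebv(micro_base):
    base, cfg = micro_base
    import dataclasses
    cfg = dataclasses.replace(cfg, selection_design="ebv")
    return branch_recent(base, cfg, np.random.default_rng(203)), cfg


def random_pedigree(n, n_founders, rng, generations=None):
    """Random two-sex pedigree with parents preceding offspring."""
    from minkgs.pedigree import FEMALE, MALE, Pedigree
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    sex = np.array([MALE, FEMALE] * (n // 2 + 1))[:n]
    rng.shuffle(sex)
    gen = np.zeros(n, dtype=int)
    for i in range(n_founders, n):
        males = np.where(sex[:i] == MALE)[0]
        females = np.where(sex[:i] == FEMALE)[0]
        if len(males) == 0 or len(females) == 0:
            continue
        sire[i] = rng.choice(males)
        dam[i] = rng.choice(females)
        gen[i] = max(gen[sire[i]], gen[dam[i]]) + 1
    return Pedigree(sire, dam, sex, gen)


def gene_drop_a(ped, n_reps, rng):
    """Monte-Carlo A matrix by gene dropping unique founder alleles."""
    n = ped.n
    alleles = np.zeros((n_reps, n, 2), dtype=np.int32)
    counter = 0
    for i in range(n):
        if ped.sire[i] < 0:
            alleles[:, i, 0] = 2 * i
            alleles[:, i, 1] = 2 * i + 1
        else:
            pick_s = rng.integers(0, 2, n_reps)
            pick_d = rng.integers(0, 2, n_reps)
            alleles[:, i, 0] = alleles[np.arange(n_reps), ped.sire[i], pick_s]
            alleles[:, i, 1] = alleles[np.arange(n_reps), ped.dam[i], pick_d]
    # A_ij = 2 * kinship = 0.5 * sum_{a,b} P(allele a of i IBD allele b of j)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            same = (alleles[:, i, :, None] == alleles[:, j, None, :])
            A[i, j] = A[j, i] = 0.5 * same.sum(axis=(1, 2)).mean()
    return A
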