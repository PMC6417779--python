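"""Forward-in-time breeding-population simulator.

Three phases mimic a farmed-mink demography:

1. *Historical*: constant-size random mating (default 1000 generations at
   N = 1000) followed by a linear bottleneck (to N = 100 over 50
   generations) that builds up linkage disequilibrium.
2. *Expansion*: 50 + 50 founders sampled from the last historical
   generation; a constant breeding nucleus (50 dams x 5 kits per
   generation, random mates) runs for 30 generations while offspring
   accumulate; the recent phase recruits from the youngest cohorts.
3. *Recent*: 260 sires x 1250 dams, five kits per dam, ten generations of
   truncation selection on either own phenotype or pedigree-BLUP EBV,
   replacing 50% of dams and 80% of sires each generation.

Founder haplotypes start at allele frequency 1/2 (uniform over alleles at
multi-allelic loci); mutation-drift over the historical phase then shapes
the frequency spectrum.  Marker and QTL loci are recruited from the loci
still segregating at the end of the historical phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import genome as gn
from .genome import GenomeMap, alloc_haplotypes, drop_gametes
from .pedigree import FEMALE, MALE, Pedigree
from .trait import TraitModel

logger = logging.getLogger("minkgs")


@dataclass
class SimConfig:
    """Knobs of the three-phase simulation (defaults are the study design)."""

    # historical phase
    n_hist_generations: int = 1000
    hist_size: int = 1000
    bottleneck_generations: int = 50
    bottleneck_final: int = 100
    # expansion phase
    expand_founders: int = 50          # per sex
    expand_generations: int = 30
    expand_final: int = 3000           # size of the last expanded generation
    # recent phase
    kits_per_dam: int = 5
    poisson_litter: bool = False       # Poisson(kits_per_dam) litters if True
    recent_sires: int = 260
    recent_dams: int = 1250
    recent_generations: int = 10
    dam_replacement: float = 0.50
    sire_replacement: float = 0.80
    selection_design: str = "phenotypic"   # or "ebv"
    # genome / panel
    n_chromosomes: int = 14
    genome_length_cm: float = 1192.0
    n_qtl: int = 5000
    n_markers: int = 10000
    n_marker_candidates: int = 40000
    n_qtl_candidates: int = 10000
    maf_min_qtl: float = 0.01
    maf_min_marker: float = 0.05
    # trait / observation
    h2: float = 0.20
    miss_rate: float = 0.05
    error_rate: float = 0.005
    error_per_genotype: bool = False   # resample the genotype instead of
                                       # flipping single alleles
    mutation_rate: float = 1e-5
    # bookkeeping
    store_haplotypes_from: int = 7     # keep kit haplotypes for gens >= this

    def validate(self) -> None:
        for name in ("dam_replacement", "sire_replacement", "miss_rate",
                     "error_rate", "mutation_rate", "maf_min_qtl",
                     "maf_min_marker"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_hist_generations", "hist_size", "bottleneck_generations",
                     "bottleneck_final", "expand_founders", "expand_generations",
                     "kits_per_dam", "recent_sires", "recent_dams",
                     "recent_generations", "n_chromosomes", "n_qtl", "n_markers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie strictly between 0 and 1")
        if self.selection_design not in ("phenotypic", "ebv"):
            raise ValueError("selection_design must be 'phenotypic' or 'ebv'")



def hist_trajectory(config: SimConfig) -> np.ndarray:
    """Population size per historical generation: constant, then a linear
    decline to the bottleneck size."""
    flat = np.full(config.n_hist_generations, config.hist_size)
    decline = np.linspace(config.hist_size, config.bottleneck_final,
                          config.bottleneck_generations + 1)[1:]
    sizes = np.concatenate([flat, np.round(decline).astype(int)])
    return sizes


@dataclass
class Population:
    """A single cohort: haplotypes aligned with a genome map, plus sex."""

    haps: np.ndarray          # (n, 2, n_loci) int8
    sex: np.ndarray           # int8, 0 = male / 1 = female
    gmap: GenomeMap

    @property
    def n(self) -> int:
        return self.haps.shape[0]

    def allele_freqs(self) -> np.ndarray:
        """Per-locus frequency of each allele code, shape (n_loci, 4)."""
        L = self.gmap.n_loci
        out = np.empty((L, 4))
        flat = self.haps.reshape(-1, L)
        for a in range(4):
            out[:, a] = (flat == a).mean(axis=0)
        return out

    def maf(self) -> np.ndarray:
        """1 - (major allele frequency); reduces to min(p, 1-p) when
        biallelic."""
        return 1.0 - self.allele_freqs().max(axis=1)


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    sex = np.full(n, MALE, dtype=np.int8)
    sex[rng.choice(n, size=n // 2, replace=False)] = FEMALE
    return sex


def _founder_population(gmap: GenomeMap, n: int,
                        rng: np.random.Generator) -> Population:
    """All loci at frequency 1/2 (uniform over alleles if multi-allelic)."""
    L = gmap.n_loci
    haps, _ = alloc_haplotypes(n, L)
    for a_count in np.unique(gmap.n_alleles):
        cols = np.where(gmap.n_alleles == a_count)[0]
        haps[:, :, cols] = rng.integers(0, a_count, size=(n, 2, len(cols)),
                                        dtype=np.int8)
    return Population(haps, _balanced_sexes(n, rng), gmap)


def _random_union(pop: Population, n_off: int, config: SimConfig,
                  rng: np.random.Generator) -> Population:
    """One generation of random union of gametes with two sexes."""
    males = np.where(pop.sex == MALE)[0]
    females = np.where(pop.sex == FEMALE)[0]
    sires = males[rng.integers(0, len(males), size=n_off)]
    dams = females[rng.integers(0, len(females), size=n_off)]
    haps, words = alloc_haplotypes(n_off, pop.gmap.n_loci)
    for slot, par in ((0, sires), (1, dams)):
        drop_gametes(pop.haps, par, pop.gmap, rng, config.mutation_rate,
                     out=haps[:, slot, :],
                     out_words=None if words is None else words[:, slot, :])
    return Population(haps, _balanced_sexes(n_off, rng), pop.gmap)


def run_historical(config: SimConfig, gmap: GenomeMap,
                   rng: np.random.Generator) -> Population:
    """Historical phase; returns the final (bottlenecked) generation."""
    config.validate()
    sizes = hist_trajectory(config)
    pop = _founder_population(gmap, sizes[0], rng)
    for g, n_next in enumerate(sizes):
        pop = _random_union(pop, int(n_next), config, rng)
        if g % 200 == 0 and logger.isEnabledFor(logging.INFO):
            logger.info("historical generation %d: N=%d", g, pop.n)
    return pop


@dataclass
class LociRecruitment:
    """Outcome of marker-panel / QTL recruitment."""

    keep: np.ndarray          # indices into the candidate map, sorted
    gmap: GenomeMap           # restricted map (classes MARKER / QTL)
    marker_idx: np.ndarray    # indices into the restricted map
    qtl_idx: np.ndarray


def recruit_loci(pop: Population, config: SimConfig,
                 rng: np.random.Generator) -> LociRecruitment:
    """Draw the marker panel and QTL set from segregating candidates.

    Markers come from biallelic candidates with MAF >= ``maf_min_marker``;
    QTL from candidates with MAF > ``maf_min_qtl``.  The two sets are
    disjoint by construction (candidate classes are disjoint).
    """
    maf = pop.maf()
    cls = pop.gmap.locus_class
    mk_pool = np.where((cls == gn.CANDIDATE_MARKER)
                       & (maf >= config.maf_min_marker))[0]
    qtl_pool = np.where((cls == gn.CANDIDATE_QTL)
                        & (maf > config.maf_min_qtl))[0]
    if len(mk_pool) < config.n_markers:
        raise ValueError(
            f"only {len(mk_pool)} segregating biallelic candidates for a "
            f"{config.n_markers}-marker panel (short {config.n_markers - len(mk_pool)})")
    if len(qtl_pool) < config.n_qtl:
        raise ValueError(
            f"only {len(qtl_pool)} segregating QTL candidates for "
            f"{config.n_qtl} QTL (short {config.n_qtl - len(qtl_pool)})")
    # QTL first: the trait architecture is then identical across panel sizes
    qtls = rng.choice(qtl_pool, size=config.n_qtl, replace=False)
    markers = rng.choice(mk_pool, size=config.n_markers, replace=False)
    keep = np.sort(np.concatenate([markers, qtls]))
    new_class = np.where(np.isin(keep, markers), gn.MARKER, gn.QTL).astype(np.int8)
    sub = pop.gmap.subset(keep, new_class)
    return LociRecruitment(keep=keep, gmap=sub,
                           marker_idx=np.where(new_class == gn.MARKER)[0],
                           qtl_idx=np.where(new_class == gn.QTL)[0])


def restrict_population(pop: Population, rec: LociRecruitment) -> Population:
    return Population(np.ascontiguousarray(pop.haps[:, :, rec.keep]),
                      pop.sex, rec.gmap)


def run_expansion(pop: Population, config: SimConfig,
                  rng: np.random.Generator,
                  trait: TraitModel | None = None) -> Population:
    """Expansion phase: a constant breeding nucleus whose offspring
    accumulate.

    Each generation, ``expand_founders`` randomly chosen dams of the
    current cohort are each mated to one random sire of the cohort and
    produce ``kits_per_dam`` kits (so the per-generation cohort stays at
    nucleus capacity while the population of non-breeding offspring
    accumulates).  The returned population pools the youngest cohorts up
    to ``expand_final`` animals -- the pool the recent phase recruits its
    founders from.
    """
    males = np.where(pop.sex == MALE)[0]
    females = np.where(pop.sex == FEMALE)[0]
    if len(males) < config.expand_founders or len(females) < config.expand_founders:
        raise ValueError("too few founders per sex for the expansion phase")
    sel = np.concatenate([rng.choice(males, config.expand_founders, replace=False),
                          rng.choice(females, config.expand_founders, replace=False)])
    cur = Population(np.ascontiguousarray(pop.haps[sel]), pop.sex[sel], pop.gmap)
    cohort_size = config.expand_founders * config.kits_per_dam
    n_pool = max(1, -(-config.expand_final // cohort_size))
    cohorts: list[Population] = []
    for g in range(config.expand_generations):
        cur = _nucleus_litter(cur, config, rng)
        cohorts.append(cur)
        cohorts = cohorts[-n_pool:]
        if logger.isEnabledFor(logging.INFO):
            msg = f"expansion generation {g + 1}: cohort {cur.n}"
            if trait is not None:
                msg += f", mean TBV={trait.tbv(cur.haps).mean():.4f}"
            logger.info(msg)
    haps = np.ascontiguousarray(np.concatenate([c.haps for c in cohorts]))
    sex = np.concatenate([c.sex for c in cohorts])
    return Population(haps, sex, pop.gmap)


def _nucleus_litter(pop: Population, config: SimConfig,
                    rng: np.random.Generator) -> Population:
    """One nucleus generation: ``expand_founders`` random dams, one random
    sire each, litters of ``kits_per_dam``."""
    males = np.where(pop.sex == MALE)[0]
    females = np.where(pop.sex == FEMALE)[0]
    if len(males) == 0 or len(females) == 0:
        raise ValueError("a sex died out during expansion")
    n_dams = min(len(females), config.expand_founders)
    dams = rng.choice(females, size=n_dams, replace=False)
    litter = (rng.poisson(config.kits_per_dam, size=n_dams)
              if config.poisson_litter
              else np.full(n_dams, config.kits_per_dam))
    dam_of_kit = np.repeat(dams, litter)
    sire_of_dam = males[rng.integers(0, len(males), size=n_dams)]
    sire_of_kit = np.repeat(sire_of_dam, litter)
    n_off = len(dam_of_kit)
    haps, words = alloc_haplotypes(n_off, pop.gmap.n_loci)
    for slot, par in ((0, sire_of_kit), (1, dam_of_kit)):
        drop_gametes(pop.haps, par, pop.gmap, rng, config.mutation_rate,
                     out=haps[:, slot, :],
                     out_words=None if words is None else words[:, slot, :])
    sex = rng.integers(0, 2, size=n_off).astype(np.int8)
    return Population(haps, sex, pop.gmap)


@dataclass
class RecentResult:
    """Recent-phase output: pedigree-indexed records plus stored haplotypes.

    Row ``i`` of every array is pedigree animal ``i`` (founders first, then
    kits in birth order).
    """

    pedigree: Pedigree
    tbv: np.ndarray
    phenotype: np.ndarray
    gmap: GenomeMap
    trait: TraitModel
    rows_of_gen: dict[int, np.ndarray]       # generation -> pedigree rows
    haps_of_gen: dict[int, np.ndarray]       # stored generations only

    def haplotypes_for_rows(self, rows: np.ndarray) -> np.ndarray:
        """Gather stored haplotypes for pedigree rows (must lie in stored
        generations)."""
        gen = self.pedigree.generation
        out = np.empty((len(rows), 2, self.gmap.n_loci), dtype=np.int8)
        for g, grows in self.rows_of_gen.items():
            if g not in self.haps_of_gen:
                continue
            base = grows[0]
            sel = np.where((gen[rows] == g))[0]
            if sel.size:
                out[sel] = self.haps_of_gen[g][rows[sel] - base]
        missing = ~np.isin(gen[rows], list(self.haps_of_gen))
        if np.any(missing):
            raise ValueError("haplotypes not stored for some requested rows")
        return out


def _rank_desc(values: np.ndarray) -> np.ndarray:
    """Indices sorted by descending value, ties broken by position (id)."""
    order = np.lexsort((np.arange(len(values)), -values))
    return order


def run_recent(pop: Population, config: SimConfig, trait: TraitModel,
               rng: np.random.Generator) -> RecentResult:
    """Recent phase under truncation selection.

    Each generation all dams produce a litter; afterwards
    ``dam_replacement`` of the dams and ``sire_replacement`` of the sires
    are replaced by the top-ranked kits of the current generation, ranked
    on own phenotype or on pedigree-BLUP EBV (refit each generation on all
    phenotypes recorded so far with the true variance ratio).
    """
    males = np.where(pop.sex == MALE)[0]
    females = np.where(pop.sex == FEMALE)[0]
    if len(males) < config.recent_sires or len(females) < config.recent_dams:
        raise ValueError("expanded population too small for the recent phase")
    L = pop.gmap.n_loci
    n_kits = config.recent_dams * config.kits_per_dam
    n_total = config.recent_sires + config.recent_dams \
        + config.recent_generations * n_kits

    sire_arr = np.full(n_total, -1, dtype=np.int64)
    dam_arr = np.full(n_total, -1, dtype=np.int64)
    sex_arr = np.empty(n_total, dtype=np.int8)
    gen_arr = np.zeros(n_total, dtype=np.int32)
    tbv = np.empty(n_total)
    phen = np.empty(n_total)

    # founders: rows 0..recent_sires-1 are sires, then dams
    f_m = rng.choice(males, config.recent_sires, replace=False)
    f_f = rng.choice(females, config.recent_dams, replace=False)
    n_f = config.recent_sires + config.recent_dams
    founder_haps = np.ascontiguousarray(pop.haps[np.concatenate([f_m, f_f])])
    sex_arr[:config.recent_sires] = MALE
    sex_arr[config.recent_sires:n_f] = FEMALE
    tbv[:n_f] = trait.tbv(founder_haps)
    phen[:n_f] = trait.phenotypes(tbv[:n_f], rng)

    # parent pool: pedigree rows + haplotype bank aligned with pool order
    sire_rows = np.arange(config.recent_sires)
    dam_rows = np.arange(config.recent_sires, n_f)
    pool_haps = {int(r): founder_haps[i] for i, r in
                 enumerate(np.concatenate([sire_rows, dam_rows]))}

    rows_of_gen = {0: np.arange(n_f)}
    haps_of_gen: dict[int, np.ndarray] = {}
    if config.store_haplotypes_from <= 0:
        haps_of_gen[0] = founder_haps

    n_keep_dams = config.recent_dams - round(config.dam_replacement * config.recent_dams)
    n_keep_sires = config.recent_sires - round(config.sire_replacement * config.recent_sires)
    next_row = n_f
    ebv = None
    _f_cache = None

    for g in range(1, config.recent_generations + 1):
        # mate: shuffle dams, deal them round-robin over shuffled sires
        dams_shuffled = rng.permutation(dam_rows)
        sires_shuffled = rng.permutation(sire_rows)
        sire_of_dam = np.resize(sires_shuffled, len(dams_shuffled))
        litter = (rng.poisson(config.kits_per_dam, size=len(dams_shuffled))
                  if config.poisson_litter
                  else np.full(len(dams_shuffled), config.kits_per_dam))
        kit_dam = np.repeat(dams_shuffled, litter)
        kit_sire = np.repeat(sire_of_dam, litter)
        n_off = len(kit_dam)
        rows = np.arange(next_row, next_row + n_off)

        parent_rows = np.array(sorted(pool_haps), dtype=np.int64)
        bank = np.stack([pool_haps[int(r)] for r in parent_rows])
        row_to_bank = {int(r): i for i, r in enumerate(parent_rows)}
        kh, kw = alloc_haplotypes(n_off, L)
        for slot, par in ((0, kit_sire), (1, kit_dam)):
            drop_gametes(bank, np.array([row_to_bank[int(r)] for r in par]),
                         pop.gmap, rng, config.mutation_rate,
                         out=kh[:, slot, :],
                         out_words=None if kw is None else kw[:, slot, :])

        sire_arr[rows] = kit_sire
        dam_arr[rows] = kit_dam
        sex_arr[rows] = rng.integers(0, 2, size=n_off).astype(np.int8)
        gen_arr[rows] = g
        tbv[rows] = trait.tbv(kh)
        phen[rows] = trait.phenotypes(tbv[rows], rng)
        rows_of_gen[g] = rows
        if g >= config.store_haplotypes_from:
            haps_of_gen[g] = kh
        next_row += n_off

        if logger.isEnabledFor(logging.INFO):
            logger.info("recent generation %d: %d kits, mean TBV=%.4f",
                        g, n_off, tbv[rows].mean())

        if g == config.recent_generations:
            break

        # replacement: rank on the design criterion
        if config.selection_design == "ebv":
            ebv, _f_cache = _pedigree_ebv(sire_arr[:next_row], dam_arr[:next_row],
                                          sex_arr[:next_row], gen_arr[:next_row],
                                          phen[:next_row], trait.h2,
                                          f_init=_f_cache)
            crit = ebv
        else:
            crit = phen[:next_row]
        kit_m = rows[sex_arr[rows] == MALE]
        kit_f = rows[sex_arr[rows] == FEMALE]
        n_new_dams = config.recent_dams - n_keep_dams
        n_new_sires = config.recent_sires - n_keep_sires
        if len(kit_f) < n_new_dams or len(kit_m) < n_new_sires:
            raise ValueError("not enough kits of the required sex to fill "
                             "the replacement quota")
        keep_d = dam_rows[_rank_desc(crit[dam_rows])][:n_keep_dams]
        keep_s = sire_rows[_rank_desc(crit[sire_rows])][:n_keep_sires]
        new_d = kit_f[_rank_desc(crit[kit_f])][:n_new_dams]
        new_s = kit_m[_rank_desc(crit[kit_m])][:n_new_sires]
        dam_rows = np.sort(np.concatenate([keep_d, new_d]))
        sire_rows = np.sort(np.concatenate([keep_s, new_s]))
        live = set(map(int, np.concatenate([dam_rows, sire_rows])))
        pool_haps = {r: h for r, h in pool_haps.items() if r in live}
        for r in np.concatenate([new_d, new_s]):
            pool_haps[int(r)] = kh[int(r) - rows[0]]

    ped = Pedigree(sire_arr[:next_row], dam_arr[:next_row],
                   sex_arr[:next_row], gen_arr[:next_row])
    return RecentResult(pedigree=ped, tbv=tbv[:next_row], phenotype=phen[:next_row],
                        gmap=pop.gmap, trait=trait, rows_of_gen=rows_of_gen,
                        haps_of_gen=haps_of_gen)


def _pedigree_ebv(sire, dam, sex, generation, phen, h2, f_init=None):
    """Pedigree BLUP on all records to date (true variance components).

    ``f_init`` caches inbreeding coefficients of animals already present
    at the previous refit (they never change as the pedigree grows)."""
    from .models import solve_blup
    from .relationship import a_inverse, inbreeding

    ped = Pedigree(sire, dam, sex, generation)
    F = inbreeding(ped, f_init=f_init)
    ainv = a_inverse(ped, F)
    res = solve_blup(ped.n, np.arange(ped.n), phen, ainv, h2)
    return res.ebv, F


@dataclass
class ObservedGenotypes:
    """Marker dosages with missingness and genotyping error applied.

    ``dosage`` counts copies of allele 1; -1 codes a missing call.
    """

    dosage: np.ndarray            # (n, m) int8
    marker_idx: np.ndarray        # marker columns in the working map

    @property
    def missing(self) -> np.ndarray:
        return self.dosage < 0

    def allele_freqs(self) -> np.ndarray:
        """Observed frequency of allele 1 per marker (non-missing calls)."""
        d = np.ma.masked_less(self.dosage, 0)
        return np.asarray(d.mean(axis=0)) / 2.0


def observe_genotypes(haps: np.ndarray, marker_idx: np.ndarray,
                      miss_rate: float, error_rate: float,
                      rng: np.random.Generator,
                      per_genotype_error: bool = False) -> ObservedGenotypes:
    """Observed marker dosages.

    Each (individual, marker) call is set missing with ``miss_rate``;
    surviving allele calls flip with ``error_rate`` (per allele, so a
    homozygote becomes a heterozygote with probability ~2e).  With
    ``per_genotype_error`` the whole genotype is resampled uniformly from
    {0, 1, 2} instead.
    """
    if not (0.0 <= miss_rate <= 1.0 and 0.0 <= error_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    marker_idx = np.asarray(marker_idx)
    n = haps.shape[0]
    m = len(marker_idx)
    dosage = np.empty((n, m), dtype=np.int8)
    # chunk rows to bound the size of the temporary uniform draws
    step = max(1, int(2e7) // max(m, 1))
    for lo in range(0, n, step):
        hi = min(n, lo + step)
        a0 = haps[lo:hi, 0, marker_idx]
        a1 = haps[lo:hi, 1, marker_idx]
        k = hi - lo
        if error_rate > 0.0:
            if per_genotype_error:
                d = (a0 + a1).astype(np.int8)
                hit = rng.random((k, m)) < error_rate
                d[hit] = rng.integers(0, 3, size=int(hit.sum()), dtype=np.int8)
            else:
                f0 = (rng.random((k, m)) < error_rate).astype(np.int8)
                f1 = (rng.random((k, m)) < error_rate).astype(np.int8)
                d = ((a0 ^ f0) + (a1 ^ f1)).astype(np.int8)
        else:
            d = (a0 + a1).astype(np.int8)
        if miss_rate > 0.0:
            d[rng.random((k, m)) < miss_rate] = -1
        dosage[lo:hi] = d
    return ObservedGenotypes(dosage=dosage, marker_idx=marker_idx)
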