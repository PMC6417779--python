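"""Scenario orchestration: simulate, evaluate, summarise, aggregate.

A *scenario* is one cell of the factorial design
(heritability x marker density x selection design); within a scenario,
training-set sizes and evaluation methods share the same simulated
population, and every replicate re-simulates everything from its own
seeded stream.  Training sets are nested across sizes within a replicate
(the 1000-animal set is a subset of the 2000-animal set, and so on) to
reduce between-size Monte-Carlo noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .genome import MARKER, build_genome_map
from .models import accuracy, bias, solve_blup, solve_gblup, solve_ssgblup
from .popstats import (DiversityStats, LDTable, estimate_ne,
                       genomic_inbreeding_fhom, ld_r2_decay,
                       observed_heterozygosity, pedigree_inbreeding)
from .relationship import (a22, a_inverse, blend_g, h_inverse, inbreeding,
                           invert_g_with_blending, vanraden_g)
from .simulate import (LociRecruitment, Population, RecentResult, SimConfig,
                       observe_genotypes, recruit_loci, restrict_population,
                       run_expansion, run_historical, run_recent)
from .trait import build_trait

logger = logging.getLogger("minkgs")

METHODS = ("blup", "gblup", "ssgblup")
PREDICTION_SET_SIZE = 500
TS_GENERATIONS = (7, 8, 9)
PREDICTION_GENERATION = 10
DIVERSITY_GENERATIONS = (7, 8, 9, 10)
G_BLEND_BETA = 0.05


@dataclass
class ScenarioSpec:
    """One factorial cell plus its replication settings."""

    h2: float = 0.20
    design: str = "phenotypic"
    n_markers: int = 10000
    ts_sizes: tuple[int, ...] = (1000,)
    n_prediction: int = PREDICTION_SET_SIZE
    n_replicates: int = 10
    base_seed: int = 1
    config: SimConfig = field(default_factory=SimConfig)

    def replicate_config(self) -> SimConfig:
        return replace(self.config, h2=self.h2, selection_design=self.design,
                       n_markers=self.n_markers)

    def label(self) -> str:
        """Seed label.  Marker density is deliberately excluded so that
        density cells share simulations (common random numbers): the
        demography, QTL draws and training-set choices are then identical
        across densities and only the panel differs."""
        return f"h2={self.h2}-{self.design}"


@dataclass
class BaseSim:
    """History + expansion shared by the trait/design branches."""

    pop: Population             # last expansion generation, recruited loci only
    recruitment: LociRecruitment


def simulate_base(config: SimConfig, rng: np.random.Generator) -> BaseSim:
    """Historical phase, locus recruitment, expansion phase.

    Each stage consumes its own child stream, so e.g. changing the marker
    density leaves the demography and QTL draws untouched (common random
    numbers across scenario cells).
    """
    r_hist, r_rec, r_exp = rng.spawn(3)
    gmap = build_genome_map(config.n_marker_candidates, config.n_qtl_candidates,
                            r_hist, n_chromosomes=config.n_chromosomes,
                            total_length_cm=config.genome_length_cm)
    hist = run_historical(config, gmap, r_hist)
    rec = recruit_loci(hist, config, r_rec)
    pop = restrict_population(hist, rec)
    expanded = run_expansion(pop, config, r_exp)
    return BaseSim(pop=expanded, recruitment=rec)


def branch_recent(base: BaseSim, config: SimConfig, rng: np.random.Generator,
                  raw_effects: np.ndarray | None = None) -> RecentResult:
    """Build the trait (calibrated on the expansion base) and run the
    recent phase for one (h2, design) branch."""
    r_trait, r_recent = rng.spawn(2)
    trait = build_trait(base.pop.haps, base.recruitment.qtl_idx, config.h2,
                        r_trait, raw_effects=raw_effects)
    return run_recent(base.pop, config, trait, r_recent)


def simulate_population(config: SimConfig, rng: np.random.Generator) -> RecentResult:
    """Full pipeline for a single scenario replicate."""
    base = simulate_base(config, rng)
    return branch_recent(base, config, rng)


@dataclass
class EvaluationSet:
    """Masked prediction animals, nested training sets, observed genotypes."""

    ts_rows: np.ndarray           # nested pool, first k rows = TS of size k
    pred_rows: np.ndarray
    genotyped_rows: np.ndarray    # ts_rows + pred_rows, in that order
    dosage: np.ndarray            # observed dosages for genotyped_rows


def draw_evaluation_set(recent: RecentResult, config: SimConfig,
                        max_ts: int, rng: np.random.Generator,
                        n_pred: int = PREDICTION_SET_SIZE) -> EvaluationSet:
    gen = recent.pedigree.generation
    pool = np.where(np.isin(gen, TS_GENERATIONS))[0]
    if len(pool) < max_ts:
        raise ValueError(f"training pool of {len(pool)} cannot supply {max_ts}")
    g10 = np.where(gen == PREDICTION_GENERATION)[0]
    if len(g10) < n_pred:
        raise ValueError("final generation smaller than the prediction set")
    ts_rows = rng.choice(pool, size=max_ts, replace=False)
    pred_rows = rng.choice(g10, size=n_pred, replace=False)
    rows = np.concatenate([ts_rows, pred_rows])
    haps = recent.haplotypes_for_rows(rows)
    marker_cols = np.where(recent.gmap.locus_class == MARKER)[0]
    obs = observe_genotypes(haps, marker_cols,
                            config.miss_rate, config.error_rate, rng,
                            per_genotype_error=config.error_per_genotype)
    return EvaluationSet(ts_rows=ts_rows, pred_rows=pred_rows,
                         genotyped_rows=rows, dosage=obs.dosage)


def evaluate_replicate(recent: RecentResult, config: SimConfig,
                       eval_set: EvaluationSet,
                       ts_sizes: tuple[int, ...],
                       methods: tuple[str, ...] = METHODS,
                       beta: float = G_BLEND_BETA,
                       plan: list[tuple[str, int]] | None = None) -> pd.DataFrame:
    """Accuracy and bias on the masked prediction set for every requested
    (method, training-set size) cell.

    The genomic methods (GBLUP, ssGBLUP) are fit on the training-set
    phenotypes with the prediction set masked.  The pedigree BLUP
    baseline keeps the prediction animals' own phenotypes in addition to
    the training set: it represents the evaluation a breeder can already
    run without genotyping, which is the baseline genomic prediction
    must beat.
    """
    ped = recent.pedigree
    n = ped.n
    pred = eval_set.pred_rows
    tbv_pred = recent.tbv[pred]
    rows = []
    if plan is None:
        plan = [(m, ts) for ts in ts_sizes for m in methods]
    wanted = {ts: tuple(m for m, t in plan if t == ts)
              for ts in sorted({t for _, t in plan})}
    all_methods = {m for m, _ in plan}

    F = inbreeding(ped)
    if {"blup", "ssgblup"} & all_methods:
        ainv = a_inverse(ped, F)
    if {"gblup", "ssgblup"} & all_methods:
        a22_full = a22(ped, eval_set.genotyped_rows, F)
        # one G over the whole genotyped pool; training-set sub-blocks are
        # exact because allele frequencies come from the pooled set
        G_full = vanraden_g(eval_set.dosage)
    for ts, methods in wanted.items():
        ts_rows = eval_set.ts_rows[:ts]
        y_ts = recent.phenotype[ts_rows]
        if "blup" in methods:
            with_own = np.concatenate([ts_rows, pred])
            res = solve_blup(n, with_own, recent.phenotype[with_own], ainv,
                             config.h2)
            rows.append(dict(method="blup", ts_size=ts,
                             accuracy=accuracy(tbv_pred, res.ebv[pred]),
                             bias=bias(tbv_pred, res.ebv[pred])))
        need_g = {"gblup", "ssgblup"} & set(methods)
        if need_g:
            sel = np.concatenate([np.arange(ts),
                                  np.arange(len(eval_set.ts_rows),
                                            len(eval_set.genotyped_rows))])
            G = G_full[np.ix_(sel, sel)]
            A22_k = a22_full[np.ix_(sel, sel)]
            Gstar = blend_g(G, A22_k, beta)
            record_mask = np.zeros(len(sel), dtype=bool)
            record_mask[:ts] = True
            if "gblup" in methods:
                res = solve_gblup(Gstar, record_mask, y_ts, config.h2)
                pred_ebv = res.ebv[ts:]
                rows.append(dict(method="gblup", ts_size=ts,
                                 accuracy=accuracy(tbv_pred, pred_ebv),
                                 bias=bias(tbv_pred, pred_ebv)))
            if "ssgblup" in methods:
                g_inv = invert_g_with_blending(G, A22_k, beta)
                gidx = eval_set.genotyped_rows[sel]
                order = np.argsort(gidx)
                hinv = h_inverse(ainv, A22_k[np.ix_(order, order)],
                                 g_inv[np.ix_(order, order)], gidx[order])
                res = solve_ssgblup(n, ts_rows, y_ts, hinv, config.h2)
                pred_ebv = res.ebv[pred]
                rows.append(dict(method="ssgblup", ts_size=ts,
                                 accuracy=accuracy(tbv_pred, pred_ebv),
                                 bias=bias(tbv_pred, pred_ebv)))
    return pd.DataFrame(rows)


STATS_MAF_FILTER = 0.05   # panel QC threshold applied before the summaries


def _qc_markers(h: np.ndarray, maf_filter: float) -> np.ndarray:
    """Columns of a 0/1 haplotype matrix passing the sample MAF filter."""
    p = h.mean(axis=0)
    return np.minimum(p, 1.0 - p) >= maf_filter


def diversity_summary(recent: RecentResult, config: SimConfig,
                      rng: np.random.Generator,
                      generations: tuple[int, ...] = DIVERSITY_GENERATIONS,
                      sample_per_gen: int = 1250,
                      maf_filter: float = STATS_MAF_FILTER) -> DiversityStats:
    """Table-1-style statistics over the recent four generations.

    Markers failing a sample MAF filter are excluded first (standard
    panel QC).  Ho and F_HOM are computed on observed genotypes of a
    per-generation random sample; Ne averages the LD-based estimate over
    the same generations; F_PED covers all animals of those generations.
    """
    marker_cols = np.where(recent.gmap.locus_class == MARKER)[0]
    f_ped = pedigree_inbreeding(recent.pedigree, generations)
    hos, fhoms, nes = [], [], []
    for g in generations:
        grows = recent.rows_of_gen[g]
        take = rng.choice(grows, size=min(sample_per_gen, len(grows)),
                          replace=False)
        haps = recent.haplotypes_for_rows(take)
        h = haps.reshape(-1, recent.gmap.n_loci)[:, marker_cols]
        keep = _qc_markers(h, maf_filter)
        cols = marker_cols[keep]
        obs = observe_genotypes(haps, cols, config.miss_rate,
                                config.error_rate, rng,
                                per_genotype_error=config.error_per_genotype)
        hos.append(observed_heterozygosity(obs))
        fhoms.append(genomic_inbreeding_fhom(obs))
        ld = ld_r2_decay(h[:, keep], recent.gmap.locus_chrom[cols],
                         recent.gmap.locus_pos[cols])
        ne, _ = estimate_ne(ld, sample_size=len(take))
        nes.append(ne)
    return DiversityStats(f_ped=f_ped, f_hom=float(np.mean(fhoms)),
                          ho=float(np.mean(hos)), ne_hat=float(np.mean(nes)),
                          scope=tuple(generations))


def ld_summary(recent: RecentResult, rng: np.random.Generator,
               generation: int = PREDICTION_GENERATION,
               sample: int = 1250,
               maf_filter: float = STATS_MAF_FILTER) -> LDTable:
    """Table-2-style LD decay from true haplotypes of the final
    generation, after the same panel QC as the diversity summary."""
    marker_cols = np.where(recent.gmap.locus_class == MARKER)[0]
    grows = recent.rows_of_gen[generation]
    take = rng.choice(grows, size=min(sample, len(grows)), replace=False)
    haps = recent.haplotypes_for_rows(take)
    h = haps.reshape(-1, recent.gmap.n_loci)[:, marker_cols]
    keep = _qc_markers(h, maf_filter)
    cols = marker_cols[keep]
    return ld_r2_decay(h[:, keep], recent.gmap.locus_chrom[cols],
                       recent.gmap.locus_pos[cols])


def run_replicate(spec: ScenarioSpec, replicate: int) -> dict:
    """Simulate and evaluate one replicate of a scenario.

    Returns a dict with the per-cell accuracy/bias frame, diversity
    statistics and the final-generation LD table.
    """
    config = spec.replicate_config()
    seed = derive_seed(spec.base_seed, spec.label(), replicate)
    rng = np.random.default_rng(seed)
    recent = simulate_population(config, rng)
    eval_set = draw_evaluation_set(recent, config, max(spec.ts_sizes), rng,
                                   n_pred=spec.n_prediction)
    cells = evaluate_replicate(recent, config, eval_set, spec.ts_sizes)
    cells["replicate"] = replicate
    div = diversity_summary(recent, config, rng)
    ld = ld_summary(recent, rng)
    return {"cells": cells, "diversity": div, "ld": ld, "seed": seed}


def run_scenario(spec: ScenarioSpec) -> dict:
    reps = [run_replicate(spec, r) for r in range(spec.n_replicates)]
    cells = pd.concat([r["cells"] for r in reps], ignore_index=True)
    return {"cells": cells, "aggregate": aggregate(cells), "replicates": reps}


def aggregate(cells: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of accuracy and bias over replicates per (method, TS)."""
    n_reps = cells["replicate"].nunique() if "replicate" in cells else 1
    if n_reps == 1:
        logger.warning("single replicate: SDs reported as 0")
    g = cells.groupby(["method", "ts_size"], as_index=False).agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_sd=("accuracy", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        bias_mean=("bias", "mean"),
        bias_sd=("bias", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        n=("accuracy", "size"),
    )
    return g


def percent_gain(value: float, reference: float) -> float:
    """Relative gain in percent, e.g. accuracy 0.44 over 0.32 -> +37.5."""
    return 100.0 * (value - reference) / reference


def relative_gain_table(agg: pd.DataFrame) -> pd.DataFrame:
    """Percent accuracy change of GBLUP and ssGBLUP over BLUP, and of
    ssGBLUP over GBLUP, averaged over training-set sizes."""
    means = agg.groupby("method")["accuracy_mean"].mean()
    rows = []
    for a, b in (("gblup", "blup"), ("ssgblup", "blup"), ("ssgblup", "gblup")):
        if a in means and b in means:
            rows.append(dict(comparison=f"{a}_vs_{b}",
                             gain_pct=percent_gain(means[a], means[b])))
    return pd.DataFrame(rows)
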