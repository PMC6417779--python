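"""Simulator phases: drift oracles, recruitment, trait calibration,
selection response, observation model, reproducibility."""

import dataclasses

import numpy as np
import pytest

import minkgs.genome as gn
from conftest import micro_config
from minkgs.genome import build_genome_map
from minkgs.pedigree import FEMALE, MALE
from minkgs.scenario import branch_recent, simulate_base
from minkgs.simulate import (Population, SimConfig, hist_trajectory,
                             observe_genotypes, recruit_loci, run_expansion,
                             run_historical, run_recent, _founder_population,
                             _random_union)
from minkgs.trait import build_trait, sample_raw_effects


class TestHistorical:
    def test_trajectory_is_flat_then_monotone_decline(self):
        cfg = SimConfig()
        sizes = hist_trajectory(cfg)
        assert len(sizes) == 1050
        assert np.all(sizes[:1000] == 1000)
        assert np.all(np.diff(sizes[1000:]) <= 0)
        assert sizes[-1] == 100

    def test_final_population_size_matches_bottleneck(self):
        cfg = micro_config()
        gm = build_genome_map(cfg.n_marker_candidates, cfg.n_qtl_candidates,
                              np.random.default_rng(0),
                              n_chromosomes=cfg.n_chromosomes,
                              total_length_cm=cfg.genome_length_cm)
        pop = run_historical(cfg, gm, np.random.default_rng(1))
        assert pop.n == cfg.bottleneck_final

    def test_heterozygosity_decay_matches_wright_fisher(self):
        # constant N, no mutation: E[2pq at t] = H0 (1 - 1/(2N))^t
        # (expected heterozygosity with the 2n/(2n-1) estimator factor)
        N, t, reps = 40, 15, 8
        gm = build_genome_map(300, 0, np.random.default_rng(2),
                              n_chromosomes=2, total_length_cm=100.0)
        cfg = SimConfig(mutation_rate=0.0)
        het = []
        for r in range(reps):
            rng = np.random.default_rng(50 + r)
            pop = _founder_population(gm, N, rng)
            for _ in range(t):
                pop = _random_union(pop, N, cfg, rng)
            p = pop.haps.reshape(-1, gm.n_loci).mean(axis=0)
            het.append((2 * p * (1 - p)).mean() * 2 * N / (2 * N - 1))
        expected = 0.5 * (1 - 1 / (2 * N)) ** t
        se = np.std(het, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(het) - expected) < 3 * se + 0.005

    def test_allele_frequency_martingale(self):
        # no mutation, no selection: mean frequency change is zero
        N, t = 50, 10
        gm = build_genome_map(500, 0, np.random.default_rng(3),
                              n_chromosomes=2, total_length_cm=100.0)
        cfg = SimConfig(mutation_rate=0.0)
        rng = np.random.default_rng(4)
        pop = _founder_population(gm, N, rng)
        p0 = pop.allele_freqs()[:, 1]
        for _ in range(t):
            pop = _random_union(pop, N, cfg, rng)
        p1 = pop.allele_freqs()[:, 1]
        drift = p1 - p0
        se = drift.std(ddof=1) / np.sqrt(len(drift))
        assert abs(drift.mean()) < 3 * se + 1e-3


class TestRecruitment:
    def _pop(self, seed=5):
        gm = build_genome_map(600, 200, np.random.default_rng(seed),
                              n_chromosomes=2, total_length_cm=100.0)
        rng = np.random.default_rng(seed + 1)
        return _founder_population(gm, 60, rng)

    def test_requested_counts_and_maf_threshold(self):
        pop = self._pop()
        cfg = micro_config(n_markers=200, n_qtl=50)
        rec = recruit_loci(pop, cfg, np.random.default_rng(6))
        assert len(rec.marker_idx) == 200
        assert len(rec.qtl_idx) == 50
        # brute-force MAF check on the recruited panel
        sub = pop.haps[:, :, rec.keep]
        panel = sub[:, :, rec.marker_idx]
        p = (panel == 1).mean(axis=(0, 1))
        assert np.all(np.minimum(p, 1 - p) >= cfg.maf_min_marker)
        assert set(rec.marker_idx) & set(rec.qtl_idx) == set()

    def test_zero_marker_request_is_valid(self):
        pop = self._pop()
        cfg = micro_config(n_markers=1, n_qtl=10)
        cfg = dataclasses.replace(cfg, n_markers=0)
        rec = recruit_loci(pop, cfg, np.random.default_rng(7))
        assert len(rec.marker_idx) == 0

    def test_fixed_panel_raises_with_shortfall(self):
        pop = self._pop()
        pop.haps[:] = 0
        cfg = micro_config(n_markers=10, n_qtl=10)
        with pytest.raises(ValueError, match="short"):
            recruit_loci(pop, cfg, np.random.default_rng(8))


class TestTrait:
    def test_calibration_hits_target_variance_exactly(self):
        pop = TestRecruitment()._pop()
        cfg = micro_config(n_markers=100, n_qtl=80)
        rec = recruit_loci(pop, cfg, np.random.default_rng(9))
        haps = pop.haps[:, :, rec.keep]
        for h2 in (0.1, 0.5):
            trait = build_trait(haps, rec.qtl_idx, h2, np.random.default_rng(10))
            assert np.var(trait.tbv(haps)) == pytest.approx(h2, abs=1e-6)

    def test_gamma_magnitude_mean(self):
        eff = sample_raw_effects(25000, np.random.default_rng(11))
        mean = np.abs(eff).mean()
        se = np.abs(eff).std(ddof=1) / np.sqrt(eff.size)
        assert abs(mean - 0.40) < 3 * se

    def test_tbv_equals_naive_three_qtl_sum(self):
        effects = np.array([[0.5, -0.2, 0.0, 0.0],
                            [1.0, 0.3, 0.0, 0.0],
                            [-0.4, 0.1, 0.0, 0.0]])
        haps = np.array([[[0, 1, 1], [1, 1, 0]],
                         [[1, 0, 0], [0, 0, 1]]], dtype=np.int8)
        from minkgs.trait import TraitModel
        trait = TraitModel(np.arange(3), effects, h2=0.5)
        naive = []
        for i in range(2):
            s = 0.0
            for q in range(3):
                s += effects[q, haps[i, 0, q]] + effects[q, haps[i, 1, q]]
            naive.append(s)
        np.testing.assert_allclose(trait.tbv(haps), naive, atol=1e-12)


class TestExpansion:
    def test_single_generation_litter_arithmetic(self):
        gm = build_genome_map(80, 0, np.random.default_rng(12),
                              n_chromosomes=1, total_length_cm=50.0)
        pop = _founder_population(gm, 120, np.random.default_rng(13))
        cfg = micro_config()
        cfg = dataclasses.replace(cfg, expand_founders=50,
                                  expand_generations=1,
                                  expand_final=50 * cfg.kits_per_dam)
        out = run_expansion(pop, cfg, np.random.default_rng(14))
        assert out.n == 50 * cfg.kits_per_dam

    def test_no_selection_means_no_genetic_trend(self):
        gm = build_genome_map(200, 100, np.random.default_rng(15),
                              n_chromosomes=2, total_length_cm=100.0)
        cfg = micro_config(expand_founders=20, expand_generations=4)
        diffs = []
        for r in range(10):
            rng = np.random.default_rng(60 + r)
            pop = _founder_population(gm, 60, rng)
            rec = recruit_loci(pop, micro_config(n_markers=50, n_qtl=60), rng)
            from minkgs.simulate import restrict_population
            pop = restrict_population(pop, rec)
            trait = build_trait(pop.haps, rec.qtl_idx, 0.5, rng)
            before = trait.tbv(pop.haps).mean()
            out = run_expansion(pop, cfg, rng, trait=trait)
            diffs.append(trait.tbv(out.haps).mean() - before)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 0.01

    def test_too_few_founders_raises(self):
        gm = build_genome_map(40, 0, np.random.default_rng(16),
                              n_chromosomes=1, total_length_cm=50.0)
        pop = _founder_population(gm, 10, np.random.default_rng(17))
        with pytest.raises(ValueError):
            run_expansion(pop, micro_config(expand_founders=30),
                          np.random.default_rng(18))


class TestRecentPhase:
    def test_pedigree_is_valid_dag_with_sexed_parents(self, micro_recent):
        recent, cfg = micro_recent
        recent.pedigree.validate()
        nonf = ~recent.pedigree.is_founder
        assert np.all(recent.pedigree.sire[nonf] >= 0)
        assert np.all(recent.pedigree.dam[nonf] >= 0)

    def test_replacement_counts_match_rates(self, micro_recent):
        recent, cfg = micro_recent
        ped = recent.pedigree
        n_new_dams = round(cfg.dam_replacement * cfg.recent_dams)
        for g in range(3, cfg.recent_generations + 1):
            kits = recent.rows_of_gen[g]
            dams = np.unique(ped.dam[kits])
            assert len(dams) == cfg.recent_dams
            from_prev = (ped.generation[dams] == g - 1).sum()
            assert from_prev == n_new_dams
            sires = np.unique(ped.sire[kits])
            assert (ped.generation[sires] == g - 1).sum() == round(
                cfg.sire_replacement * cfg.recent_sires)

    def test_phenotypic_selection_gives_positive_genetic_trend(self, micro_recent):
        recent, cfg = micro_recent
        assert (recent.tbv[recent.rows_of_gen[10]].mean()
                > recent.tbv[recent.rows_of_gen[1]].mean())

    def test_phenotypic_variance_near_one_in_first_generation(self, micro_recent):
        # at this micro scale only ~50 founders carry the genetic variance,
        # so the realized Var(TBV) is noisy; the band reflects that
        recent, cfg = micro_recent
        assert np.var(recent.phenotype[recent.rows_of_gen[1]]) == \
            pytest.approx(1.0, abs=0.35)

    def test_ebv_design_accumulates_more_inbreeding(self, micro_recent,
                                                    micro_recent_ebv):
        from minkgs.popstats import pedigree_inbreeding
        rp, _ = micro_recent
        re_, _ = micro_recent_ebv
        gens = list(range(5, 11))
        assert pedigree_inbreeding(re_.pedigree, gens) > \
            pedigree_inbreeding(rp.pedigree, gens)

    def test_stored_tbv_matches_recomputation_from_haplotypes(self, micro_recent):
        recent, cfg = micro_recent
        rows = recent.rows_of_gen[9]
        haps = recent.haplotypes_for_rows(rows)
        np.testing.assert_array_equal(recent.trait.tbv(haps),
                                      recent.tbv[rows])

    def test_same_seed_bit_identical(self):
        cfg = micro_config(recent_generations=4, selection_design="ebv")
        def run(seed):
            base = simulate_base(cfg, np.random.default_rng(seed))
            return branch_recent(base, cfg, np.random.default_rng(seed + 1))
        r1, r2 = run(33), run(33)
        np.testing.assert_array_equal(r1.phenotype, r2.phenotype)
        np.testing.assert_array_equal(r1.pedigree.sire, r2.pedigree.sire)
        for g in r1.haps_of_gen:
            np.testing.assert_array_equal(r1.haps_of_gen[g], r2.haps_of_gen[g])


class TestObservation:
    def test_perfect_observation_recovers_truth(self):
        rng = np.random.default_rng(20)
        haps = rng.integers(0, 2, (30, 2, 50)).astype(np.int8)
        obs = observe_genotypes(haps, np.arange(50), 0.0, 0.0, rng)
        np.testing.assert_array_equal(obs.dosage, haps.sum(axis=1))

    def test_total_missingness(self):
        rng = np.random.default_rng(21)
        haps = rng.integers(0, 2, (10, 2, 20)).astype(np.int8)
        obs = observe_genotypes(haps, np.arange(20), 1.0, 0.0, rng)
        assert np.all(obs.dosage == -1)

    def test_rates_within_binomial_error(self):
        rng = np.random.default_rng(22)
        n, m = 400, 2500   # one million cells
        haps = np.zeros((n, 2, m), np.int8)
        obs = observe_genotypes(haps, np.arange(m), 0.05, 0.005, rng)
        frac_missing = obs.missing.mean()
        se = np.sqrt(0.05 * 0.95 / (n * m))
        assert abs(frac_missing - 0.05) < 3 * se
        # all-zero truth: every nonzero non-missing dosage is an error
        err = (obs.dosage > 0).sum() / (~obs.missing).sum()
        # per-allele flips at 0.005 make a genotype wrong w.p. ~2*0.005
        assert abs(err - 2 * 0.005 * 0.995) < 3 * np.sqrt(0.01 / (n * m)) + 5e-4

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            observe_genotypes(np.zeros((2, 2, 3), np.int8), np.arange(3),
                              -0.1, 0.0, np.random.default_rng(0))
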