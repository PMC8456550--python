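import dataclasses

import numpy as np
import pandas as pd
import pytest

from transmut import (
    BulkCounts,
    G_CALL_THRESHOLD,
    SimConfig,
    call_associations,
    haldane_r,
    null_strain_config,
    poisson_dispersion_test,
    simulate_cross_and_bulks,
    simulate_ems_cohort,
    simulate_plate_experiment,
    simulate_reference_panel,
    simulate_coverage_table,
    detect_aneuploidy,
)
from transmut.synthetic_data import _simulate_spores, _order_loci


def _bulk_list(df):
    return [
        BulkCounts(r.variant_id, r.low_ref, r.low_alt, r.high_ref, r.high_alt)
        for r in df.itertuples()
    ]


class TestReproducibility:
    def test_cohort_and_bulks_identical_from_seed(self):
        cfg = SimConfig(seed=11, n_strains=3)
        runs = []
        for _ in range(2):
            rng = cfg.rng()
            cohort = simulate_ems_cohort(cfg, rng)
            bulks = simulate_cross_and_bulks(
                cohort[cohort.strain == "strain000"], cfg, rng
            )
            runs.append((cohort, bulks))
        pd.testing.assert_frame_equal(runs[0][0], runs[1][0])
        pd.testing.assert_frame_equal(runs[0][1], runs[1][1])


class TestCohort:
    def test_pure_poisson_counts_not_overdispersed(self):
        cfg = SimConfig(seed=2, n_strains=1000, count_weights=(1.0, 0.0),
                        count_lambdas=(23.9, 23.9))
        cohort = simulate_ems_cohort(cfg)
        counts = cohort.groupby("strain").size().to_numpy()
        dispersion = counts.var(ddof=1) / counts.mean()
        assert 0.85 < dispersion < 1.15

    def test_default_mixture_is_detectably_overdispersed(self):
        cfg = SimConfig(seed=3, n_strains=200)
        cohort = simulate_ems_cohort(cfg)
        counts = cohort.groupby("strain").size().to_numpy()
        assert poisson_dispersion_test(counts, n_resamples=5000, seed=0) < 0.01

    def test_mean_count_near_study_average(self):
        cfg = SimConfig(seed=4, n_strains=500)
        cohort = simulate_ems_cohort(cfg)
        mean = cohort.groupby("strain").size().mean()
        assert mean == pytest.approx(23.9, abs=1.0)

    def test_spectrum_dominated_by_gc_to_at(self):
        from transmut import Mutation, classify_spectrum

        cfg = SimConfig(seed=5, n_strains=200)
        cohort = simulate_ems_cohort(cfg)
        snvs = cohort[cohort.mtype == "SNV"]
        muts = [Mutation(r.id, r.chrom, r.pos, r.ref, r.alt) for r in snvs.itertuples()]
        counts = classify_spectrum(muts)
        frac = counts["GC_to_AT_transition"] / len(muts)
        assert frac == pytest.approx(0.963, abs=0.02)


class TestCross:
    def test_haldane_limits(self):
        assert haldane_r(0.0) == 0.0
        assert haldane_r(1e9) == pytest.approx(0.5)
        # ~1 cM ~ 1% recombination at short distances
        assert haldane_r(1.0) == pytest.approx(0.0099, abs=1e-3)

    def test_zero_distance_always_coinherited(self, rng):
        loci = _order_loci(
            pd.DataFrame(
                {"id": ["a", "b"], "chrom": ["chrI", "chrI"], "pos": [1000, 1000],
                 "effect_size": [0.0, 0.0]}
            ),
            SimConfig(),
        )
        geno = _simulate_spores(loci, 2000, rng)
        assert (geno[:, 0] == geno[:, 1]).all()

    def test_distant_loci_uncorrelated(self, rng):
        loci = _order_loci(
            pd.DataFrame(
                {"id": ["a", "b"], "chrom": ["chrI", "chrI"], "pos": [1, 10_000_000],
                 "effect_size": [0.0, 0.0]}
            ),
            SimConfig(),
        )
        geno = _simulate_spores(loci, 20_000, rng).astype(float)
        assert abs(np.corrcoef(geno.T)[0, 1]) < 0.05

    def test_neutral_mutation_frequencies_near_half(self):
        cfg = null_strain_config(SimConfig(seed=6, n_strains=1))
        rng = cfg.rng()
        cohort = simulate_ems_cohort(cfg, rng)
        bulks = simulate_cross_and_bulks(cohort, cfg, rng)
        assert np.allclose(bulks.low_freq, 0.5, atol=0.02)
        assert np.allclose(bulks.high_freq, 0.5, atol=0.02)

    def test_causal_effect_separates_bulks(self):
        cfg = SimConfig(seed=7, n_strains=1)
        rng = cfg.rng()
        diffs = []
        for _ in range(20):
            cohort = simulate_ems_cohort(cfg, rng)
            bulks = simulate_cross_and_bulks(cohort, cfg, rng)
            causal = bulks[bulks.is_causal]
            diffs.append(float(np.abs(causal.high_freq - causal.low_freq).iloc[0]))
        assert np.mean(diffs) > 0.5

    def test_population_and_sorted_modes_agree(self):
        cfg = SimConfig(seed=8, n_strains=1, coverage=100)
        cohort = simulate_ems_cohort(cfg, cfg.rng())

        def mean_freqs(mode, n_spores):
            c = dataclasses.replace(cfg, cross_mode=mode, n_spores=n_spores)
            rng = np.random.default_rng(99)
            lows = []
            for _ in range(15):
                b = simulate_cross_and_bulks(cohort, c, rng)
                lows.append(b.low_freq.to_numpy())
            return np.mean(lows, axis=0)

        sorted_f = mean_freqs("sorted", 1000)
        pop_f = mean_freqs("population", 40_000)
        assert np.allclose(sorted_f, pop_f, atol=0.05)

    def test_coverage_table_flags_disome(self):
        cfg = SimConfig(seed=9)
        table = simulate_coverage_table(cfg, aneuploid_chroms=("chrV",))
        assert detect_aneuploidy(table) == ["chrV"]


class TestPlates:
    def test_zero_noise_wells_equal_truth_plus_baseline(self):
        cfg = SimConfig(seed=10, replicate_cv=0.0, position_effect_sd=0.0,
                        row_gradient=0.0, col_gradient=0.0)
        wells, _ = simulate_plate_experiment({"s1": 1.2}, cfg)
        s1 = wells[wells.strain_id == "s1"]
        assert np.allclose(s1["value"], 1.2 + cfg.autofluorescence)
        ctrl = wells[wells.is_control]
        assert np.allclose(ctrl["value"], 1.0 + cfg.autofluorescence)

    def test_panel_between_position_variance_exceeds_within(self):
        cfg = SimConfig(seed=11)
        panel = simulate_reference_panel(cfg)
        assert panel.shape == (146, 4)
        between = panel.mean(axis=1).var(ddof=1)
        within = panel.var(axis=1, ddof=1).mean()
        assert between > within

    def test_plate_layout_counts(self):
        cfg = SimConfig(seed=12)
        wells, _ = simulate_plate_experiment({f"s{i}": 1.0 for i in range(10)}, cfg)
        one_plate = wells[wells.plate_id == wells.plate_id.iloc[0]]
        assert one_plate.is_control.sum() == cfg.n_controls
        assert one_plate.is_autofluorescence.sum() == 1
        assert wells.groupby("strain_id").size()["s3"] == cfg.n_replicates


class TestEndToEnd:
    """Full pipeline on seeded cohorts: simulate -> per-variant G-tests ->
    calls, under the default sorted-bulk conditions."""

    def test_causal_mutation_recovered_and_top_ranked(self):
        cfg = SimConfig(seed=13, n_strains=30)
        rng = cfg.rng()
        cohort = simulate_ems_cohort(cfg, rng)
        called, top = 0, 0
        n = 0
        for _, sub in cohort.groupby("strain"):
            if not sub.is_causal.any():
                continue
            n += 1
            bulks = simulate_cross_and_bulks(sub, cfg, rng)
            calls = call_associations(_bulk_list(bulks)).table
            merged = bulks.merge(calls, on="variant_id")
            causal = merged[merged.is_causal].iloc[0]
            if causal.G > G_CALL_THRESHOLD:
                called += 1
            causal_cm = causal.pos / 1000 * cfg.cm_per_kb
            unlinked = merged[
                (merged.chrom != causal.chrom)
                | (np.abs(merged.pos / 1000 * cfg.cm_per_kb - causal_cm) > 25)
            ]
            if len(unlinked) == 0 or causal.G >= unlinked.G.max():
                top += 1
        assert called / n >= 0.90
        assert top / n >= 0.90

    def test_null_strains_rarely_produce_calls(self):
        cfg = null_strain_config(SimConfig(seed=14, n_strains=200))
        rng = cfg.rng()
        cohort = simulate_ems_cohort(cfg, rng)
        clean = 0
        n_strains = cohort.strain.nunique()
        for _, sub in cohort.groupby("strain"):
            bulks = simulate_cross_and_bulks(sub, cfg, rng)
            calls = call_associations(_bulk_list(bulks)).table
            if not calls.associated.any():
                clean += 1
        assert clean / n_strains >= 0.95
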