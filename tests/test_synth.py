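"""Synthetic cohort generator: phenotypes, manifest, beta matrix, replicate."""

import numpy as np
import pandas as pd
import pytest

from methylsync.qc import filter_probes, personal_dispersion, replicate_error
from methylsync.synth import (
    SimulationConfig,
    calibrate_sigma_tech,
    generate_beta_matrix,
    generate_manifest,
    generate_phenotype_series,
    generate_replicate,
    simulate_dataset,
)


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_probes=10, frac_dmp=0.7, frac_sync=0.4)
        with pytest.raises(ValueError):
            SimulationConfig(n_probes=10, frac_dmp=-0.1)

    def test_timepoints_must_increase(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_probes=10, timepoints=(3.0, 2.0, 5.0))

    def test_extra_pheno_days_interleave_uniquely(self):
        cfg = SimulationConfig(n_probes=10, n_extra_pheno_timepoints=4)
        days = cfg.pheno_days()
        assert len(days) == len(cfg.timepoints) + 4
        assert len(np.unique(days)) == len(days)
        assert set(cfg.timepoints) <= set(days)


class TestPhenotypes:
    def test_glucose_stage_means_recovered_at_large_n(self):
        """Per-stage sample means sit within 3 SE of (4.5, 5.2, 6.0) mmol/L."""
        cfg = SimulationConfig(n_probes=10, n_subjects=1000, seed=4)
        tab = generate_phenotype_series("glucose", cfg)
        bounds = cfg.glucose_stage_boundaries
        stage = np.searchsorted(bounds, tab["day"], side="left")
        for s, (mean, sd) in enumerate(
            zip(cfg.glucose_stage_means, cfg.glucose_stage_sds)
        ):
            vals = tab.loc[stage == s, "glucose"]
            se = sd / np.sqrt(len(vals))
            assert abs(vals.mean() - mean) < 3 * se

    def test_glucose_zero_sd_is_exact_step_function(self):
        cfg = SimulationConfig(n_probes=10, seed=1, glucose_stage_sds=(0.0, 0.0, 0.0))
        tab = generate_phenotype_series("glucose", cfg)
        stage = np.searchsorted(cfg.glucose_stage_boundaries, tab["day"], side="left")
        expected = np.asarray(cfg.glucose_stage_means)[stage]
        assert np.array_equal(tab["glucose"].to_numpy(), expected)

    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig(n_probes=10, seed=7)
        a = generate_phenotype_series("tmd", cfg)
        b = generate_phenotype_series("tmd", SimulationConfig(n_probes=10, seed=7))
        assert a.equals(b)

    def test_units_recorded(self):
        cfg = SimulationConfig(n_probes=10)
        assert generate_phenotype_series("glucose", cfg).attrs["units"]["glucose"] == "mmol/L"

    def test_unknown_kind_names_valid_kinds(self):
        with pytest.raises(ValueError, match="glucose"):
            generate_phenotype_series("cortisol", SimulationConfig(n_probes=10))


class TestManifest:
    def test_category_counts_follow_largest_remainder(self):
        cfg = SimulationConfig(n_probes=1000, seed=2)
        props = {"cgi_relation": {"Island": 0.3, "Shore": 0.3, "Shelf": 0.2, "OpenSea": 0.2}}
        annot = generate_manifest(cfg, props)
        assert (annot["cgi_relation"] == "Island").sum() == 300

    def test_igr_probes_have_no_genes(self):
        annot = generate_manifest(SimulationConfig(n_probes=500, seed=3))
        igr = annot["feature_groups"] == "IGR"
        assert igr.any()
        assert (annot.loc[igr, "genes"] == "").all()
        assert (annot.loc[~igr, "genes"] != "").all()

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            generate_manifest(
                SimulationConfig(n_probes=10),
                {"cgi_relation": {"Island": 0.6, "Shore": 0.2, "Shelf": 0.1, "OpenSea": 0.2}},
            )

    def test_flagged_fractions_drive_filter_exactly(self):
        """Configured flag fractions → the filter removes exactly that set."""
        cfg = SimulationConfig(n_probes=10000, seed=5)
        props = {
            "probe_type": {"cg": 0.98, "ch": 0.0, "rs": 0.02},
            "snp_frac": 0.01,
            "multimap_frac": 0.01,
            "beadfail_frac": 0.005,
        }
        annot = generate_manifest(cfg, props)
        phen = generate_phenotype_series("glucose", cfg)
        beta, _ = generate_beta_matrix(cfg, phen, annot)
        _, report = filter_probes(beta, annot)
        flagged = (
            (annot["beadfail_frac"] >= 0.05)
            | (annot["probe_type"] != "cg")
            | annot["snp_flag"]
            | annot["multimap_flag"]
        )
        assert report.total_removed == int(flagged.sum())
        assert report.retained == 10000 - int(flagged.sum())
        assert report.removed["non_cg"] == 200  # exact rs count by rounding


class TestBetaMatrix:
    def test_noise_free_sync_probe_correlates_perfectly(self):
        cfg = SimulationConfig(
            n_probes=50, frac_dmp=0.0, frac_sync=0.04, effect_sync=0.05,
            sigma_bio=0.0, seed=6,
        )
        annot = generate_manifest(cfg)
        phen = generate_phenotype_series("glucose", cfg)
        beta, truth = generate_beta_matrix(cfg, phen, annot)
        sync = truth.index[truth["class"] == "sync_glucose"]
        assert len(sync) == 2
        for subj in cfg.subjects:
            series = beta.subject_series(subj)
            ph = phen[phen["subject"] == subj].set_index("day").loc[
                list(series.columns), "glucose"
            ]
            for probe in sync:
                r = np.corrcoef(series.loc[probe], ph)[0, 1]
                assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_no_planting_gives_all_null_truth(self):
        cfg = SimulationConfig(n_probes=100, frac_dmp=0.0, frac_sync=0.0, seed=7)
        _, truth = generate_beta_matrix(
            cfg, generate_phenotype_series("glucose", cfg), generate_manifest(cfg)
        )
        assert (truth["class"] == "null").all()
        assert (truth["effect"] == 0).all()

    def test_truth_class_counts_match_config_rounding(self, small_cohort):
        truth = small_cohort.truth
        cfg = small_cohort.config
        assert (truth["class"] == "dmp").sum() == round(cfg.frac_dmp * cfg.n_probes)
        n_sync = truth["class"].str.startswith("sync").sum()
        assert n_sync == round(cfg.frac_sync * cfg.n_probes)

    def test_values_within_truncation_bounds(self, small_cohort):
        vals = small_cohort.beta.values.to_numpy()
        assert vals.min() >= 0.001 and vals.max() <= 0.999

    def test_null_sd_personal_matches_sigma_bio(self):
        """Median sd_personal of null probes ≈ E[sample SD | N(0, σ_bio²)]."""
        cfg = SimulationConfig(n_probes=20000, frac_dmp=0.0, frac_sync=0.0, seed=8)
        annot = generate_manifest(cfg)
        beta, _ = generate_beta_matrix(
            cfg, generate_phenotype_series("glucose", cfg), annot
        )
        metrics = personal_dispersion(beta)
        # closed form: sample SD of 6 normal draws has median sqrt(chi2_5 median/5)·σ
        from scipy.stats import chi2

        implied = cfg.sigma_bio * np.sqrt(chi2.ppf(0.5, df=5) / 5)
        observed = float(np.nanmedian(metrics.sd_personal.to_numpy()))
        assert abs(observed - implied) / implied < 0.2

    def test_zero_noise_no_effects_series_constant(self):
        cfg = SimulationConfig(
            n_probes=30, frac_dmp=0.0, frac_sync=0.0, sigma_bio=0.0, seed=9
        )
        beta, _ = generate_beta_matrix(
            cfg, generate_phenotype_series("glucose", cfg), generate_manifest(cfg)
        )
        for subj in cfg.subjects:
            series = beta.subject_series(subj).to_numpy()
            assert np.all(series == series[:, [0]])

    def test_phenotype_subject_mismatch_errors(self):
        cfg = SimulationConfig(n_probes=10, seed=1)
        phen = generate_phenotype_series("glucose", cfg)
        phen = phen[phen["subject"] != "S03"]
        with pytest.raises(ValueError, match="S03"):
            generate_beta_matrix(cfg, phen, generate_manifest(cfg))


class TestReplicate:
    def test_zero_sigma_tech_zero_error(self, small_cohort):
        beta = small_cohort.beta.drop_replicates()
        rep = generate_replicate(beta, beta.samples[0], sigma_tech=0.0, seed=1)
        err, summary = replicate_error(rep)
        assert (err == 0).all()

    def test_p75_calibration_closed_form(self):
        """σ_tech from P75(|N(0,2σ²)|)=0.008 → empirical P75 within ±20%."""
        sigma = calibrate_sigma_tech(0.008, frac_below=0.75)
        cfg = SimulationConfig(
            n_probes=20000, frac_dmp=0.0, frac_sync=0.0, sigma_tech=sigma, seed=10
        )
        beta, _ = generate_beta_matrix(
            cfg, generate_phenotype_series("glucose", cfg), generate_manifest(cfg)
        )
        rep = generate_replicate(beta, beta.samples[0], sigma, seed=10)
        _, summary = replicate_error(rep)
        assert abs(summary["q75"] - 0.008) / 0.008 < 0.2

    def test_same_seed_identical_replicate(self, small_cohort):
        beta = small_cohort.beta.drop_replicates()
        r1 = generate_replicate(beta, beta.samples[0], 0.005, seed=3)
        r2 = generate_replicate(beta, beta.samples[0], 0.005, seed=3)
        assert r1.values.equals(r2.values)

    def test_unknown_sample_errors(self, small_cohort):
        with pytest.raises(ValueError, match="unknown sample"):
            generate_replicate(small_cohort.beta, "nope", 0.005)


def test_simulate_dataset_bit_identical_under_seed():
    a = simulate_dataset(SimulationConfig(n_probes=300, seed=42))
    b = simulate_dataset(SimulationConfig(n_probes=300, seed=42))
    assert a.beta.values.equals(b.beta.values)
    assert a.manifest.equals(b.manifest)
    assert a.phenotypes.equals(b.phenotypes)
    assert a.truth.equals(b.truth)
    c = simulate_dataset(SimulationConfig(n_probes=300, seed=43))
    assert not a.beta.values.equals(c.beta.values)
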