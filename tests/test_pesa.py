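"""PeSa dual-correlation screen: components, scan, aggregation, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from methylsync.pesa import (
    aggregate_genes,
    pearson_corr_p,
    pesa_probe,
    pesa_scan,
    rank_sync_probes,
    slope_series,
)
from methylsync.synth import SimulationConfig, generate_phenotype_series

from conftest import clean_annotation, make_beta


def _t_sf_oracle(t, df):
    """Student-t survival function via the regularized incomplete beta."""
    x = df / (df + t * t)
    return 0.5 * special.betainc(df / 2.0, 0.5, x)


def _pearson_oracle(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)
    r = np.corrcoef(a, b)[0, 1]
    if abs(r) >= 1.0:
        return r, 0.0
    t = abs(r) * np.sqrt((n - 2) / (1 - r * r))
    return r, 2 * _t_sf_oracle(t, n - 2)


class TestPearson:
    def test_identical_series_rho_one_p_zero(self):
        rho, p = pearson_corr_p([0.1, 0.4, 0.2, 0.6, 0.5, 0.9], [0.1, 0.4, 0.2, 0.6, 0.5, 0.9])
        assert rho == 1.0 and p == 0.0

    def test_reversed_series_rho_minus_one(self):
        rho, p = pearson_corr_p([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1])
        assert rho == -1.0 and p == 0.0

    def test_matches_t_cdf_oracle_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            a, b = rng.normal(size=(2, 6))
            rho, p = pearson_corr_p(a, b)
            rho_o, p_o = _pearson_oracle(a, b)
            assert rho == pytest.approx(rho_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_constant_vector_convention(self):
        rho, p = pearson_corr_p([0.5, 0.5, 0.5, 0.5], [1, 2, 3, 4])
        assert np.isnan(rho) and p == 1.0

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            pearson_corr_p([1, 2], [3, 4])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 6))
        r1, p1 = pearson_corr_p(a, b)
        r2, p2 = pearson_corr_p(b, a)
        assert r1 == pytest.approx(r2, abs=1e-12) and p1 == pytest.approx(p2, abs=1e-12)
        r3, p3 = pearson_corr_p(2.5 * a + 1.0, b)
        assert r3 == pytest.approx(r1, abs=1e-9) and p3 == pytest.approx(p1, abs=1e-9)
        r4, _ = pearson_corr_p(-1.5 * a, b)
        assert r4 == pytest.approx(-r1, abs=1e-9)


@pytest.mark.parametrize(
    "series,expected",
    [
        ([1, 3, 2], [2, -1]),
        ([5, 5, 5, 5], [0, 0, 0]),
        ([1, 3, 5, 7], [2, 2, 2]),
    ],
)
def test_slope_series_examples(series, expected):
    assert slope_series(series).tolist() == expected


def test_slope_series_too_short():
    with pytest.raises(ValueError):
        slope_series([1.0])


class TestPesaProbe:
    def test_exact_shape_match_passes(self):
        # b is an affine image of a: correlation 1 up to float rounding
        call = pesa_probe([0.1, 0.3, 0.2, 0.5, 0.4, 0.6], [1, 3, 2, 5, 4, 6])
        assert call.rho_corr == pytest.approx(1.0, abs=1e-12)
        assert call.p_corr < 1e-15
        assert call.rho_slope == pytest.approx(1.0, abs=1e-12)
        assert call.p_slope < 1e-15
        assert call.passed

    def test_mirrored_antiphase_passes_with_negative_rho(self):
        a = [0.1, 0.3, 0.2, 0.5, 0.4, 0.6]
        b = [-x for x in a]
        call = pesa_probe(a, b)
        assert call.rho_corr == pytest.approx(-1.0, abs=1e-12)
        assert call.passed

    def test_linear_trends_fail_conservatively(self):
        """Both exactly linear → slope series constant → p_slope=1 → no pass."""
        call = pesa_probe([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12])
        assert call.p_corr == 0.0
        assert call.p_slope == 1.0 and not call.passed

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=(2, 6))
        c1, c2 = pesa_probe(a, b), pesa_probe(b, a)
        assert c1.p_corr == pytest.approx(c2.p_corr, abs=1e-12)
        assert c1.p_slope == pytest.approx(c2.p_slope, abs=1e-12)
        assert c1.passed == c2.passed

    def test_null_pass_rate_bounded_alpha2_alpha(self):
        """Independent series: dual-criterion rate between α² and α."""
        rng = np.random.default_rng(14)
        passes = sum(
            pesa_probe(rng.normal(size=6), rng.normal(size=6)).passed
            for _ in range(4000)
        )
        rate = passes / 4000
        assert 0.0025 * 0.5 <= rate <= 0.05  # small slack below α² for MC noise

    def test_requires_four_points(self):
        with pytest.raises(ValueError):
            pesa_probe([1, 2, 3], [4, 5, 6])


class TestPesaScan:
    def _scan_setup(self, sigma_bio, seed=15):
        cfg = SimulationConfig(
            n_probes=200, frac_dmp=0.0, frac_sync=0.1, effect_sync=0.05,
            sigma_bio=sigma_bio, seed=seed,
        )
        from methylsync.synth import generate_beta_matrix, generate_manifest

        annot = generate_manifest(cfg)
        phen = generate_phenotype_series("glucose", cfg)
        beta, truth = generate_beta_matrix(cfg, phen, annot)
        return cfg, beta, phen, truth

    def test_noise_free_sync_probes_all_recovered(self):
        cfg, beta, phen, truth = self._scan_setup(sigma_bio=0.0)
        sync = set(truth.index[truth["class"] == "sync_glucose"])
        # perfect coupling holds only where the [0.001, 0.999] truncation
        # did not clip the planted trajectory
        vals = beta.values
        unclipped = {
            p for p in sync
            if (vals.loc[p] > 0.001).all() and (vals.loc[p] < 0.999).all()
        }
        assert unclipped  # the check must not be vacuous
        for subj in cfg.subjects:
            res = pesa_scan(beta, phen, subj, "glucose", sd_min=0.0)
            passing = set(res.loc[res["pass"], "probe"])
            assert unclipped <= passing

    def test_bookkeeping_fields(self):
        cfg, beta, phen, _ = self._scan_setup(sigma_bio=0.01)
        res = pesa_scan(beta, phen, "S01", "glucose")
        assert res.attrs["n_candidates"] == len(res)
        assert res.attrs["n_passing"] == int(res["pass"].sum())
        assert res.attrs["frac_passing"] == pytest.approx(
            res.attrs["n_passing"] / max(res.attrs["n_candidates"], 1)
        )

    def test_infinite_sd_min_gives_empty_result(self):
        cfg, beta, phen, _ = self._scan_setup(sigma_bio=0.01)
        res = pesa_scan(beta, phen, "S01", "glucose", sd_min=np.inf)
        assert len(res) == 0 and res.attrs["n_candidates"] == 0

    def test_no_shared_days_errors(self):
        cfg, beta, phen, _ = self._scan_setup(sigma_bio=0.01)
        shifted = phen.copy()
        shifted["day"] = shifted["day"] + 10000
        with pytest.raises(ValueError, match="shared sampling days"):
            pesa_scan(beta, shifted, "S01", "glucose")


def _calls(rows):
    return pd.DataFrame(rows, columns=["probe", "subject", "rho_corr", "p_corr",
                                       "rho_slope", "p_slope", "pass"])


class TestAggregateGenes:
    def _annot(self):
        return clean_annotation(
            ["cg1", "cg2", "cg3"],
            genes=["GENEA", "GENEA;GENEB", ""],
            feature_groups=["Body", "TSS200;Body", "IGR"],
        )

    def test_gene_in_all_subjects_flagged(self):
        rows = [(f"cg1", f"S{i:02d}", 0.9, 0.01, 0.9, 0.01, True) for i in range(1, 7)]
        table = aggregate_genes([_calls(rows)], self._annot())
        rec = table[table["gene"] == "GENEA"].iloc[0]
        assert rec["n_subjects"] == 6 and rec["consistent_all"]

    def test_igr_probe_contributes_nothing(self):
        rows = [("cg3", "S01", 0.9, 0.01, 0.9, 0.01, True)]
        table = aggregate_genes([_calls(rows)], self._annot())
        assert len(table) == 0

    def test_multi_gene_probe_counts_for_both(self):
        rows = [("cg2", "S01", 0.9, 0.01, 0.9, 0.01, True)]
        table = aggregate_genes([_calls(rows)], self._annot())
        assert set(table["gene"]) == {"GENEA", "GENEB"}

    def test_invariant_to_subject_order(self):
        rows = [("cg1", s, 0.9, 0.01, 0.9, 0.01, True) for s in ("S01", "S02", "S03")]
        t1 = aggregate_genes([_calls(rows)], self._annot())
        t2 = aggregate_genes([_calls(rows[::-1])], self._annot())
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_input_empty_table(self):
        assert len(aggregate_genes([], self._annot())) == 0


class TestRankSyncProbes:
    def test_absolute_value_ranking(self):
        df = _calls([
            ("a", "S01", 0.99, 1e-4, 0.9, 0.01, True),
            ("b", "S01", -0.995, 1e-5, 0.9, 0.01, True),
            ("c", "S01", 0.5, 0.2, 0.9, 0.01, False),
        ])
        ranked = rank_sync_probes(df)
        assert ranked["probe"].tolist() == ["b", "a", "c"]

    def test_tie_broken_by_probe_id(self):
        df = _calls([
            ("z", "S01", 0.8, 0.01, 0.9, 0.01, True),
            ("a", "S01", -0.8, 0.01, 0.9, 0.01, True),
        ])
        assert rank_sync_probes(df)["probe"].tolist() == ["a", "z"]

    def test_top_k_and_full_list(self):
        df = _calls([(f"p{i}", "S01", 0.1 * i, 0.01, 0.5, 0.01, True) for i in range(5)])
        assert len(rank_sync_probes(df, top_k=2)) == 2
        assert len(rank_sync_probes(df)) == 5
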