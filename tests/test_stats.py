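"""Weighted chi-squared gene tests, BH, chi-scores, burden and RMAF models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xdisp.stats import (
    GeneTestResult,
    bh_adjust,
    burden_model,
    chi_score,
    gene_tests,
    rmaf_sex_compare,
    set_vs_rest,
    size_nem_correlation,
    weighted_chi2,
)


def _records(statuses_f, statuses_m):
    """Gene-level records for one gene: one patient per status entry."""
    pids = [f"F{i}" for i in range(len(statuses_f))] + [
        f"M{i}" for i in range(len(statuses_m))
    ]
    clinical = pd.DataFrame(
        {
            "patient_id": pids,
            "sex": ["female"] * len(statuses_f) + ["male"] * len(statuses_m),
            "cancer_type": "C1",
        }
    )
    records = pd.DataFrame(
        {
            "patient_id": pids,
            "gene": "G",
            "chrom": "X",
            "pos": range(len(pids)),
            "rmaf": [0.0 if s == "NEM" else 1.0 for s in statuses_f + statuses_m],
            "status": statuses_f + statuses_m,
            "rule": "pileup",
            "total_reads": 50,
        }
    )
    return records, clinical


class TestWeightedChi2:
    def test_unit_weights_equal_classic_chi2(self):
        statuses_f = ["NEM"] * 12 + ["EM"] * 8
        statuses_m = ["NEM"] * 3 + ["EM"] * 17
        records, clinical = _records(statuses_f, statuses_m)
        ones = pd.Series(1.0, index=records["patient_id"])
        res = weighted_chi2("G", records, clinical, ones)
        ref_stat, ref_p, _, _ = sps.chi2_contingency(
            [[12, 8], [3, 17]], correction=False
        )
        assert res.chi2_stat == pytest.approx(ref_stat, abs=1e-10)
        assert res.p_value == pytest.approx(ref_p, abs=1e-10)
        assert res.n_nem_f == 12 and res.n_nem_m == 3

    def test_balanced_table_gives_zero_statistic(self):
        records, clinical = _records(
            ["NEM"] * 10 + ["EM"] * 10, ["NEM"] * 10 + ["EM"] * 10
        )
        ones = pd.Series(1.0, index=records["patient_id"])
        res = weighted_chi2("G", records, clinical, ones)
        assert res.chi2_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_weights_change_the_table(self):
        records, clinical = _records(["NEM", "EM"], ["NEM", "EM"])
        w = pd.Series([0.5, 1.0, 1.0, 0.25], index=records["patient_id"])
        res = weighted_chi2("G", records, clinical, w)
        np.testing.assert_allclose(res.table, [[0.5, 1.0], [1.0, 0.25]])

    def test_zero_marginal_is_untestable(self):
        records, clinical = _records(["NEM", "NEM"], ["NEM", "NEM"])
        ones = pd.Series(1.0, index=records["patient_id"])
        res = weighted_chi2("G", records, clinical, ones)
        assert not res.testable and np.isnan(res.chi2_stat)

    def test_single_sex_is_untestable(self):
        records, clinical = _records(["NEM", "EM"], [])
        ones = pd.Series(1.0, index=records["patient_id"])
        assert not weighted_chi2("G", records, clinical, ones).testable


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_rolled_bh_on_random_vector(self):
        rng = np.random.default_rng(0)
        p = rng.random(57)
        # independent step-up implementation
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)

    def test_empty_and_invalid(self):
        assert bh_adjust([]).size == 0
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestChiScore:
    @staticmethod
    def _result(stat, prop_f, prop_m):
        return GeneTestResult(
            gene="G", table=np.ones((2, 2)), chi2_stat=stat, p_value=0.05,
            n_nem_f=1, n_nem_m=1, prop_nem_f=prop_f, prop_nem_m=prop_m,
            testable=True,
        )

    def test_sign_follows_female_excess(self):
        assert chi_score(self._result(4.0, 0.6, 0.3)) == pytest.approx(2.0)
        assert chi_score(self._result(9.0, 0.2, 0.5)) == pytest.approx(-3.0)

    def test_sign_flips_under_sex_swap(self):
        a = chi_score(self._result(4.0, 0.6, 0.3))
        b = chi_score(self._result(4.0, 0.3, 0.6))
        assert a == -b


class TestSetVsRest:
    def test_identical_groups_large_p(self):
        scores = np.concatenate([np.linspace(-2, 2, 50), np.linspace(-2, 2, 50)])
        in_set = np.array([True] * 50 + [False] * 50)
        _, p = set_vs_rest(scores, in_set)
        assert p > 0.9

    def test_shifted_set_detected(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(2, 1, 50), rng.normal(0, 1, 500)])
        in_set = np.array([True] * 50 + [False] * 500)
        _, p = set_vs_rest(scores, in_set)
        assert p < 0.01

    def test_label_exchange_keeps_p(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(0, 1, 100)
        in_set = rng.random(100) < 0.3
        _, p1 = set_vs_rest(scores, in_set)
        _, p2 = set_vs_rest(scores, ~in_set)
        assert p1 == pytest.approx(p2)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            set_vs_rest([1.0, 2.0], [True, True])


class TestBurdenModel:
    def test_recovers_twofold_rate_ratio(self):
        rng = np.random.default_rng(3)
        n = 1000
        counts = np.concatenate([rng.poisson(4.0, n), rng.poisson(2.0, n)])
        sex = np.array(["female"] * n + ["male"] * n)
        res = burden_model(counts, sex)
        assert 1.8 <= res.rate_ratio <= 2.2
        assert res.ci_low <= res.rate_ratio <= res.ci_high

    def test_null_ci_covers_one(self):
        rng = np.random.default_rng(4)
        covered = 0
        for _ in range(100):
            counts = rng.poisson(3.0, 300)
            sex = np.array(["female"] * 150 + ["male"] * 150)
            res = burden_model(counts, sex)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 90

    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3.0, 200)
        sex = np.array(["female"] * 100 + ["male"] * 100)
        a = burden_model(counts, sex)
        b = burden_model(counts, sex, weights=np.full(200, 1.0))
        assert a.rate_ratio == pytest.approx(b.rate_ratio, rel=1e-10)

    def test_single_sex_and_all_zero_errors(self):
        with pytest.raises(ValueError):
            burden_model([1, 2], ["male", "male"])
        with pytest.raises(ValueError):
            burden_model([0, 0], ["male", "female"])


class TestRmafSexCompare:
    @staticmethod
    def _records(rmafs_f, rmafs_m, cancers=None):
        pids = [f"F{i}" for i in range(len(rmafs_f))] + [
            f"M{i}" for i in range(len(rmafs_m))
        ]
        n = len(pids)
        clinical = pd.DataFrame(
            {
                "patient_id": pids,
                "sex": ["female"] * len(rmafs_f) + ["male"] * len(rmafs_m),
                "cancer_type": cancers if cancers is not None else ["C1"] * n,
            }
        )
        records = pd.DataFrame(
            {
                "patient_id": pids, "gene": "G", "chrom": "X",
                "pos": range(n), "rmaf": rmafs_f + rmafs_m,
                "status": "EM", "rule": "pileup", "total_reads": 50,
            }
        )
        return records, clinical

    def test_identical_distributions_zero_coefficient(self):
        vals = [0.1, 0.4, 0.6, 0.9] * 25
        records, clinical = self._records(vals, vals)
        coef, _ = rmaf_sex_compare(records, clinical)
        assert coef == pytest.approx(0.0, abs=1e-10)

    def test_silencing_gives_negative_female_coefficient(self):
        rng = np.random.default_rng(6)
        f = list(np.where(rng.random(1000) < 0.5, 0.0, 1.0))
        m = [1.0] * 1000
        records, clinical = self._records(f, m)
        coef, p = rmaf_sex_compare(records, clinical)
        assert coef < 0 and p < 1e-3

    def test_boundary_values_clipped_to_zero_effect(self):
        records, clinical = self._records([1.0] * 10, [1.0] * 10)
        coef, _ = rmaf_sex_compare(records, clinical)
        assert coef == pytest.approx(0.0, abs=1e-10)

    def test_cancer_adjustment_used_with_multiple_cancers(self):
        # confounded design: females mostly in the low-RMAF cancer; the
        # adjusted model attributes the difference to cancer, not sex
        f = [0.2] * 80 + [0.8] * 20
        m = [0.2] * 20 + [0.8] * 80
        cancers = (["LOW"] * 80 + ["HIGH"] * 20) + (["LOW"] * 20 + ["HIGH"] * 80)
        records, clinical = self._records(f, m, cancers)
        coef_adj, _ = rmaf_sex_compare(records, clinical)
        assert abs(coef_adj) < 1e-8


class TestSizeNemCorrelation:
    def test_perfect_correlation(self):
        r, _ = size_nem_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_independent_counts_near_zero(self):
        rng = np.random.default_rng(7)
        lengths = rng.lognormal(10, 1, 500)
        counts = rng.poisson(3, 500)
        r, _ = size_nem_correlation(lengths, counts)
        assert abs(r) < 0.15

    def test_three_point_hand_fixture(self):
        # x = (1,2,3), y = (2,2,5): r = 3/sqrt(2*6) hand-computed
        r, _ = size_nem_correlation([1, 2, 3], [2, 2, 5])
        assert r == pytest.approx(3 / np.sqrt(12))

    def test_zero_variance_undefined(self):
        assert size_nem_correlation([1, 1, 1], [1, 2, 3]) == (None, None)


class TestGeneTests:
    def test_full_table_on_simulated_bundle(self, small_bundle):
        from xdisp.cohort import cpm_normalize, filter_mutations
        from xdisp.rmaf import classify_mutations, resolve_gene_level

        muts = filter_mutations(small_bundle.mutations, exclude_y=True)
        cpm = cpm_normalize(small_bundle.counts)
        records = resolve_gene_level(
            classify_mutations(muts, small_bundle.pileups, cpm, small_bundle.clinical)
        )
        ones = pd.Series(1.0, index=small_bundle.clinical["patient_id"])
        out = gene_tests(records, small_bundle.clinical, ones)
        testable = out[out["testable"]]
        assert len(testable) > 10
        # adjusted p never below raw p; chi_score^2 equals the statistic
        assert (testable["adj_p"] >= testable["p_value"] - 1e-12).all()
        np.testing.assert_allclose(
            testable["chi_score"] ** 2, testable["chi2_stat"], rtol=1e-8
        )
        # with silencing only in females, significant genes skew female-NEM
        assert (testable["chi_score"] >= 0).mean() > 0.8
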