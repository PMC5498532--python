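"""Survival estimation, log-rank, ROC cutoff, and association statistics."""

import numpy as np
import pandas as pd
import pytest

from emtscreen import (
    chisq_association,
    group_association,
    km_estimate,
    logrank_test,
    paired_association,
    roc_cutoff,
    summarize_by_subtype,
)
from emtscreen.clinical_stats import logrank_min_p_cutoff
from emtscreen.data_model import DataModelError

from .oracles import (
    chi2_2x2_closed_form,
    chi2_oracle,
    km_oracle,
    logrank_oracle,
    paired_t_oracle,
    pooled_t_oracle,
)


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        c = km_estimate([1, 2, 3], [0, 0, 0])
        assert c.event_times.size == 0
        assert c.survival_at(10.0) == 1.0

    def test_all_events_product_limit(self):
        c = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_mixed_censoring_hand_computation(self):
        """{(1,e),(2,c),(3,e),(4,e)}: S(1)=3/4, S(3)=3/4*1/2=3/8, S(4)=0."""
        c = km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        np.testing.assert_allclose(c.event_times, [1, 3, 4])
        np.testing.assert_allclose(c.survival, [0.75, 0.375, 0.0])
        np.testing.assert_array_equal(c.at_risk, [4, 2, 1])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(1, 40).round(2)
        c = km_estimate(t, np.ones(40, int))
        for tt, s in zip(c.event_times, c.survival):
            assert s == pytest.approx((t > tt).mean(), abs=1e-12)

    def test_matches_oracle_randomized(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(3, 40)
            t = rng.exponential(1, n).round(3)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            c = km_estimate(t, e)
            oracle = km_oracle(t, e)
            for tt, s in zip(c.event_times, c.survival):
                assert s == pytest.approx(oracle[tt], abs=1e-10)

    def test_empty_fatal(self):
        with pytest.raises(DataModelError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_hand_table(self):
        res = logrank_test([1, 3], [1, 1], [2, 4], [1, 1])
        expected = logrank_oracle([1, 3], [1, 1], [2, 4], [1, 1])
        assert res.statistic == pytest.approx(expected, abs=1e-10)
        assert res.df == 1

    def test_matches_oracle_randomized(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            na, nb = rng.integers(5, 25, 2)
            ta, tb = rng.exponential(1, na), rng.exponential(1.5, nb)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(ta, ea, tb, eb)
            assert res.statistic == pytest.approx(
                logrank_oracle(ta, ea, tb, eb), abs=1e-10
            )

    def test_group_exchange_invariance(self):
        rng = np.random.default_rng(14)
        ta, tb = rng.exponential(1, 20), rng.exponential(2, 15)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 15)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_no_events_warns_null(self):
        res = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestRocCutoff:
    def test_perfect_separation(self):
        res = roc_cutoff([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.youden_j == pytest.approx(1.0)
        assert 3 < res.cutoff < 10

    def test_forced_sweep_example(self):
        res = roc_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.cutoff == pytest.approx(2.5)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(15)
        v = rng.normal(size=60)
        lab = (v + rng.normal(0, 1, 60) > 0).astype(int)
        j1 = roc_cutoff(v, lab).youden_j
        j2 = roc_cutoff(np.exp(v), lab).youden_j
        assert j1 == pytest.approx(j2, abs=1e-12)

    def test_permuted_labels_give_small_j(self):
        """Labels independent of values: J stays below 0.25 nearly always."""
        rng = np.random.default_rng(16)
        small = 0
        n_rep = 200
        for _ in range(n_rep):
            v = rng.normal(size=200)
            lab = rng.permutation([0] * 100 + [1] * 100)
            if roc_cutoff(v, lab).youden_j < 0.25:
                small += 1
        assert small / n_rep >= 0.95

    def test_one_class_fatal(self):
        with pytest.raises(DataModelError):
            roc_cutoff([1, 2, 3], [1, 1, 1])

    def test_logrank_min_p_cutoff_respects_floor(self):
        rng = np.random.default_rng(17)
        n = 100
        v = rng.normal(size=n)
        t = rng.exponential(np.where(v > 0, 0.5, 2.0))
        e = np.ones(n, int)
        c, res = logrank_min_p_cutoff(v, t, e)
        assert (v > c).sum() >= 10 and (v <= c).sum() >= 10
        assert res.p_value < 0.01


class TestGroupAssociation:
    def test_identical_groups(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array(["M0"] * 3 + ["M1"] * 3)
        res = group_association(v, g, "M0")
        assert res.fold_change == pytest.approx(1.0)
        assert res.test.p_value == pytest.approx(1.0)

    def test_fold_change_arithmetic(self):
        v = np.array([5.0, 5.0, 4.0, 4.0])
        g = np.array(["M0", "M0", "M1", "M1"])
        res = group_association(v, g, "M0")
        assert res.fold_change == pytest.approx(1.25)
        assert res.numerator == "M0" and res.denominator == "M1"

    def test_matches_pooled_t_oracle(self):
        rng = np.random.default_rng(18)
        a, b = rng.normal(5, 1, 12), rng.normal(4, 1, 9)
        v = np.concatenate([a, b])
        g = np.array(["M0"] * 12 + ["M1"] * 9)
        res = group_association(v, g, "M0")
        t_exp, p_exp = pooled_t_oracle(a, b)
        assert res.test.statistic == pytest.approx(t_exp, abs=1e-10)
        assert res.test.p_value == pytest.approx(p_exp, abs=1e-10)

    def test_small_group_fatal(self):
        with pytest.raises(DataModelError):
            group_association(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]), "a")


class TestPairedAssociation:
    def test_identical_pairs_null(self):
        res = paired_association([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_paired_oracle(self):
        rng = np.random.default_rng(19)
        a = rng.normal(5, 1, 10)
        b = a - 1 + rng.normal(0, 0.3, 10)
        res = paired_association(a, b)
        t_exp, p_exp = paired_t_oracle(a, b)
        assert res.statistic == pytest.approx(t_exp, abs=1e-10)
        assert res.p_value == pytest.approx(p_exp, abs=1e-10)

    def test_swap_negates_t(self):
        rng = np.random.default_rng(20)
        a, b = rng.normal(size=8), rng.normal(size=8)
        r1, r2 = paired_association(a, b), paired_association(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestChisq:
    def test_independence_table(self):
        res = chisq_association([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_expected_table(self):
        res = chisq_association([[20, 5], [5, 20]])
        assert res.statistic == pytest.approx(18.0, abs=1e-10)
        assert res.df == 1

    def test_closed_form_2x2_randomized(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            table = rng.integers(1, 50, (2, 2))
            res = chisq_association(table)
            assert res.statistic == pytest.approx(
                chi2_2x2_closed_form(table), abs=1e-10
            )

    def test_matches_oracle_rxc(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            table = rng.integers(1, 30, (4, 2))
            res = chisq_association(table)
            stat, p, df = chi2_oracle(table)
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)
            assert res.df == df

    def test_duplicated_row_collapse_invariance(self):
        """Merging two identically proportioned rows leaves the Pearson
        statistic unchanged (the degrees of freedom, and hence p, drop)."""
        r1 = chisq_association([[10, 20], [10, 20], [30, 5]])
        r2 = chisq_association([[20, 40], [30, 5]])
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
        assert r1.df == r2.df + 1

    def test_zero_marginal_fatal(self):
        with pytest.raises(DataModelError):
            chisq_association([[0, 0], [5, 5]])


class TestSubtypeSummary:
    def test_identical_groups_null_kw(self):
        scores = pd.Series([1.0, 2.0, 3.0] * 4)
        labels = pd.Series(["S1"] * 3 + ["S2"] * 3 + ["S3"] * 3 + ["S4"] * 3)
        summary, test = summarize_by_subtype(scores, labels)
        assert test.statistic == pytest.approx(0.0, abs=1e-9)
        assert set(summary["subtype"]) == {"S1", "S2", "S3", "S4"}

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(23)
        scores = np.concatenate([rng.normal(0, 1, 75), rng.normal(3, 1, 25)])
        labels = ["S1"] * 25 + ["S2"] * 25 + ["S3"] * 25 + ["S4"] * 25
        _, test = summarize_by_subtype(pd.Series(scores), pd.Series(labels))
        assert test.p_value < 0.001
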