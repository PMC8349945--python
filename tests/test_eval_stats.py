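import numpy as np
import pytest
from oracles import auc_by_pair_enumeration, delong_variance_by_hand, youden_by_grid

from simivim import (
    ConfusionTable,
    LabeledSample,
    accuracy_from_rates,
    confusion_metrics,
    delong_compare,
    group_test,
    icc,
    roc,
)


def random_sample(rng, n_max=40, direction="higher_is_positive"):
    n_pos = int(rng.integers(1, n_max // 2))
    n_neg = int(rng.integers(1, n_max // 2))
    # mix continuous and tied integer scores
    if rng.random() < 0.5:
        pos = rng.normal(1.0, 1.0, n_pos)
        neg = rng.normal(0.0, 1.0, n_neg)
    else:
        pos = rng.integers(0, 6, n_pos).astype(float)
        neg = rng.integers(0, 6, n_neg).astype(float)
    values = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    return LabeledSample(values, labels, direction)


class TestROC:
    def test_perfect_separation(self):
        s = LabeledSample([5, 6, 7, 1, 2], [True, True, True, False, False])
        res = roc(s)
        assert res.auc == 1.0
        assert res.optimal_sens == 1.0 and res.optimal_spec == 1.0

    def test_direction_flip(self):
        s = LabeledSample([1, 2, 3, 4], [True, True, False, False], "lower_is_positive")
        assert roc(s).auc == 1.0
        s2 = LabeledSample([1, 2, 3, 4], [True, True, False, False], "higher_is_positive")
        assert roc(s2).auc == 0.0

    def test_auc_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            s = random_sample(rng)
            expected = auc_by_pair_enumeration(s.values[s.labels], s.values[~s.labels])
            assert roc(s).auc == pytest.approx(expected, abs=1e-12)

    def test_auc_plus_flipped_is_one_without_ties(self):
        rng = np.random.default_rng(7)
        values = rng.permutation(np.arange(30, dtype=float))
        labels = rng.random(30) > 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a = roc(LabeledSample(values, labels, "higher_is_positive")).auc
        b = roc(LabeledSample(values, labels, "lower_is_positive")).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_auc_within_ci(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            res = roc(random_sample(rng))
            lo, hi = res.auc_ci95
            assert lo <= res.auc <= hi

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            LabeledSample([1.0, 2.0], [True, True])


class TestYouden:
    def test_worked_example(self):
        """pos {0,1,2.5} / neg {2,3,4}, lower positive: cutoff 2.75 with
        sens 1, spec 2/3 maximises J = 2/3."""
        s = LabeledSample([0, 1, 2.5, 2, 3, 4],
                          [True, True, True, False, False, False],
                          "lower_is_positive")
        res = roc(s)
        assert res.optimal_cutoff == pytest.approx(2.75)
        assert res.optimal_sens == pytest.approx(1.0)
        assert res.optimal_spec == pytest.approx(2 / 3)

    def test_separable_sample_deterministic(self):
        s = LabeledSample([1, 2, 3, 4], [True, True, False, False], "lower_is_positive")
        res = roc(s)
        assert res.optimal_cutoff == pytest.approx(2.5)
        assert res.optimal_sens == res.optimal_spec == 1.0

    @pytest.mark.parametrize("direction", ["higher_is_positive", "lower_is_positive"])
    def test_matches_grid_oracle(self, direction):
        rng = np.random.default_rng(77)
        for _ in range(100):
            s = random_sample(rng, direction=direction)
            res = roc(s)
            j_oracle, sens_oracle = youden_by_grid(
                s.values, s.labels, direction == "lower_is_positive")
            j = res.optimal_sens + res.optimal_spec - 1.0
            assert j == pytest.approx(j_oracle, abs=1e-9)
            assert res.optimal_sens == pytest.approx(sens_oracle, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        """A strictly increasing transform leaves J and the induced sample
        classification unchanged (the cutoff moves inside the mapped gap)."""
        rng = np.random.default_rng(5)
        s = random_sample(rng)
        res = roc(s)
        t = LabeledSample(np.exp(s.values / 3.0), s.labels, s.direction)
        res_t = roc(t)
        assert (res_t.optimal_sens + res_t.optimal_spec
                == pytest.approx(res.optimal_sens + res.optimal_spec, abs=1e-12))
        calls = s.values > res.optimal_cutoff
        calls_t = t.values > res_t.optimal_cutoff
        assert np.array_equal(calls, calls_t)

    def test_accuracy_uses_sample_prevalence(self):
        s = LabeledSample([1, 2, 3, 10, 11], [True, True, True, False, False],
                          "lower_is_positive")
        res = roc(s)
        assert res.optimal_acc == pytest.approx((1.0 * 3 + 1.0 * 2) / 5)


class TestDeLong:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(3)
        s = random_sample(rng)
        res = roc(s)
        z, p = delong_compare(res, res, paired=True)
        assert z == 0.0 and p == 1.0

    def test_ci_consistent_with_variance(self):
        rng = np.random.default_rng(4)
        res = roc(random_sample(rng))
        half = 1.959963984540054 * np.sqrt(res.auc_var)
        lo, hi = res.auc_ci95
        assert hi == pytest.approx(min(1.0, res.auc + half), abs=1e-12)
        assert lo == pytest.approx(max(0.0, res.auc - half), abs=1e-12)

    def test_variance_matches_hand_enumeration(self):
        """Six-subject toy marker: structural-components variance equals
        the longhand placement computation."""
        values = np.array([0.9, 0.8, 0.35, 0.7, 0.3, 0.2])
        labels = np.array([True, True, True, False, False, False])
        res = roc(LabeledSample(values, labels))
        expected = delong_variance_by_hand(values[labels], values[~labels])
        assert res.auc_var == pytest.approx(expected, rel=1e-12)

    def test_paired_variance_decomposition(self):
        """var(AUC_a - AUC_b) = var_a + var_b - 2 cov, with the covariance
        recomputed from the placement components directly."""
        rng = np.random.default_rng(11)
        n = 30
        labels = np.concatenate([np.ones(15, bool), np.zeros(15, bool)])
        base = rng.normal(labels.astype(float), 1.0)
        va = base + rng.normal(0, 0.5, n)
        vb = base + rng.normal(0, 0.5, n)
        ra, rb = roc(LabeledSample(va, labels)), roc(LabeledSample(vb, labels))
        z, _ = delong_compare(ra, rb, paired=True)

        from simivim.eval_stats import _placements

        a10, a01, auc_a = _placements(va[labels], va[~labels])
        b10, b01, auc_b = _placements(vb[labels], vb[~labels])
        cov = (np.cov(a10, b10, ddof=1)[0, 1] / a10.size
               + np.cov(a01, b01, ddof=1)[0, 1] / a01.size)
        var = ra.auc_var + rb.auc_var - 2 * cov
        assert z == pytest.approx((auc_a - auc_b) / np.sqrt(var), rel=1e-12)

    def test_paired_requires_matching_labels(self):
        ra = roc(LabeledSample([1, 2, 3, 4], [True, True, False, False]))
        rb = roc(LabeledSample([1, 2, 3, 4], [True, False, True, False]))
        with pytest.raises(ValueError):
            delong_compare(ra, rb, paired=True)

    def test_unpaired_uses_variance_sum(self):
        rng = np.random.default_rng(13)
        ra, rb = roc(random_sample(rng)), roc(random_sample(rng))
        z, p = delong_compare(ra, rb, paired=False)
        expected_z = (ra.auc - rb.auc) / np.sqrt(ra.auc_var + rb.auc_var)
        assert z == pytest.approx(expected_z, rel=1e-12)
        assert 0 <= p <= 1


class TestGroupTest:
    def test_identical_groups_give_p_one(self):
        # skewed duplicates fail the normality gate -> exact Mann-Whitney
        a = [1.0, 1.0, 1.0, 8.0]
        res = group_test(a, list(a))
        assert res.test_name == "mann_whitney_exact"
        assert res.p_value == pytest.approx(1.0)
        # normal-looking identical groups take the Welch branch, same p
        res_t = group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res_t.test_name == "welch_t"
        assert res_t.p_value == pytest.approx(1.0)

    def test_tiny_separated_groups_exact_p(self):
        """{1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 assignments,
        two-sided exact p = 2/20 = 0.1. (These values look perfectly
        normal to Shapiro-Wilk, so the enumeration is exercised directly.)"""
        from simivim.eval_stats import _mwu_exact

        _, p = _mwu_exact(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert p == pytest.approx(0.1)

    def test_gaussian_separation_selects_welch(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(3.0, 1.0, 30)
        res = group_test(a, b)
        assert res.test_name == "welch_t"
        assert res.p_value < 1e-3

    def test_skewed_data_selects_mann_whitney(self):
        rng = np.random.default_rng(22)
        a = rng.exponential(1.0, 50) ** 3
        b = rng.exponential(2.0, 50) ** 3
        assert group_test(a, b).test_name == "mann_whitney_normal"

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_test([1.0], [2.0, 3.0])


class TestConfusionMetrics:
    @pytest.mark.parametrize("tp,fn,tn,fp,expected", [
        (72, 2, 32, 3, (0.973, 0.914, 0.954)),
        (70, 4, 29, 6, (0.946, 0.829, 0.908)),
    ])
    def test_pooled_reader_tables(self, tp, fn, tn, fp, expected):
        """Reader-study counts reproduce the printed metrics exactly at
        3-decimal display precision."""
        sens, spec, acc = confusion_metrics(ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn))
        assert (round(sens, 3), round(spec, 3), round(acc, 3)) == expected

    def test_perfect_table(self):
        assert confusion_metrics(ConfusionTable(10, 0, 5, 0)) == (1.0, 1.0, 1.0)

    def test_empty_class_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            confusion_metrics(ConfusionTable(tp=5, fp=0, tn=0, fn=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(-1, 0, 0, 1)

    @pytest.mark.parametrize("sens,spec,n_pos,n_neg,expected", [
        (0.932, 0.943, 74, 35, 0.936),  # combined D'/f' rule
        (0.892, 0.914, 74, 35, 0.899),  # ADC rule
        (0.988, 0.913, 86, 23, 0.972),  # D', haemangioma contrast
        (0.907, 1.000, 97, 12, 0.917),  # f', FNH contrast
    ])
    def test_accuracy_from_printed_rates(self, sens, spec, n_pos, n_neg, expected):
        assert round(accuracy_from_rates(sens, spec, n_pos, n_neg), 3) == expected


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc(x) == pytest.approx(1.0)

    def test_constant_shift_below_one_for_absolute_agreement(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x = np.column_stack([base, base + 1.0])
        assert icc(x, "ICC2") < 1.0
        assert icc(x, "ICC3") == pytest.approx(1.0)

    def test_matches_anova_oracle(self):
        """Five-subject toy matrix vs an independent two-way ANOVA
        mean-squares computation (pingouin)."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = np.array([[9, 2, 5, 8],
                      [6, 1, 3, 2],
                      [8, 4, 6, 8],
                      [7, 1, 2, 6],
                      [10, 5, 6, 9]], dtype=float)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(5), 4),
            "rater": np.tile(np.arange(4), 5),
            "score": x.ravel(),
        })
        res = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        one_way, absolute, consistency = res["ICC"].values[:3]
        assert icc(x, "ICC1") == pytest.approx(one_way, rel=1e-9)
        assert icc(x, "ICC2") == pytest.approx(absolute, rel=1e-9)
        assert icc(x, "ICC3") == pytest.approx(consistency, rel=1e-9)

    def test_zero_between_subject_variance_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            icc(np.array([[1.0, 2.0], [1.0, 2.0]]))

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))
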