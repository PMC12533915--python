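"""Evaluation statistics against hand arithmetic and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vcglvh import (ConfusionCounts, auc, ccr_table, confusion_metrics,
                    counts_from_rates, crossvalidate, delong_test,
                    make_feature_table, mcnemar_bonferroni,
                    power_two_proportions)
from vcglvh.modeling import LABEL
from vcglvh.trees import TrainConfig, train_tree


class TestConfusionMetrics:
    def test_cornell_test_row_hand_arithmetic(self):
        rep = confusion_metrics(ConfusionCounts(TP=20, FP=4, FN=73, TN=107))
        row = rep.as_percent_row()
        assert row["accuracy_pct"] == 62.25 or row["accuracy_pct"] == 62.3
        assert rep.accuracy == pytest.approx(127 / 204)
        assert row["ppv_pct"] == pytest.approx(83.3)
        assert row["npv_pct"] == pytest.approx(59.4)
        assert row["f1"] == pytest.approx(0.342)

    def test_degenerate_all_negative(self):
        rep = confusion_metrics(ConfusionCounts(TP=0, FP=0, FN=0, TN=10))
        assert rep.accuracy == 1.0
        assert np.isnan(rep.sensitivity)
        assert rep.specificity == 1.0

    def test_swap_symmetry(self):
        a = confusion_metrics(ConfusionCounts(TP=30, FP=7, FN=12, TN=51))
        b = confusion_metrics(ConfusionCounts(TP=51, FP=12, FN=7, TN=30))
        assert b.sensitivity == pytest.approx(a.specificity)
        assert b.specificity == pytest.approx(a.sensitivity)
        assert b.ppv == pytest.approx(a.npv)
        assert b.npv == pytest.approx(a.ppv)

    def test_brute_force_tally(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            calls = rng.integers(0, 2, n)
            truth = rng.integers(0, 2, n)
            if not (calls.any() or truth.any()):
                continue
            c = ConfusionCounts.from_calls(calls, truth)
            assert c.TP == sum(int(a and t) for a, t in zip(calls, truth))
            assert c.TN == sum(int(not a and not t)
                               for a, t in zip(calls, truth))
            assert c.total == n

    def test_clopper_pearson_known_value(self):
        # 127/204 exact 95% CI (binomial test inversion)
        rep = confusion_metrics(ConfusionCounts(TP=20, FP=4, FN=73, TN=107))
        lo, hi = rep.accuracy_ci
        assert lo == pytest.approx(stats.beta.ppf(0.025, 127, 78), abs=1e-12)
        assert hi == pytest.approx(stats.beta.ppf(0.975, 128, 77), abs=1e-12)
        assert lo < rep.accuracy < hi

    def test_wilson_option(self):
        rep = confusion_metrics(ConfusionCounts(TP=20, FP=4, FN=73, TN=107),
                                ci_method="wilson")
        lo, hi = rep.accuracy_ci
        assert lo < 127 / 204 < hi
        with pytest.raises(ValueError, match="CI method"):
            confusion_metrics(ConfusionCounts(TP=1, FP=1, FN=1, TN=1),
                              ci_method="bogus")

    def test_counts_from_rates_inversion(self):
        c = counts_from_rates(21.5, 96.4, n_pos=93, n_neg=111)
        assert (c.TP, c.TN) == (20, 107)
        assert (c.FN, c.FP) == (73, 4)


class TestDeLong:
    def test_perfect_scores(self):
        labels = np.array([0, 1] * 20)
        res = delong_test(labels.astype(float), labels.astype(float), labels)
        assert res.auc_a == 1.0

    def test_identical_classifiers(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50) + labels
        res = delong_test(scores, scores, labels)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_auc_equals_trapezoid_roc(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        scores = rng.normal(size=80)        # continuous: tie-free
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_bootstrap_oracle_60_patients(self):
        rng = np.random.default_rng(3)
        n = 60
        labels = np.r_[np.zeros(30), np.ones(30)].astype(int)
        scores_a = rng.normal(size=n) + 1.0 * labels
        scores_b = rng.normal(size=n) + 0.5 * labels
        res = delong_test(scores_a, scores_b, labels)

        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(np.unique(labels[idx])) < 2:
                continue
            boots.append(auc(scores_a[idx], labels[idx])
                         - auc(scores_b[idx], labels[idx]))
        boots = np.asarray(boots)
        diff_var = res.var_a + res.var_b - 2 * res.cov_ab
        se = np.sqrt(diff_var)
        assert (res.auc_a - res.auc_b) == pytest.approx(np.mean(boots),
                                                        abs=3 * se)
        assert np.sqrt(boots.var()) == pytest.approx(se, rel=0.35)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            delong_test([1.0, 2.0], [1.0, 2.0], [1, 1])


class TestMcNemar:
    def test_exact_binomial_oracle(self):
        # b=15, c=3 -> two-sided exact binomial p = 0.0075...
        truth = np.zeros(60, dtype=int)
        calls_a = truth.copy()
        calls_b = truth.copy()
        calls_b[:15] = 1                 # only A right on 15
        calls_a[15:18] = 1               # only B right on 3
        p = mcnemar_bonferroni(calls_a, calls_b, truth)
        k, n = 3, 18
        exact = 2 * sum(stats.binom.pmf(i, n, 0.5) for i in range(k + 1))
        assert p == pytest.approx(exact, rel=1e-9)
        assert p == pytest.approx(0.0075, abs=5e-4)

    def test_identical_calls(self):
        truth = np.array([0, 1, 0, 1])
        calls = np.array([0, 1, 1, 1])
        assert mcnemar_bonferroni(calls, calls, truth) == 1.0

    def test_bonferroni_truncates_at_one(self):
        truth = np.zeros(30, dtype=int)
        calls_a = truth.copy()
        calls_b = truth.copy()
        calls_a[:5] = 1
        calls_b[5:9] = 1
        p1 = mcnemar_bonferroni(calls_a, calls_b, truth, m_comparisons=1)
        p9 = mcnemar_bonferroni(calls_a, calls_b, truth, m_comparisons=9)
        assert p9 == min(1.0, 9 * p1)
        assert mcnemar_bonferroni(calls_a, calls_b, truth,
                                  m_comparisons=1000) == 1.0

    def test_chi2_branch_above_cut(self):
        truth = np.zeros(100, dtype=int)
        calls_a = truth.copy()
        calls_b = truth.copy()
        calls_a[:20] = 1                 # A wrong on 20 -> c
        calls_b[20:30] = 1               # B wrong on 10 -> b
        p = mcnemar_bonferroni(calls_a, calls_b, truth)
        res = stats.chi2.sf((abs(20 - 10) - 1) ** 2 / 30, 1)
        assert p == pytest.approx(res, rel=1e-9)

    def test_zero_discordance(self):
        truth = np.array([0, 1, 0, 1])
        assert mcnemar_bonferroni(truth, truth, truth) == 1.0


def _tree_builder(whitelist, min_cases=5):
    def build(train_df, seed):
        feats = [c for c in train_df.columns if c != LABEL]
        return train_tree(train_df[feats], train_df[LABEL].to_numpy(int),
                          whitelist, TrainConfig(min_cases=min_cases,
                                                 seed=seed))
    return build


class TestCrossValidate:
    def test_separable_high_accuracy(self):
        df = make_feature_table(200, {"driver": 5.0}, noise_features=3,
                                seed=4)
        out = crossvalidate(df, _tree_builder(["driver"]), k=10, seed=4)
        assert out["pooled"].accuracy >= 0.95
        assert out["pooled"].auc >= 0.95

    def test_fold_sizes_balanced(self):
        df = make_feature_table(103, {"driver": 2.0}, seed=5)
        out = crossvalidate(df, _tree_builder(["driver"]), k=10, seed=5)
        sizes = out["per_fold"]["n"]
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 103

    def test_null_auc_near_half(self):
        aucs = []
        for seed in range(10):
            df = make_feature_table(120, {"driver": 0.0}, noise_features=2,
                                    seed=seed)
            out = crossvalidate(df, _tree_builder(["driver"]), k=5,
                                seed=seed)
            aucs.append(out["pooled"].auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_k_bounds(self):
        df = make_feature_table(50, {"driver": 1.0}, seed=6)
        with pytest.raises(ValueError, match="k"):
            crossvalidate(df, _tree_builder(["driver"]), k=1)
        with pytest.raises(ValueError, match="minority"):
            crossvalidate(df, _tree_builder(["driver"]), k=45)


class TestCcr:
    def test_paper_stratum(self):
        calls = np.r_[np.ones(34), np.zeros(7)]
        truth = np.ones(41)
        table = ccr_table(calls, truth, ["normal"] * 41)
        row = table.iloc[0]
        assert row["n"] == 41 and row["correct"] == 34
        assert row["ccr_pct"] == pytest.approx(82.9, abs=0.05)

    def test_all_correct(self):
        table = ccr_table([1, 0, 1], [1, 0, 1], ["a", "a", "b"])
        assert (table["ccr_pct"] == 100.0).all()

    def test_weighted_conservation(self):
        rng = np.random.default_rng(7)
        n = 200
        calls = rng.integers(0, 2, n)
        truth = rng.integers(0, 2, n)
        strata = rng.choice(["a", "b", "c"], n)
        table = ccr_table(calls, truth, strata)
        overall = (table["correct"].sum()) / n
        assert overall == pytest.approx((calls == truth).mean())


class TestPower:
    def test_paper_value(self):
        assert power_two_proportions(0.30, 0.40, 0.05, 0.80) == 178

    def test_doubling_h_quarters_n(self):
        h = 2 * np.arcsin(np.sqrt(0.40)) - 2 * np.arcsin(np.sqrt(0.30))
        p2 = np.sin((2 * np.arcsin(np.sqrt(0.30)) + 2 * h) / 2) ** 2
        n1 = power_two_proportions(0.30, 0.40)
        n2 = power_two_proportions(0.30, float(p2))
        assert abs(n2 - n1 / 4) <= 1

    def test_tiny_effect_no_overflow(self):
        n = power_two_proportions(0.5, 0.5001)
        assert n > 1e6
        assert np.isfinite(n)

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError):
            power_two_proportions(0.3, 0.3)
        with pytest.raises(ValueError):
            power_two_proportions(0.0, 0.5)
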