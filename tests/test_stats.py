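import itertools

import numpy as np
import pytest
from scipy.special import logit as sp_logit

from mmar.stats import (
    _delong_components,
    categorical_nri,
    chi_squared,
    delong_compare,
    logistic_fit,
    mann_whitney_u,
    pearson_r,
    reclassification,
    roc_auc,
    summarize_group,
    youden_cutoff,
)


# ---------------------------------------------------------------- correlation
class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = pearson_r(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert r == pytest.approx(oracle, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------- group tests
class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, _ = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    def test_identical_multisets_give_half_product(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, _ = mann_whitney_u(a, list(a))
        assert u == len(a) ** 2 / 2

    def test_small_sample_p_equals_permutation_enumeration(self):
        a = np.array([1.3, 2.9, 3.1, 7.2])
        b = np.array([0.5, 2.0, 4.1, 5.0])
        u_obs, p = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        n = len(a)
        us = []
        for idx in itertools.combinations(range(len(pooled)), n):
            ga = pooled[list(idx)]
            gb = np.delete(pooled, list(idx))
            us.append((ga[:, None] > gb[None, :]).sum())
        us = np.array(us)
        # two-sided: deviation from the null mean at least as extreme
        dev = abs(u_obs - n * n / 2)
        oracle = (np.abs(us - n * n / 2) >= dev - 1e-9).mean()
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestChiSquared:
    def test_exact_independence_gives_zero(self):
        table = np.outer([30, 70], [0.2, 0.3, 0.5]) * 1.0
        stat, p = chi_squared(table)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_2x2_closed_form(self):
        stat, _ = chi_squared([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)

    def test_random_2x3_matches_hand_computed_expecteds(self):
        table = np.array([[12.0, 5.0, 9.0], [7.0, 11.0, 4.0]])
        stat, _ = chi_squared(table)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert stat == pytest.approx(((table - exp) ** 2 / exp).sum(), rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [3, 4]])


class TestSummarizeGroup:
    def test_median_and_quartiles_one_to_nine(self):
        s = summarize_group(np.arange(1.0, 10.0), np.arange(9) < 4)
        assert s["all"]["median"] == 5.0
        assert (s["all"]["q1"], s["all"]["q3"]) == (3.0, 7.0)

    def test_identical_groups_p_near_one(self):
        v = np.r_[np.arange(6.0), np.arange(6.0)]
        g = np.r_[np.ones(6), np.zeros(6)].astype(bool)
        assert summarize_group(v, g)["p_value"] == pytest.approx(1.0)

    def test_seven_point_type7_quartiles(self):
        # linear interpolation between order statistics on 1..7
        s = summarize_group(np.arange(1.0, 8.0), np.arange(7) < 3)
        assert (s["all"]["q1"], s["all"]["median"], s["all"]["q3"]) == (2.5, 4.0, 5.5)


# ------------------------------------------------------------------------ ROC
def auc_pair_counting_oracle(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r = roc_auc([1, 2, 3, 10, 11], np.array([0, 0, 0, 1, 1], bool))
        assert r.auc == 1.0 and r.ci_low == r.ci_high == 1.0

    def test_all_ties_give_half(self):
        r = roc_auc(np.ones(8), np.arange(8) < 3)
        assert r.auc == 0.5

    def test_four_point_example(self):
        scores = np.array([0.2, 0.9, 0.4, 0.8])
        labels = np.array([0, 1, 1, 0], bool)
        r = roc_auc(scores, labels)
        assert r.auc == 0.75
        assert r.auc == auc_pair_counting_oracle(scores, labels)

    def test_auc_equals_mann_whitney_scaling_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(8, 60))
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            r = roc_auc(scores, labels)
            u, _ = mann_whitney_u(scores[labels], scores[~labels])
            assert r.auc == pytest.approx(u / (labels.sum() * (~labels).sum()), abs=1e-12)

    def test_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_ci_shrinks_with_sample_size(self):
        rng = np.random.default_rng(9)
        widths = []
        for n in (40, 160, 640):
            pos = rng.normal(1, 1, n)
            neg = rng.normal(0, 1, n)
            r = roc_auc(np.r_[pos, neg], np.r_[np.ones(n), np.zeros(n)].astype(bool))
            widths.append(r.ci_high - r.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], np.ones(3, bool))


class TestDelongCompare:
    def test_identical_classifiers(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=40)
        y = rng.random(40) < 0.5
        a, b, z, p = delong_compare(s, s, y)
        assert a == b and z == 0.0 and p == 1.0

    def test_single_auc_variance_consistency(self):
        rng = np.random.default_rng(21)
        s = rng.normal(size=60)
        y = rng.random(60) < 0.45
        r = roc_auc(s, y)
        v10, v01 = _delong_components(s, y)
        var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
        assert r.var == pytest.approx(var, rel=1e-12)

    def test_variance_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(33)
        n = 40
        pos = rng.normal(0.8, 1, n)
        neg = rng.normal(0, 1, n)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(n), np.zeros(n)].astype(bool)
        r = roc_auc(scores, labels)
        boots = []
        for _ in range(2000):
            bi = rng.integers(0, n, n)
            bj = rng.integers(0, n, n)
            bs = np.r_[pos[bi], neg[bj]]
            boots.append(roc_auc(bs, labels).auc)
        assert np.sqrt(r.var) == pytest.approx(np.std(boots, ddof=1), rel=0.15)


class TestYoudenCutoff:
    def test_perfect_separation_metrics(self):
        with pytest.warns(UserWarning):
            r = roc_auc([1, 2, 8, 9], np.array([0, 0, 1, 1], bool))
        cut = youden_cutoff(r)
        assert cut.sensitivity == 1.0 and cut.specificity == 1.0
        assert 2 < cut.cutoff <= 8

    def test_all_ties_zero_youden(self):
        r = roc_auc(np.ones(6), np.arange(6) < 2)
        assert youden_cutoff(r).youden == 0.0

    def test_matches_exhaustive_scan_oracle(self):
        scores = np.array([0.1, 0.3, 0.35, 0.4, 0.55, 0.6, 0.8, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 1, 0, 1], bool)
        r = roc_auc(scores, labels)
        cut = youden_cutoff(r)
        best_j, best_t = -np.inf, None
        for t in sorted(np.unique(scores)):  # ties -> lowest cutoff wins
            sens = (scores[labels] >= t).mean()
            spec = (scores[~labels] < t).mean()
            if sens + spec - 1 > best_j + 1e-12:
                best_j, best_t = sens + spec - 1, t
        assert cut.cutoff == best_t
        assert cut.youden == pytest.approx(best_j)

    def test_ppv_npv_consistent_with_2x2(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        cut = youden_cutoff(roc_auc(scores, labels))
        pred = scores >= cut.cutoff
        tp, fp = (pred & labels).sum(), (pred & ~labels).sum()
        tn, fn = (~pred & ~labels).sum(), (~pred & labels).sum()
        assert cut.ppv == pytest.approx(tp / (tp + fp))
        assert cut.npv == pytest.approx(tn / (tn + fn))


# --------------------------------------------------------------- risk models
class TestLogisticFit:
    def test_null_model_recovers_prevalence(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        y = (rng.random(400) < 0.3).astype(float)
        fit = logistic_fit(x[:, None], y)
        assert fit.coef[1] == pytest.approx(0.0, abs=0.25)
        assert fit.coef[0] == pytest.approx(sp_logit(y.mean()), abs=0.25)

    def test_binary_predictor_equals_log_odds_ratio(self):
        # 2x2 table: exposed 30/70 events, unexposed 10/90
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        fit = logistic_fit(x[:, None], y)
        oracle = np.log((30 * 90) / (70 * 10))
        assert fit.coef[1] == pytest.approx(oracle, rel=1e-6)

    def test_fitted_probabilities_average_to_prevalence(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(200, 2))
        y = (rng.random(200) < 1 / (1 + np.exp(-(x[:, 0] - 0.3)))).astype(float)
        fit = logistic_fit(x, y)
        assert fit.fitted.mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_separation_flagged_not_raised(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        with pytest.warns(UserWarning, match="separation"):
            fit = logistic_fit(x[:, None], y)
        assert fit.separation


class TestReclassification:
    def test_identical_models_are_null(self):
        rng = np.random.default_rng(8)
        p = rng.random(30)
        y = rng.random(30) < 0.5
        rec = reclassification(p, p, y)
        assert rec.nri == 0.0 and rec.idi == 0.0

    def test_perfect_extension_hits_extremes(self):
        y = np.array([1, 1, 1, 0, 0, 0], bool)
        base = np.full(6, 0.5)
        ext = y.astype(float)
        rec = reclassification(base, ext, y)
        assert rec.nri == 2.0 and rec.idi == 1.0

    def test_six_subject_enumeration_oracle(self):
        y = np.array([1, 1, 1, 0, 0, 0], bool)
        base = np.array([0.6, 0.4, 0.5, 0.5, 0.3, 0.6])
        ext = np.array([0.7, 0.3, 0.6, 0.4, 0.35, 0.6])
        rec = reclassification(base, ext, y)
        # events: up, down, up -> (2-1)/3; non-events: down, up, same -> 0/3
        assert rec.nri == pytest.approx((2 - 1) / 3 + (1 - 1) / 3)
        idi_oracle = (np.mean(ext[y]) - np.mean(ext[~y])) - (
            np.mean(base[y]) - np.mean(base[~y])
        )
        assert rec.idi == pytest.approx(idi_oracle, rel=1e-12)

    def test_idi_equals_discrimination_slope_difference(self):
        rng = np.random.default_rng(10)
        y = rng.random(100) < 0.4
        base, ext = rng.random(100), rng.random(100)
        rec = reclassification(base, ext, y)
        slope = lambda p: p[y].mean() - p[~y].mean()
        assert rec.idi == pytest.approx(slope(ext) - slope(base), rel=1e-12)

    def test_categorical_nri_with_thresholds(self):
        y = np.array([1, 1, 0, 0], bool)
        base = np.array([0.1, 0.25, 0.25, 0.4])
        ext = np.array([0.35, 0.25, 0.1, 0.2])
        # 0.3 edge: one event crosses up, one non-event crosses down, rest stay
        assert categorical_nri(base, ext, y, [0.3]) == pytest.approx(0.5 + 0.5)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            reclassification([0.5], [0.5, 0.4], np.array([1, 0], bool))
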