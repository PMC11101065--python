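"""ROC/AUC, bootstrap CI, Hosmer-Lemeshow, calibration, decision curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chromopath.evaluation import (
    bootstrap_auc_ci,
    calibration_curve,
    decision_curve,
    gaussian_linear_score_auc,
    hosmer_lemeshow,
    roc_auc,
)


def brute_force_auc(scores, labels):
    """Exhaustive pair-counting oracle: (#pos>neg + 0.5 #ties) / (npos nneg)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_auc_one(self):
        y = np.r_[np.zeros(5), np.ones(5)]
        s = np.r_[np.arange(5), np.arange(10, 15)]
        assert roc_auc(s, y).auc == 1.0

    def test_all_ties_auc_half(self):
        y = np.r_[np.zeros(5), np.ones(5)]
        assert roc_auc(np.ones(10), y).auc == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        # coarse scores force ties
        s = rng.integers(0, 8, size=n).astype(float)
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        res = roc_auc(s, y)
        assert res.auc == pytest.approx(brute_force_auc(s, y), abs=1e-13)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=60),
        st.integers(0, 2**31 - 1),
    )
    def test_auc_property_oracle_and_monotone_invariance(self, raw, seed):
        """For arbitrary tied integer scores with both classes present,
        AUC equals the pair-counting oracle and survives a strictly
        increasing transform."""
        s = np.array(raw, dtype=float)
        y = np.random.default_rng(seed).integers(0, 2, size=len(s))
        y[0], y[1] = 0, 1
        res = roc_auc(s, y)
        assert res.auc == pytest.approx(brute_force_auc(s, y), abs=1e-13)
        assert roc_auc(2.0 * s + 1.0, y).auc == res.auc

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        base = roc_auc(s, y).auc
        assert roc_auc(np.exp(s), y).auc == base
        assert roc_auc(3 * s - 7, y).auc == base

    def test_trapezoid_area_equals_mann_whitney(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 150))
            s = np.round(rng.normal(size=n), 1)  # with ties
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            res = roc_auc(s, y)
            assert abs(res.trapezoid_auc() - res.auc) < 1e-12

    def test_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        s = rng.normal(size=300)
        y = rng.integers(0, 2, size=300)
        y[:2] = [0, 1]
        assert roc_auc(s, y).auc == pytest.approx(
            sklearn_metrics.roc_auc_score(y, s), abs=1e-12
        )

    def test_curve_endpoints_and_monotonicity(self, rng):
        s = rng.normal(size=80)
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        res = roc_auc(s, y)
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(4.0), np.ones(4))


class TestBootstrapCI:
    def test_deterministic_given_seed(self, rng):
        s = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        a = bootstrap_auc_ci(s, y, n_boot=2, seed=3)
        b = bootstrap_auc_ci(s, y, n_boot=2, seed=3)
        assert a == b

    def test_separated_large_sample_lower_bound(self):
        y = np.r_[np.zeros(400), np.ones(400)]
        s = np.r_[np.random.default_rng(0).normal(0, 1, 400),
                  np.random.default_rng(1).normal(10, 1, 400)]
        lo, hi = bootstrap_auc_ci(s, y, n_boot=200, seed=5)
        assert lo >= 0.99 and hi == 1.0

    def test_approximate_coverage_of_true_auc(self):
        """Percentile bootstrap CIs cover the true (closed-form) AUC in
        roughly 95% of repeated experiments; assert >= 90% over 200 runs
        (binomial slack) at n=500, B=300."""
        true_auc = float(stats.norm.cdf(1.0 / np.sqrt(2.0)))
        rng = np.random.default_rng(99)
        hits = 0
        for i in range(200):
            y = np.r_[np.zeros(250), np.ones(250)]
            s = np.r_[rng.normal(0, 1, 250), rng.normal(1, 1, 250)]
            lo, hi = bootstrap_auc_ci(s, y, n_boot=300, seed=1000 + i)
            hits += lo <= true_auc <= hi
        assert hits / 200 >= 0.90

    def test_ci_brackets_point_estimate(self, rng):
        s = rng.normal(size=200) + np.r_[np.zeros(100), np.ones(100)]
        y = np.r_[np.zeros(100), np.ones(100)]
        point = roc_auc(s, y).auc
        lo, hi = bootstrap_auc_ci(s, y, n_boot=500, seed=2)
        assert lo <= point <= hi


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups_give_zero_chi2(self):
        # 9 risk groups, each with predicted p = k/10 and exactly k events
        probs, labels = [], []
        for k in range(1, 10):
            probs += [k / 10] * 10
            labels += [1] * k + [0] * (10 - k)
        res = hosmer_lemeshow(np.array(probs), np.array(labels), g=10)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_decile_grouping_gives_df_8(self, rng):
        p = rng.uniform(0.05, 0.95, size=500)
        y = (rng.random(500) < p).astype(int)
        res = hosmer_lemeshow(p, y, g=10)
        assert res.n_groups == 10 and res.df == 8
        assert res.table["n"].sum() == 500

    def test_matches_hand_computed_oe_table(self):
        """30 distinct probabilities, g=3: groups are the sorted tenths; the
        chi-square is recomputed here by direct O/E arithmetic."""
        rng = np.random.default_rng(7)
        p = np.sort(rng.uniform(0.1, 0.9, 30))
        y = (rng.random(30) < p).astype(int)
        res = hosmer_lemeshow(p, y, g=3)
        chi2 = 0.0
        for k in range(3):
            sl = slice(10 * k, 10 * (k + 1))
            e1 = p[sl].sum()
            o1 = y[sl].sum()
            e0 = 10 - e1
            o0 = 10 - o1
            chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        assert res.chi2 == pytest.approx(chi2, rel=1e-12)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)

    def test_row_order_invariance(self, rng):
        p = rng.uniform(0.05, 0.95, 100)
        y = (rng.random(100) < p).astype(int)
        res1 = hosmer_lemeshow(p, y)
        perm = rng.permutation(100)
        res2 = hosmer_lemeshow(p[perm], y[perm])
        assert res1.chi2 == pytest.approx(res2.chi2, rel=1e-12)

    def test_tied_probabilities_stay_together(self):
        p = np.r_[np.full(50, 0.3), np.full(50, 0.7)]
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        res = hosmer_lemeshow(p, y, g=10)
        assert res.n_groups == 2

    def test_probability_domain_enforced(self):
        with pytest.raises(ValueError, match="strictly"):
            hosmer_lemeshow(np.r_[np.zeros(5), np.full(6, 0.5)],
                            np.r_[np.zeros(5), np.ones(6)].astype(int))


class TestCalibrationCurve:
    def test_calibrated_simulation_hugs_diagonal(self):
        """With labels ~ Bernoulli(p), every decile point sits within the
        +/-0.02 binomial-error band of the diagonal at n=100,000."""
        rng = np.random.default_rng(17)
        p = rng.uniform(0.02, 0.98, size=100_000)
        y = (rng.random(100_000) < p).astype(int)
        cal = calibration_curve(p, y, bins=10)
        assert np.all(np.abs(cal["mean_pred"] - cal["frac_obs"]) < 0.02)

    def test_constant_probs_single_bin(self):
        p = np.full(40, 0.25)
        y = np.r_[np.ones(10), np.zeros(30)].astype(int)
        cal = calibration_curve(p, y)
        assert len(cal) == 1
        assert cal["frac_obs"].iloc[0] == 0.25

    def test_degenerate_perfect_probs(self):
        p = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        cal = calibration_curve(p, y)
        pts = set(zip(cal["mean_pred"], cal["frac_obs"]))
        assert pts == {(0.0, 0.0), (1.0, 1.0)}


class TestDecisionCurve:
    def test_perfect_predictor_net_benefit_is_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)].astype(int)
        p = y.astype(float)
        dca = decision_curve(p, y)
        assert np.allclose(dca["nb_model"], 0.3)

    def test_treat_all_crosses_zero_at_prevalence(self):
        y = np.r_[np.ones(20), np.zeros(80)].astype(int)
        p = np.clip(y * 0.9 + 0.05, 0.05, 0.95)
        dca = decision_curve(p, y, thresholds=np.array([0.1, 0.2, 0.3]))
        at_prev = dca.loc[dca["threshold"] == 0.2, "nb_all"].iloc[0]
        assert at_prev == pytest.approx(0.0, abs=1e-15)
        assert dca.loc[dca["threshold"] == 0.1, "nb_all"].iloc[0] > 0
        assert dca.loc[dca["threshold"] == 0.3, "nb_all"].iloc[0] < 0
        assert (dca["nb_none"] == 0).all()

    def test_hand_worked_ten_rows(self):
        """10 rows: 4 events with probs .9,.8,.7,.2; 6 non-events with
        probs .6,.5,.4,.3,.2,.1 — NB checked at p_t = 0.25 and 0.65."""
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        dca = decision_curve(p, y, thresholds=np.array([0.25, 0.65]))
        # p_t=0.25: calls p>=0.25 -> TP=3, FP=4; NB = 0.3 - 0.4*(25/75)
        nb_25 = 3 / 10 - (4 / 10) * (0.25 / 0.75)
        # p_t=0.65: TP=3 (.9,.8,.7), FP=0; NB = 0.3
        assert dca["nb_model"].iloc[0] == pytest.approx(nb_25, rel=1e-12)
        assert dca["nb_model"].iloc[1] == pytest.approx(0.3, rel=1e-12)

    def test_model_beats_extremes_somewhere_when_informative(self, rng):
        p = rng.uniform(0.02, 0.98, 5000)
        y = (rng.random(5000) < p).astype(int)
        dca = decision_curve(p, y)
        gain = dca["nb_model"] - np.maximum(dca["nb_all"], 0.0)
        assert (gain > 0).any()
        # at vanishing threshold the model approaches treat-all
        first = dca.iloc[0]
        assert abs(first["nb_model"] - first["nb_all"]) < 0.01

    def test_bootstrap_band_brackets_curve(self, rng):
        p = rng.uniform(0.05, 0.95, 300)
        y = (rng.random(300) < p).astype(int)
        dca = decision_curve(p, y, thresholds=np.array([0.2, 0.5]),
                             n_boot=200, seed=8)
        assert (dca["nb_model_lo"] <= dca["nb_model"] + 1e-12).all()
        assert (dca["nb_model_hi"] >= dca["nb_model"] - 1e-12).all()

    def test_threshold_domain(self):
        y = np.r_[np.ones(5), np.zeros(5)].astype(int)
        with pytest.raises(ValueError, match="strictly"):
            decision_curve(y.astype(float), y, thresholds=np.array([0.0, 0.5]))


class TestGaussianClosedForm:
    def test_matches_monte_carlo(self, rng):
        beta = np.array([1.0, -0.5])
        m1, s1 = np.array([1.0, 0.0]), np.array([1.0, 2.0])
        m0, s0 = np.array([0.0, 0.5]), np.array([1.5, 1.0])
        closed = gaussian_linear_score_auc(beta, m1, s1, m0, s0)
        n = 60_000
        x1 = rng.normal(m1, s1, size=(n, 2)) @ beta
        x0 = rng.normal(m0, s0, size=(n, 2)) @ beta
        s = np.r_[x1, x0]
        y = np.r_[np.ones(n), np.zeros(n)]
        assert roc_auc(s, y).auc == pytest.approx(closed, abs=0.005)
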