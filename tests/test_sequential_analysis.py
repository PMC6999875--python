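import numpy as np
import pandas as pd
import pytest
from scipy import stats

from interadapt.errors import DegenerateDataError, TooFewTrialsError
from interadapt.sequential_analysis import (
    GroupSplit,
    ccf_score_correlation,
    lagged_ccf,
    lasso_fit,
    prewhiten_gappy,
    prewhiten_pair,
    score_model_design,
    sequential_effect,
    split_groups,
    variance_ratio_test,
)


class TestGroupSplit:
    def test_mean_threshold(self):
        split = split_groups({"a": 1.0, "b": 1.0, "c": 1.0, "d": 5.0})
        assert split.high == ["d"]
        assert set(split.low) == {"a", "b", "c"}
        assert split.threshold == pytest.approx(2.0)

    def test_nine_below_mean_gives_9_8_split(self):
        # 9 subjects clustered low, 8 spread high, as in a 17-subject cohort
        vals = {f"s{i}": v for i, v in enumerate([1.0] * 9 + [9, 10, 11, 12, 13, 14, 15, 16])}
        split = split_groups(vals)
        assert len(split.low) == 9
        assert len(split.high) == 8

    def test_invariant_under_common_scaling(self):
        vals = {f"s{i}": v for i, v in enumerate([1.0, 2.0, 3.0, 10.0, 0.5])}
        s1 = split_groups(vals)
        s2 = split_groups({k: 7.3 * v for k, v in vals.items()})
        assert s1.labels == s2.labels

    def test_all_equal_raises(self):
        with pytest.raises(DegenerateDataError):
            split_groups({"a": 2.0, "b": 2.0, "c": 2.0, "d": 2.0})


class TestVarianceRatioTest:
    def test_identical_groups(self):
        x = np.arange(20.0)
        ratio, dof, p = variance_ratio_test(x, x)
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)
        assert dof == (19, 19)

    def test_elementwise_doubling_gives_ratio_four(self):
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 8.0])
        ratio, _, _ = variance_ratio_test(2.0 * a, a)
        assert ratio == pytest.approx(4.0, abs=1e-12)

    def test_power_matches_analytic_f_distribution(self):
        """Monte-Carlo rejection rate under a true variance ratio of 2.5
        matches the analytic power of the two-sided F-test within 3 points."""
        alpha = 0.001
        n = 60
        true_ratio = 2.5
        d = (n - 1, n - 1)
        c_lo = stats.f.ppf(alpha / 2, *d)
        c_hi = stats.f.ppf(1 - alpha / 2, *d)
        analytic = stats.f.sf(c_hi / true_ratio, *d) + stats.f.cdf(c_lo / true_ratio, *d)
        rng = np.random.default_rng(13)
        reject = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(0, np.sqrt(true_ratio), n)
            b = rng.normal(0, 1.0, n)
            _, _, p = variance_ratio_test(a, b)
            reject += p < alpha
        assert reject / reps == pytest.approx(analytic, abs=0.03)

    def test_zero_denominator_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            variance_ratio_test(np.arange(5.0), np.ones(5))


def _subject_frame(te, mv):
    return pd.DataFrame(
        {"trial_index": np.arange(1, len(te) + 1), "TE": te, "Mv": mv}
    )


def _two_group_split(subjects_low, subjects_high):
    labels = {s: "LOW" for s in subjects_low} | {s: "HIGH" for s in subjects_high}
    return GroupSplit(threshold=0.0, labels=labels)


class TestSequentialEffect:
    def test_planted_exact_slope_recovered(self):
        """dMv(t+1) = -15.9 TE(t) exactly -> slope -15.9 to machine precision."""
        rng = np.random.default_rng(0)
        te = rng.normal(0, 0.05, 60)
        mv = np.empty(60)
        mv[0] = 40.0
        for t in range(59):
            mv[t + 1] = mv[t] - 15.9 * te[t]
        split = _two_group_split([], ["A"])
        eff = sequential_effect({"A": _subject_frame(te, mv)}, split)
        assert eff.subject_slopes["A"] == pytest.approx(-15.9, abs=1e-9)
        assert eff.group_slope["HIGH"] == pytest.approx(-15.9, abs=1e-9)

    def test_no_correction_slope_ci_contains_zero(self):
        """When TE carries no information about speed changes the group slope
        is statistically indistinguishable from zero."""
        rng = np.random.default_rng(21)
        frames = {}
        for s in range(6):
            te = rng.normal(0, 0.05, 78)  # independent of Mv by construction
            mv = 40.0 + rng.normal(0, 1.5, 78)
            frames[f"S{s}"] = _subject_frame(te, mv)
        split = _two_group_split(list(frames), [])
        eff = sequential_effect(frames, split)
        assert abs(eff.group_slope["LOW"]) < 3 * eff.group_slope_se["LOW"]

    def test_planted_slope_distribution_recovered(self):
        rng = np.random.default_rng(3)
        true_mean = -12.0
        frames = {}
        high = []
        for s in range(10):
            slope = rng.normal(true_mean, 1.0)
            te = rng.normal(0, 0.05, 200)
            noise = rng.normal(0, 0.2, 200)
            mv = np.empty(200)
            mv[0] = 40.0
            for t in range(199):
                mv[t + 1] = mv[t] + slope * te[t] + noise[t]
            sid = f"S{s}"
            frames[sid] = _subject_frame(te, mv)
            high.append(sid)
        eff = sequential_effect(frames, _two_group_split([], high))
        assert eff.group_slope["HIGH"] == pytest.approx(true_mean, abs=1.5)

    def test_short_subjects_excluded_and_reported(self):
        rng = np.random.default_rng(4)
        frames = {
            "ok": _subject_frame(rng.normal(0, 0.05, 30), rng.normal(40, 2, 30)),
            "short": _subject_frame(rng.normal(0, 0.05, 5), rng.normal(40, 2, 5)),
        }
        eff = sequential_effect(frames, _two_group_split(["ok", "short"], []))
        assert eff.excluded_subjects == ["short"]
        assert "short" not in eff.subject_slopes

    def test_pairs_spanning_gap_skipped(self):
        """A missing trial breaks the consecutive-pair chain: the slope uses
        only adjacent trial indices."""
        te = np.array([0.1, 0.1, -0.2, 0.1, -0.1, 0.2, 0.0, 0.1, -0.1, 0.05, 0.0, 0.1])
        mv = 40.0 + np.cumsum(np.ones_like(te))
        frame = _subject_frame(te, mv)
        gapped = frame[frame["trial_index"] != 6].reset_index(drop=True)
        eff = sequential_effect({"A": gapped}, _two_group_split(["A"], []), min_pairs=5)
        # dMv is identically +1 on every used pair -> slope 0, intercept 1
        assert eff.subject_slopes["A"] == pytest.approx(0.0, abs=1e-9)
        assert eff.subject_intercepts["A"] == pytest.approx(1.0, abs=1e-9)


class TestPrewhiten:
    def test_white_noise_unchanged(self):
        rng = np.random.default_rng(7)
        te = rng.normal(0, 1, 200)
        mv = rng.normal(0, 1, 200)
        res = prewhiten_pair(te, mv)
        assert res.ar_order == 0
        np.testing.assert_array_equal(res.te, te)

    def test_ar1_autocorrelation_removed(self):
        """AR(1) with phi = 0.6: post-whitening lag-1 autocorrelation < 0.1."""
        rng = np.random.default_rng(8)
        n = 500
        te = np.empty(n)
        te[0] = 0.0
        eps = rng.normal(0, 1, n)
        for t in range(1, n):
            te[t] = 0.6 * te[t - 1] + eps[t]
        mv = rng.normal(0, 1, n)
        res = prewhiten_pair(te, mv)
        assert res.ar_order >= 1
        w = res.te
        r1 = np.corrcoef(w[:-1], w[1:])[0, 1]
        assert abs(r1) < 0.1

    def test_common_filter_preserves_contemporaneous_correlation(self):
        """When both series share the same AR structure, filtering both with
        one model keeps ccf(0) essentially unchanged."""
        rng = np.random.default_rng(9)
        n = 2000
        e1 = rng.normal(0, 1, n)
        e2 = 0.7 * e1 + np.sqrt(1 - 0.49) * rng.normal(0, 1, n)
        te = np.empty(n)
        mv = np.empty(n)
        te[0] = mv[0] = 0.0
        for t in range(1, n):
            te[t] = 0.6 * te[t - 1] + e1[t]
            mv[t] = 0.6 * mv[t - 1] + e2[t]
        before = np.corrcoef(te, mv)[0, 1]
        res = prewhiten_pair(te, mv)
        after = np.corrcoef(res.te, res.mv)[0, 1]
        assert after == pytest.approx(before, abs=0.1)

    def test_near_unit_root_falls_back_to_differencing(self):
        rng = np.random.default_rng(10)
        te = np.cumsum(rng.normal(0, 1, 300))  # random walk
        mv = rng.normal(0, 1, 300)
        res = prewhiten_pair(te, mv)
        assert res.differenced
        assert res.te.size == 299

    def test_too_short_series_raises(self):
        with pytest.raises(TooFewTrialsError):
            prewhiten_pair(np.zeros(20), np.zeros(20))

    def test_gappy_series_keeps_nan_at_gaps(self):
        rng = np.random.default_rng(11)
        te = rng.normal(0, 1, 120)
        mv = rng.normal(0, 1, 120)
        te[50] = np.nan
        mv[50] = np.nan
        res = prewhiten_gappy(te, mv)
        p = res.ar_order
        assert np.isnan(res.te[50])
        assert np.isnan(res.te[:p]).all() if p else True  # start-up samples dropped
        assert np.isfinite(res.te[p:50]).all()
        assert np.isfinite(res.te[51 + p :]).all()


class TestLaggedCcf:
    def test_perfect_anticorrelation_at_lag_one(self):
        rng = np.random.default_rng(12)
        te = rng.normal(0, 1, 200)
        mv = np.empty(200)
        mv[1:] = -te[:-1]
        mv[0] = 0.0
        prof = lagged_ccf(te, mv, n_boot=200, seed=0)
        assert prof.ccf[1] == pytest.approx(-1.0, abs=1e-12)

    def test_null_series_small_ccf_and_ci_coverage(self):
        """Independent white series: correlations are small and the bootstrap
        CIs cover zero at roughly their nominal rate."""
        covered = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            te = rng.normal(0, 1, 500)
            mv = rng.normal(0, 1, 500)
            prof = lagged_ccf(te, mv, n_boot=300, seed=seed)
            assert np.all(np.abs(prof.ccf) < 0.15)
            covered += int(prof.ci_low[1] <= 0.0 <= prof.ci_high[1])
        assert covered >= int(0.85 * n_seeds)

    def test_invariant_to_adding_constants(self):
        rng = np.random.default_rng(14)
        te = rng.normal(0, 1, 100)
        mv = rng.normal(0, 1, 100)
        p1 = lagged_ccf(te, mv, n_boot=50, seed=1)
        p2 = lagged_ccf(te + 5.0, mv - 11.0, n_boot=50, seed=1)
        np.testing.assert_allclose(p1.ccf, p2.ccf, atol=1e-12)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(15)
        te = rng.normal(0, 1, 300)
        mv = 0.5 * te + rng.normal(0, 1, 300)
        prof = lagged_ccf(te, mv, n_boot=500, seed=2)
        assert np.all(prof.ci_low <= prof.ccf)
        assert np.all(prof.ccf <= prof.ci_high)
        assert np.all(np.abs(prof.ccf) <= 1.0)

    def test_too_few_pairs_raises(self):
        with pytest.raises(TooFewTrialsError):
            lagged_ccf(np.zeros(10), np.zeros(10), n_boot=10, seed=0)


class TestCcfScoreCorrelation:
    def _profiles(self, ccf1_values):
        from interadapt.sequential_analysis import CcfProfile

        out = {}
        for i, v in enumerate(ccf1_values):
            ccf = np.array([0.1 + 0.01 * i, v, v / 2, v / 3])
            out[f"S{i}"] = CcfProfile(
                subject_id=f"S{i}", lags=(0, 1, 2, 3), ccf=ccf,
                ci_low=ccf - 0.2, ci_high=ccf + 0.2, ar_order_te=0,
                n_pairs=np.full(4, 70),
            )
        return out

    def test_planted_negative_relation_recovered(self):
        rng = np.random.default_rng(16)
        scores = {f"S{i}": float(s) for i, s in enumerate(rng.normal(0, 1.5, 12))}
        ccf1 = [-0.1 * scores[f"S{i}"] + rng.normal(0, 0.02) for i in range(12)]
        table = ccf_score_correlation(self._profiles(ccf1), scores)
        row = table[table["lag"] == 1].iloc[0]
        assert row["pearson_r"] < -0.5

    def test_constant_ccf_raises(self):
        scores = {f"S{i}": float(i) for i in range(6)}
        with pytest.raises(DegenerateDataError):
            ccf_score_correlation(self._profiles([0.3] * 6), scores)

    def test_too_few_subjects_raises(self):
        scores = {f"S{i}": float(i) for i in range(3)}
        with pytest.raises(TooFewTrialsError):
            ccf_score_correlation(self._profiles([0.1, 0.2, 0.3]), scores)


class TestLasso:
    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(0, 2, (80, 4)), columns=list("abcd"))
        y = 1.5 * X["a"] - 0.7 * X["c"] + rng.normal(0, 0.5, 80) + 3.0
        res = lasso_fit(X, y.to_numpy(), lam=0.0, n_boot=0)
        D = np.column_stack([np.ones(80), X.to_numpy()])
        ols, *_ = np.linalg.lstsq(D, y.to_numpy(), rcond=None)
        np.testing.assert_allclose(res.beta, ols[1:], atol=1e-8)
        np.testing.assert_allclose(res.intercept, ols[0], atol=1e-8)

    def test_orthonormal_design_soft_thresholding(self):
        """On a standardized orthogonal design each penalized coefficient is
        the OLS coefficient shrunk toward zero by lambda."""
        rng = np.random.default_rng(18)
        n, p = 64, 5
        M = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        Q, _ = np.linalg.qr(M)
        X = Q[:, 1:] * np.sqrt(n)  # zero mean, unit population SD, orthogonal
        beta_true = np.array([2.0, -0.5, 0.0, 1.2, -0.1])
        y = X @ beta_true + rng.normal(0, 0.3, n)
        lam = 0.6
        res = lasso_fit(X, y, lam=lam, n_boot=0)
        b_ols = X.T @ (y - y.mean()) / n
        expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
        np.testing.assert_allclose(res.beta, expected, atol=1e-6)

    def test_huge_lambda_zeroes_everything(self):
        rng = np.random.default_rng(19)
        X = rng.normal(0, 1, (50, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 0.1, 50)
        res = lasso_fit(X, y, lam=1e6, n_boot=0)
        np.testing.assert_array_equal(res.beta, 0.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            lasso_fit(np.ones((10, 2)) + np.eye(10, 2), np.ones(10), lam=-1.0)

    def test_zero_variance_predictor_rejected(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(DegenerateDataError):
            lasso_fit(X, np.arange(20.0), lam=0.1, n_boot=0)

    def test_bootstrap_ci_brackets_strong_effect(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame({"u": rng.normal(0, 1, 120), "v": rng.normal(0, 1, 120)})
        y = 4.0 * X["u"].to_numpy() + rng.normal(0, 0.5, 120)
        res = lasso_fit(X, y, lam=0.2, n_boot=200, seed=0)
        iu = res.predictors.index("u")
        assert res.ci_low[iu] > 2.0
        assert res.beta[iu] == pytest.approx(4.0, abs=0.5)

    def test_score_model_design_shapes(self):
        s2mv = {"A": 1.0, "B": 2.0, "C": 3.0}
        s2ma = {"A": 0.5, "B": 0.4, "C": 0.6}
        scores = {"A": -1.0, "B": 0.0, "C": 1.0}
        X, y = score_model_design(s2mv, s2ma, scores)
        assert list(X.columns) == ["sigma2_Mv", "sigma2_Ma", "sigma2_Mv:sigma2_Ma"]
        np.testing.assert_allclose(X["sigma2_Mv:sigma2_Ma"], X["sigma2_Mv"] * X["sigma2_Ma"])
        assert y.tolist() == [-1.0, 0.0, 1.0]
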