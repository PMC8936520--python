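import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from conftest import efron_log_partial_likelihood, km_oracle, logrank_oracle
from mir200.survival import (
    CoxResult,
    build_endpoint,
    cox_fit,
    dichotomize_hypoxia,
    holm_sidak_adjust,
    km_estimate,
    log_minus_log,
    logrank_test,
    optimal_cutoff_scan,
    stepwise_cox,
)


def _clinical(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "followup_months", "recurrence_site", "recurrence_months"],
    )


class TestBuildEndpoint:
    def test_site_event_and_other_site_censoring(self):
        clin = _clinical(
            [
                ("a", 40.0, "central", 12.0),
                ("b", 40.0, "distant", 12.0),
                ("c", 70.0, "", np.nan),
            ]
        )
        e = build_endpoint(clin, "central_control")
        assert tuple(e.loc[0, ["time", "event"]]) == (12.0, 1)
        # recurrence at another site censors the central endpoint at that time
        assert tuple(e.loc[1, ["time", "event"]]) == (12.0, 0)
        # follow-up beyond the horizon is truncated to 60 months
        assert tuple(e.loc[2, ["time", "event"]]) == (60.0, 0)

    def test_pfs_counts_any_site(self):
        clin = _clinical([("a", 40.0, "lateral", 9.0)])
        e = build_endpoint(clin, "pfs")
        assert tuple(e.loc[0, ["time", "event"]]) == (9.0, 1)

    def test_multi_site_recurrence(self):
        clin = _clinical([("a", 40.0, "central;distant", 9.0)])
        assert build_endpoint(clin, "central_control").loc[0, "event"] == 1
        assert build_endpoint(clin, "lateral_control").loc[0, "event"] == 0

    def test_unknown_site_rejected(self):
        clin = _clinical([("a", 40.0, "liver", 9.0)])
        with pytest.raises(ValueError, match="liver"):
            build_endpoint(clin, "pfs")

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError):
            build_endpoint(_clinical([]), "overall_survival")


class TestKaplanMeier:
    def test_all_censored_is_flat(self):
        e = pd.DataFrame({"time": [5.0, 10.0, 15.0], "event": [0, 0, 0]})
        curve = km_estimate(e)["all"]
        np.testing.assert_allclose(curve.survival, 1.0)

    def test_two_events_no_censoring(self):
        e = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        curve = km_estimate(e)["all"]
        s = dict(zip(curve.times, curve.survival))
        assert s[1.0] == pytest.approx(0.5)
        assert s[2.0] == pytest.approx(0.0)

    def test_matches_hand_product_limit(self, rng):
        time = rng.integers(1, 8, size=10).astype(float)
        event = rng.integers(0, 2, size=10)
        if event.sum() == 0:
            event[0] = 1
        e = pd.DataFrame({"time": time, "event": event})
        curve = km_estimate(e)["all"]
        lookup = dict(zip(curve.times, curve.survival))
        for tau, s_expected in km_oracle(time, event):
            assert lookup[tau] == pytest.approx(s_expected, abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self, rng):
        time = rng.integers(1, 20, size=30).astype(float)
        e = pd.DataFrame({"time": time, "event": 1})
        curve = km_estimate(e)["all"]
        for tau, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((time > tau).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_give_zero(self):
        e = pd.DataFrame({"time": [1.0, 2, 3, 1, 2, 3], "event": [1, 1, 0, 1, 1, 0]})
        g = pd.Series([0, 0, 0, 1, 1, 1])
        chi2, p = logrank_test(e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_sum_oracle(self, rng):
        time = rng.integers(1, 6, size=8).astype(float)
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        e = pd.DataFrame({"time": time, "event": event})
        chi2, _ = logrank_test(e, pd.Series(group))
        assert chi2 == pytest.approx(logrank_oracle(time, event, group), rel=1e-10)

    def test_null_type_one_error(self, rng):
        hits, reps = 0, 300
        time = rng.exponential(10, size=50)
        event = (rng.random(50) < 0.7).astype(int)
        e = pd.DataFrame({"time": time, "event": event})
        for _ in range(reps):
            g = pd.Series(rng.permutation(np.repeat([0, 1], 25)))
            _, p = logrank_test(e, g)
            hits += p < 0.05
        assert abs(hits / reps - 0.05) < 0.035

    def test_requires_events(self):
        e = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            logrank_test(e, pd.Series([0, 1]))


class TestCox:
    def test_matches_bruteforce_partial_likelihood_maximizer(self, rng):
        time = np.array([3.0, 5.0, 5.0, 7.0, 9.0, 11.0, 13.0, 15.0])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = rng.normal(size=8)
        e = pd.DataFrame({"time": time, "event": event})
        res = cox_fit(e, pd.DataFrame({"x": x}))[0]
        opt = minimize_scalar(
            lambda b: -efron_log_partial_likelihood(b, time, event, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-12},
        )
        assert res.coef == pytest.approx(opt.x, abs=1e-6)

    def test_binary_hazard_ratio_recovery(self, rng):
        n = 2000
        x = rng.integers(0, 2, size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2.0) * x)))
        event = (t < 40).astype(int)
        time = np.minimum(t, 40)
        res = cox_fit(pd.DataFrame({"time": time, "event": event}), pd.DataFrame({"x": x}))[0]
        assert res.hr == pytest.approx(2.0, abs=0.15)

    def test_score_test_at_zero_equals_logrank(self, rng):
        # untied data, binary covariate: U(0)^2 / I(0) equals the log-rank chi2
        time = rng.permutation(np.arange(1.0, 13.0))
        event = np.ones(12, int)
        group = np.repeat([0, 1], 6)
        h = 1e-5
        ll = [efron_log_partial_likelihood(b, time, event, group) for b in (-h, 0, h)]
        u = (ll[2] - ll[0]) / (2 * h)
        info = -(ll[2] - 2 * ll[1] + ll[0]) / h**2
        chi2, _ = logrank_test(
            pd.DataFrame({"time": time, "event": event}), pd.Series(group)
        )
        assert u**2 / info == pytest.approx(chi2, rel=1e-4)

    def test_constant_covariate_rejected(self):
        e = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0]})
        with pytest.raises(ValueError, match="variance"):
            cox_fit(e, pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    def test_ci_brackets_hr(self, rng):
        e = pd.DataFrame({"time": rng.exponential(5, 50), "event": 1})
        res = cox_fit(e, pd.DataFrame({"x": rng.normal(size=50)}))[0]
        assert res.ci_low <= res.hr <= res.ci_high

    def test_inconsistent_ci_rejected(self):
        with pytest.raises(ValueError):
            CoxResult("x", 0.0, 1.0, hr=1.0, ci_low=2.0, ci_high=3.0, p=0.5)


class TestStepwise:
    def _simulate(self, rng, n=200, strong_loghr=-0.9, n_noise=5):
        strong = rng.normal(size=n)
        noise = rng.normal(size=(n, n_noise))
        t = rng.exponential(1.0 / (0.02 * np.exp(strong_loghr * strong)))
        event = (t < 60).astype(int)
        cov = pd.DataFrame(noise, columns=[f"noise{i}" for i in range(n_noise)])
        cov["strong"] = strong
        return pd.DataFrame({"time": np.minimum(t, 60), "event": event}), cov

    def test_selects_planted_covariate(self, rng):
        hits = 0
        for _ in range(10):
            e, cov = self._simulate(rng)
            res = stepwise_cox(e, cov, direction="both")
            hits += "strong" in res["selected"]
        assert hits >= 9

    def test_screen_failure_returns_empty_model(self, rng):
        e = pd.DataFrame({"time": rng.exponential(5, 60), "event": 1})
        cov = pd.DataFrame({"a": rng.normal(size=60)})
        res = stepwise_cox(e, cov, screen_p=1e-9)
        assert res["selected"] == [] and "note" in res

    def test_forward_backward_agree_on_orthogonal_covariates(self, rng):
        e, cov = self._simulate(rng, n=300)
        res = stepwise_cox(e, cov, direction="both")
        assert res["agree"] is True


class TestCutoffScan:
    def _step_hazard_data(self, rng, n=200, quantile=0.3, hr=3.0):
        score = rng.normal(size=n)
        cut = np.quantile(score, quantile)
        lam = np.where(score <= cut, 0.03 * hr, 0.03)
        t = rng.exponential(1.0 / lam)
        event = (t < 60).astype(int)
        return pd.Series(score), pd.DataFrame({"time": np.minimum(t, 60), "event": event})

    def test_respects_min_group_fraction(self, rng):
        score, e = self._step_hazard_data(rng, n=100)
        res = optimal_cutoff_scan(score, e, min_group_fraction=0.10, correction="none")
        assert (res.scan["n_low"] >= 10).all()
        assert (100 - res.scan["n_low"] >= 10).all()

    def test_corrected_p_not_smaller(self, rng):
        score, e = self._step_hazard_data(rng)
        res = optimal_cutoff_scan(score, e, correction="permutation", n_permutations=100, seed=0)
        assert res.p_corrected >= res.p_uncorrected
        res2 = optimal_cutoff_scan(score, e, correction="min_p")
        assert res2.p_corrected >= res2.p_uncorrected

    def test_recovers_step_breakpoint(self, rng):
        score, e = self._step_hazard_data(rng, hr=4.0)
        res = optimal_cutoff_scan(score, e, correction="none")
        assert abs(res.fraction_low - 0.3) <= 0.05

    def test_group_sizes_sum_to_n(self, rng):
        score, e = self._step_hazard_data(rng)
        res = optimal_cutoff_scan(score, e, correction="none")
        assert res.n_low + res.n_high == len(score)

    def test_too_few_subjects_rejected(self, rng):
        score, e = self._step_hazard_data(rng)
        with pytest.raises(ValueError):
            optimal_cutoff_scan(score.iloc[:10], e.iloc[:10], correction="none")


class TestLogMinusLog:
    def test_exponential_survival_is_unit_slope_line(self):
        from mir200.survival import KMCurve

        t = np.linspace(1, 50, 30)
        lam = 0.05
        curve = KMCurve("g", t, np.exp(-lam * t), np.arange(30, 0, -1), np.array([]))
        pts, notes = log_minus_log(curve)
        slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert intercept == pytest.approx(np.log(lam), abs=1e-9)

    def test_proportional_hazards_constant_offset(self):
        from mir200.survival import KMCurve

        t = np.linspace(1, 50, 30)
        p1, _ = log_minus_log(KMCurve("a", t, np.exp(-0.05 * t), t, np.array([])))
        p2, _ = log_minus_log(KMCurve("b", t, np.exp(-0.10 * t), t, np.array([])))
        offsets = p2[:, 1] - p1[:, 1]
        np.testing.assert_allclose(offsets, np.log(2.0), atol=1e-9)

    def test_degenerate_curve_is_skipped_with_note(self):
        from mir200.survival import KMCurve

        curve = KMCurve("g", np.array([1.0, 2.0]), np.array([1.0, 1.0]), np.array([2.0, 1.0]), np.array([]))
        pts, notes = log_minus_log(curve)
        assert pts.shape[0] == 0 and notes


class TestAdjustAndDichotomize:
    def test_holm_sidak_hand_example(self):
        adj = holm_sidak_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2, abs=1e-12)
        assert adj[1] == pytest.approx(0.04, abs=1e-12)

    def test_single_p_unchanged(self):
        assert holm_sidak_adjust([0.3])[0] == pytest.approx(0.3)

    def test_monotone_and_not_below_raw(self, rng):
        p = rng.random(20)
        adj = holm_sidak_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak_adjust([0.5, 1.2])

    @pytest.mark.parametrize("score,expected", [(0.2, "more"), (-0.2, "less"), (0.0, "less")])
    def test_hypoxia_dichotomization(self, score, expected):
        assert dichotomize_hypoxia([score])[0] == expected
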