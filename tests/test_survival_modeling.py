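import math

import numpy as np
import pandas as pd
import pytest

import regulonsurv as rs
from regulonsurv.io_formats import SurvivalTable
from regulonsurv.survival_modeling import CoxConvergenceError


def cox_negative_log_partial_likelihood(beta, X, time, event, ties="efron"):
    """Independent oracle: the partial likelihood written from its definition."""
    beta = np.atleast_1d(np.asarray(beta, float))
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = np.flatnonzero((time == t) & (event == 1))
        R = np.flatnonzero(time >= t)
        d = len(D)
        ll += eta[D].sum()
        if ties == "breslow":
            ll -= d * math.log(w[R].sum())
        else:
            s0, t0 = w[R].sum(), w[D].sum()
            for l in range(d):
                ll -= math.log(s0 - (l / d) * t0)
    return -ll


def _optimize_oracle(X, time, event, ties="efron"):
    from scipy.optimize import minimize

    p = X.shape[1]
    res = minimize(cox_negative_log_partial_likelihood, np.zeros(p),
                   args=(X, time, event, ties), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x


class TestFitCox:
    def test_three_subject_analytic_maximum(self):
        # events at t=1,2,3 with x = 1,0,1: the partial likelihood is maximized
        # at beta = -ln(2)/2 (stationarity of e^b/((2e^b+1)(1+e^b)))
        surv = SurvivalTable(list("abc"), [1, 2, 3], [1, 1, 1])
        fit = rs.fit_cox(np.array([1.0, 0.0, 1.0]), surv)
        assert fit.coefficients[0] == pytest.approx(-math.log(2) / 2, abs=1e-6)

    def test_constant_covariate_rejected(self):
        surv = SurvivalTable(list("abc"), [1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="zero variance"):
            rs.fit_cox(np.array([2.0, 2.0, 2.0]), surv)

    def test_zero_events_rejected(self):
        surv = SurvivalTable(list("abc"), [1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            rs.fit_cox(np.array([1.0, 0.0, 1.0]), surv)

    def test_duplicating_subjects_preserves_beta_under_breslow(self):
        rng = np.random.default_rng(1)
        n = 25
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.5 * x))
        e = np.ones(n, dtype=int)
        surv = SurvivalTable([str(i) for i in range(n)], t, e)
        fit = rs.fit_cox(x, surv, ties="breslow")
        surv2 = SurvivalTable([str(i) for i in range(2 * n)], np.tile(t, 2), np.tile(e, 2))
        fit2 = rs.fit_cox(np.tile(x, 2), surv2, ties="breslow")
        assert fit2.coefficients[0] == pytest.approx(fit.coefficients[0], abs=1e-6)
        oracle = _optimize_oracle(np.tile(x, 2)[:, None], np.tile(t, 2), np.tile(e, 2),
                                  ties="breslow")
        assert fit2.coefficients[0] == pytest.approx(oracle[0], abs=1e-6)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_independent_optimizer_with_tied_times(self, ties):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n, p = 30, 2
            X = rng.normal(size=(n, p))
            t = np.round(rng.exponential(1 / np.exp(X @ [0.5, -0.3])), 1) + 0.1
            e = rng.integers(0, 2, n)
            e[:3] = 1
            surv = SurvivalTable([str(i) for i in range(n)], t, e)
            fit = rs.fit_cox(X, surv, ties=ties)
            np.testing.assert_allclose(
                fit.coefficients, _optimize_oracle(X, t, e, ties), atol=1e-6
            )

    def test_matches_lifelines_efron(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n, p = 60, 3
        X = rng.normal(size=(n, p))
        t = rng.exponential(1 / np.exp(X @ [0.4, 0.0, -0.6]))
        e = rng.integers(0, 2, n)
        e[:3] = 1
        surv = SurvivalTable([str(i) for i in range(n)], t, e)
        fit = rs.fit_cox(X, surv)
        df = pd.DataFrame(X, columns=list("abc")).assign(T=t, E=e)
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coefficients, cph.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(fit.standard_errors, cph.standard_errors_.to_numpy(),
                                   atol=1e-4)

    def test_complete_separation_raises_with_trace(self):
        # covariate perfectly orders the death times -> beta diverges
        surv = SurvivalTable([str(i) for i in range(6)],
                             [1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])
        x = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        with pytest.raises(CoxConvergenceError) as err:
            rs.fit_cox(x, surv, max_iterations=25)
        assert len(err.value.trace) > 1


class TestWaldCi:
    def test_reference_marker_row(self):
        # beta=-0.799, se=0.177 corresponds to HR 0.45 with 95% CI (0.32, 0.64)
        hr, lo, hi, p = rs.wald_ci(-0.799, 0.177)
        assert hr == pytest.approx(0.45, abs=0.005)
        assert lo == pytest.approx(0.32, abs=0.005)
        assert hi == pytest.approx(0.64, abs=0.005)
        assert p < 1e-4

    def test_null_beta(self):
        hr, lo, hi, p = rs.wald_ci(0.0, 0.3)
        assert hr == 1.0 and p == 1.0 and lo < 1.0 < hi

    def test_z_critical_boundary(self):
        from scipy.stats import norm

        z = norm.ppf(0.975)
        _, _, _, p = rs.wald_ci(z * 0.2, 0.2)
        assert p == pytest.approx(0.05, abs=1e-10)

    def test_non_positive_se_rejected(self):
        with pytest.raises(ValueError):
            rs.wald_ci(1.0, 0.0)


def _truth_as_activity(truth):
    """Latent activities rescaled linearly per regulator into [0, 1].

    The per-regulator linear map is absorbed by the z-scoring inside the
    survival fits, so Cox coefficients per SD are unchanged.
    """
    a = truth.true_activities
    lo, hi = a.min(axis=1, keepdims=True), a.max(axis=1, keepdims=True)
    return rs.ActivityMatrix(truth.regulators, truth.sample_ids, (a - lo) / (hi - lo))


class TestUnivariateScreen:
    def test_alpha_one_returns_every_fitted_regulator(self, small_activity, small_cohort):
        _, _, surv, _, _ = small_cohort
        results = rs.univariate_screen(small_activity, surv, alpha=1.0)
        assert len(results) == len(small_activity.regulators)
        assert all(r.ci_low <= r.hazard_ratio <= r.ci_high for r in results)
        ps = [r.wald_p for r in results]
        assert ps == sorted(ps)

    def test_planted_regulator_found_with_correct_sign(self):
        cfg = rs.CohortConfig(n_samples=500, n_genes=120, n_regulators=5, regulon_size=10,
                              prognostic_regulators=((2, 0.5),), seed=21)
        _, surv, _, truth = rs.generate_cohort(cfg)
        results = rs.univariate_screen(_truth_as_activity(truth), surv, alpha=0.05)
        found = {r.regulator: r for r in results}
        assert "TF003" in found
        assert found["TF003"].hazard_ratio > 1.0

    def test_invalid_alpha_rejected(self, small_activity, small_cohort):
        _, _, surv, _, _ = small_cohort
        with pytest.raises(ValueError):
            rs.univariate_screen(small_activity, surv, alpha=0.0)


class TestRiskModel:
    def test_single_regulator_model_equals_univariate_fit(self, small_activity, small_cohort):
        _, _, surv, _, _ = small_cohort
        results = rs.univariate_screen(small_activity, surv, alpha=1.0)
        top = results[0].regulator
        model = rs.fit_risk_model(small_activity, surv, [top])
        assert model.coefficients[0] == pytest.approx(results[0].coefficient, abs=1e-8)

    def test_missing_regulator_named_in_error(self, small_activity, small_cohort):
        _, _, surv, _, _ = small_cohort
        with pytest.raises(KeyError, match="GHOST"):
            rs.fit_risk_model(small_activity, surv, ["GHOST"])

    def test_json_round_trip(self, tmp_path, small_activity, small_cohort):
        _, _, surv, _, _ = small_cohort
        model = rs.fit_risk_model(small_activity, surv, small_activity.regulators[:2])
        path = tmp_path / "model.json"
        model.to_json(path)
        back = rs.RiskModel.from_json(path)
        assert back.regulators == model.regulators
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        np.testing.assert_allclose(back.means, model.means)
        np.testing.assert_allclose(back.sds, model.sds)


class TestComputeRiskScores:
    def _model(self, coefs, means=None, sds=None):
        k = len(coefs)
        return rs.RiskModel(
            regulators=[f"R{i}" for i in range(k)],
            coefficients=np.asarray(coefs, float),
            means=np.zeros(k) if means is None else np.asarray(means),
            sds=np.ones(k) if sds is None else np.asarray(sds),
        )

    def _act(self, rows):
        rows = np.asarray(rows, float)
        return rs.ActivityMatrix([f"R{i}" for i in range(rows.shape[0])],
                                 [f"s{j}" for j in range(rows.shape[1])], rows)

    def test_direct_formula(self):
        scores = rs.compute_risk_scores(self._model([0.5, -0.3]), self._act([[0.2], [0.4]]))
        assert scores["s0"] == pytest.approx(0.5 * 0.2 - 0.3 * 0.4)

    def test_zero_coefficients_give_zero_scores(self):
        scores = rs.compute_risk_scores(self._model([0.0, 0.0]), self._act([[0.1], [0.9]]))
        assert (scores == 0).all()

    def test_doubling_a_coefficient_doubles_its_contribution(self):
        act = self._act([[0.3, 0.8], [0.2, 0.6]])
        s1 = rs.compute_risk_scores(self._model([0.5, 0.0]), act)
        s2 = rs.compute_risk_scores(self._model([1.0, 0.0]), act)
        np.testing.assert_allclose(s2.to_numpy(), 2 * s1.to_numpy())

    def test_missing_model_regulator_rejected(self):
        act_single = rs.ActivityMatrix(["R0"], ["s0"], np.array([[0.1]]))
        with pytest.raises(KeyError, match="R1"):
            rs.compute_risk_scores(self._model([0.5, 0.5]), act_single)

    def test_standardization_frozen_at_training_values(self):
        model = self._model([1.0], means=[0.5], sds=[0.25])
        scores = rs.compute_risk_scores(model, self._act([[0.75]]))
        assert scores["s0"] == pytest.approx((0.75 - 0.5) / 0.25)


class TestAssignRiskGroups:
    def test_median_split(self):
        a = rs.assign_risk_groups(np.array([1.0, 2.0, 3.0, 4.0]))
        assert a.cutoff == 2.5
        assert a.group == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        a = rs.assign_risk_groups(np.array([1.0, 2.0, 2.0, 3.0]))
        assert a.cutoff == 2.0
        assert a.group == ["low", "low", "low", "high"]

    def test_explicit_cutoff(self):
        a = rs.assign_risk_groups(np.array([-1.0, 1.0]), cutoff=0.0)
        assert a.group == ["low", "high"]

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            rs.assign_risk_groups(np.array([2.0, 2.0, 2.0]))


class TestLogrankAndKm:
    def test_two_singleton_groups_hand_enumeration(self):
        # risk sets: at t=1 both alive, E_A = 0.5, V = 0.25 -> chi2 = 1
        surv = SurvivalTable(["a", "b"], [1, 2], [1, 1])
        chi_square, p = rs.logrank_test(np.array(["A", "B"]), surv)
        assert chi_square == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_label_swap_leaves_chi_square(self, small_cohort):
        _, _, surv, _, _ = small_cohort
        rng = np.random.default_rng(0)
        groups = np.where(rng.random(surv.n_samples) < 0.5, "x", "y")
        c1, _ = rs.logrank_test(groups, surv)
        swapped = np.where(groups == "x", "y", "x")
        c2, _ = rs.logrank_test(swapped, surv)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_identical_groups_give_zero_statistic(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        surv = SurvivalTable([str(i) for i in range(6)], t, e)
        chi_square, p = rs.logrank_test(np.array(["A"] * 3 + ["B"] * 3), surv)
        assert chi_square == pytest.approx(0.0, abs=1e-12)

    def test_single_group_rejected(self):
        surv = SurvivalTable(["a", "b"], [1, 2], [1, 1])
        with pytest.raises(ValueError, match="2 groups"):
            rs.logrank_test(np.array(["A", "A"]), surv)

    def test_km_product_limit_two_events(self):
        curve = rs.km_curve(SurvivalTable(["a", "b"], [1, 2], [1, 1]))
        assert curve.at(1) == pytest.approx(0.5)
        assert curve.at(2) == pytest.approx(0.0)

    def test_km_all_censored_stays_at_one(self):
        curve = rs.km_curve(SurvivalTable(list("abc"), [1, 2, 3], [0, 0, 0]))
        assert curve.at(3) == 1.0
        assert len(curve.censor_times) == 3

    def test_km_with_interleaved_censoring(self):
        # events at 1 and 3, censored at 2: S(1)=2/3; at t=3 the risk set is
        # a single subject, so S(3) = 2/3 * (1 - 1/1) = 0
        curve = rs.km_curve(SurvivalTable(list("abc"), [1, 2, 3], [1, 0, 1]))
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(3) == pytest.approx(0.0)


class TestRawScaleMode:
    def test_raw_mode_stores_identity_standardization(self, small_activity, small_cohort):
        _, _, surv, _, _ = small_cohort
        model = rs.fit_risk_model(small_activity, surv, small_activity.regulators[:2],
                                  standardize=False)
        np.testing.assert_array_equal(model.means, np.zeros(2))
        np.testing.assert_array_equal(model.sds, np.ones(2))

    def test_raw_coefficient_scales_with_activity_sd(self, small_activity, small_cohort):
        # beta_raw = beta_z / sd(activity) for a single covariate
        _, _, surv, _, _ = small_cohort
        reg = small_activity.regulators[0]
        z_model = rs.fit_risk_model(small_activity, surv, [reg])
        raw_model = rs.fit_risk_model(small_activity, surv, [reg], standardize=False)
        sd = small_activity.row(reg).std()
        assert raw_model.coefficients[0] * sd == pytest.approx(z_model.coefficients[0],
                                                               rel=1e-6)
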