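"""Actuarial rates, effective sample sizes, ML fits and ratio uncertainty."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from protonrbe.dose_response import (
    AnimalRecord,
    DoseGroup,
    actuarial_rate,
    bed50_alpha_beta,
    build_dose_groups,
    ed50,
    effective_sample,
    fieller_cl,
    fit_generalized,
    fit_logistic,
    generalized_probability,
    logistic_probability,
    slope_regression,
)
from protonrbe.lq import FractionSchedule, LQParams, bed


def _animal(i, dose, event, t, n_fx=6, excluded=False):
    return AnimalRecord(
        animal_id=f"a{i}", position_mm=35.0, let_d=1.4, n_fractions=n_fx,
        total_dose=dose, event=event, time_days=t, excluded=excluded,
    )


def _group(dose, n, rate, n_fx=6, variance=None):
    var = rate * (1 - rate) / n if variance is None else variance
    n_eff, r_eff = effective_sample(rate, var, n)
    return DoseGroup(
        total_dose=dose, fraction_dose=dose / n_fx, n_treated=n,
        actuarial_rate=rate, actuarial_variance=var,
        n_effective=n_eff, r_effective=r_eff,
    )


class TestResponseModels:
    def test_probability_is_half_at_ed50(self):
        assert logistic_probability(50.0, -10.0, 0.2) == pytest.approx(0.5)

    def test_logistic_hand_value_and_monotonicity(self):
        assert logistic_probability(0.0, -10.0, 0.2) == pytest.approx(4.54e-5, rel=1e-2)
        assert logistic_probability(60.0, -10.0, 0.2) > logistic_probability(50.0, -10.0, 0.2)

    def test_generalized_reduces_to_logistic_when_b2_zero(self):
        D = np.linspace(10, 80, 7)
        np.testing.assert_allclose(
            generalized_probability(D, D / 6, -10.0, 0.2, 0.0),
            logistic_probability(D, -10.0, 0.2),
        )

    def test_generalized_hand_value(self):
        # linear predictor -5 + 0.04*50 + 0.02*50*5 = 2
        assert generalized_probability(50.0, 5.0, -5.0, 0.04, 0.02) == pytest.approx(0.8808, abs=1e-4)

    @given(
        b1=st.floats(0.01, 1.0),
        b2=st.floats(0.001, 0.5),
        D=st.floats(1.0, 100.0),
        d=st.floats(0.1, 20.0),
    )
    def test_linear_predictor_equals_bed_form(self, b1, b2, D, d):
        # b1*D + b2*D*d == b1*BED with alpha/beta = b1/b2 (algebraic identity)
        lhs = b1 * D + b2 * D * d
        sched = FractionSchedule(D / d, d)
        rhs = b1 * bed(sched, LQParams(b1 / b2))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestActuarialRate:
    def test_complete_follow_up_reduces_to_binomial(self):
        recs = [_animal(i, 50, i < 3, 100 if i < 3 else 300) for i in range(5)]
        rate, var = actuarial_rate(recs)
        assert rate == pytest.approx(0.6)
        assert var == pytest.approx(0.6 * 0.4 / 5)

    def test_no_events_zero_variance(self):
        recs = [_animal(i, 50, False, 300) for i in range(5)]
        rate, var = actuarial_rate(recs)
        assert rate == 0.0 and var == 0.0

    def test_censored_group_matches_hand_product_limit(self):
        # events at 120 and 200 d, censor at 150 d, two alive at 300 d:
        # S(300) = (4/5)(2/3) = 8/15, Greenwood = S^2 (1/20 + 1/6)
        recs = [
            _animal(0, 50, True, 120),
            _animal(1, 50, True, 200),
            _animal(2, 50, False, 150),
            _animal(3, 50, False, 300),
            _animal(4, 50, False, 300),
        ]
        rate, var = actuarial_rate(recs)
        assert rate == pytest.approx(7 / 15, rel=1e-9)
        assert var == pytest.approx((8 / 15) ** 2 * (1 / 20 + 1 / 6), rel=1e-9)

    def test_excluded_animals_censored_or_dropped(self):
        recs = [_animal(i, 50, i == 0, 100 if i == 0 else 300) for i in range(4)]
        recs.append(_animal(9, 50, False, 80, excluded=True))
        rate_cens, _ = actuarial_rate(recs, excluded="censor")
        rate_drop, _ = actuarial_rate(recs, excluded="drop")
        assert rate_drop == pytest.approx(0.25)
        # censor policy: the excluded animal leaves the risk set at 80 d,
        # so KM gives 1 - 3/4, not the crude 1/5 over all five animals
        assert rate_cens == pytest.approx(0.25)
        assert rate_cens != pytest.approx(1 / 5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            actuarial_rate([])


class TestEffectiveSample:
    def test_formula_value(self):
        n_eff, r_eff = effective_sample(0.5, 0.025, 20)
        assert n_eff == pytest.approx(10.0)
        assert r_eff == pytest.approx(5.0)

    def test_complete_follow_up_no_correction(self):
        p, n = 0.4, 5
        n_eff, r_eff = effective_sample(p, p * (1 - p) / n, n)
        assert n_eff == pytest.approx(n)
        assert r_eff == pytest.approx(2.0)

    def test_degenerate_rates(self):
        assert effective_sample(0.0, 0.0, 5) == (5.0, 0.0)
        assert effective_sample(1.0, 0.0, 5) == (5.0, 5.0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            effective_sample(0.5, -1e-6, 5)

    @given(
        rate=st.floats(0.01, 0.99),
        var=st.floats(1e-6, 0.25),
        n=st.integers(1, 50),
    )
    def test_r_eff_never_exceeds_n_eff(self, rate, var, n):
        n_eff, r_eff = effective_sample(rate, var, n)
        assert r_eff <= n_eff + 1e-12
        assert n_eff <= n + 1e-12


class TestFitLogistic:
    def test_two_point_exact_solution(self):
        # two groups pin the logit line exactly: b1 = (logit .75 - logit .25)/10
        groups = [_group(40.0, 4, 0.25), _group(50.0, 4, 0.75)]
        fit = fit_logistic(groups)
        b1_expect = (math.log(3) - math.log(1 / 3)) / 10.0
        assert fit.b1 == pytest.approx(b1_expect, rel=1e-5)
        assert ed50(fit).value == pytest.approx(45.0, rel=1e-5)

    def test_duplicate_groups_equal_merged(self):
        a = [_group(40.0, 10, 0.3), _group(50.0, 10, 0.8)]
        b = [_group(40.0, 5, 0.3), _group(40.0, 5, 0.3), _group(50.0, 10, 0.8)]
        fa, fb = fit_logistic(a), fit_logistic(b)
        assert fa.b0 == pytest.approx(fb.b0, rel=1e-6)
        assert fa.b1 == pytest.approx(fb.b1, rel=1e-6)

    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(42)
        b0, b1 = -17.1, 1 / 3
        doses = np.array([42.0, 46.0, 50.0, 54.0, 58.0, 62.0])
        groups = []
        for D in doses:
            p = 1 / (1 + math.exp(-(b0 + b1 * D)))
            r = rng.binomial(30, p)
            groups.append(_group(D, 30, r / 30))
        fit = fit_logistic(groups)
        est = ed50(fit)
        assert fit.converged
        assert abs(est.value - 51.3) < 2 * est.se

    def test_matches_statsmodels_glm(self):
        # independent route: GLM binomial with variance weights
        import statsmodels.api as sm

        groups = [_group(40.0, 5, 0.2), _group(45.0, 5, 0.4),
                  _group(50.0, 5, 0.6), _group(55.0, 5, 1.0)]
        fit = fit_logistic(groups)
        y = [g.actuarial_rate for g in groups]
        X = sm.add_constant([g.total_dose for g in groups])
        w = [g.n_effective for g in groups]
        glm = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
        assert fit.b0 == pytest.approx(glm.params[0], rel=1e-4)
        assert fit.b1 == pytest.approx(glm.params[1], rel=1e-4)
        np.testing.assert_allclose(fit.covariance, glm.cov_params(), rtol=1e-3)

    def test_complete_separation_flagged_not_infinite(self):
        groups = [_group(40.0, 5, 0.0), _group(45.0, 5, 0.0),
                  _group(50.0, 5, 1.0), _group(55.0, 5, 1.0)]
        fit = fit_logistic(groups)
        assert fit.separation
        assert fit.method == "firth"
        assert np.isfinite(fit.b1)

    def test_dose_shift_shifts_ed50_exactly(self):
        groups = [_group(40.0, 10, 0.2), _group(46.0, 10, 0.5), _group(52.0, 10, 0.9)]
        shifted = [_group(g.total_dose + 7.0, 10, g.actuarial_rate) for g in groups]
        e0 = ed50(fit_logistic(groups)).value
        e1 = ed50(fit_logistic(shifted)).value
        assert e1 - e0 == pytest.approx(7.0, abs=1e-6)

    def test_single_dose_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([_group(50.0, 5, 0.4), _group(50.0, 5, 0.6)])


class TestEd50Uncertainty:
    def test_point_value(self):
        from protonrbe.dose_response import LogisticFit

        fit = LogisticFit(-10.0, 0.2, np.eye(2), 0.0, True)
        assert ed50(fit).value == pytest.approx(50.0)

    def test_delta_method_hand_value(self):
        from protonrbe.dose_response import LogisticFit

        fit = LogisticFit(-10.0, 0.2, np.diag([1.0, 0.0]), 0.0, True)
        assert ed50(fit).se == pytest.approx(5.0)

    def test_delta_matches_parametric_bootstrap(self):
        from protonrbe.dose_response import LogisticFit

        cov = np.array([[4.0, -0.07], [-0.07, 0.0016]])
        fit = LogisticFit(-20.0, 0.4, cov, 0.0, True)
        est = ed50(fit)
        rng = np.random.default_rng(1)
        draws = rng.multivariate_normal([-20.0, 0.4], cov, size=10_000)
        boot = -draws[:, 0] / draws[:, 1]
        assert est.se == pytest.approx(boot.std(), rel=0.10)

    def test_negative_slope_rejected(self):
        from protonrbe.dose_response import LogisticFit

        with pytest.raises(ValueError):
            ed50(LogisticFit(-10.0, -0.2, np.eye(2), 0.0, True))


class TestFitGeneralized:
    @staticmethod
    def _make_groups(b0, b1, b2, rng, n_per=50):
        grids = {1: [16, 18, 20, 22, 24], 2: [23, 25, 27, 29, 31],
                 6: [40, 42, 44, 46, 48]}
        groups = []
        for n_fx, doses in grids.items():
            for D in doses:
                p = float(generalized_probability(D, D / n_fx, b0, b1, b2))
                r = rng.binomial(n_per, p)
                groups.append(_group(float(D), n_per, r / n_per, n_fx=n_fx))
        return groups

    def test_recovers_bed50_alpha_beta(self):
        # truth BED50 = 138, alpha/beta = 3.3 via b = (-16.56, .12, .12/3.3)
        rng = np.random.default_rng(0)
        groups = self._make_groups(-16.56, 0.12, 0.12 / 3.3, rng)
        fit = fit_generalized(groups)
        bed50_est, ab_est = bed50_alpha_beta(fit)
        assert abs(bed50_est.value - 138.0) < 2 * bed50_est.se
        assert abs(ab_est.value - 3.3) < 2 * ab_est.se

    def test_loglik_at_optimum_beats_truth(self):
        from protonrbe.dose_response import _as_arrays, _nll

        rng = np.random.default_rng(3)
        truth = np.array([-16.56, 0.12, 0.12 / 3.3])
        groups = self._make_groups(*truth, rng, n_per=10)
        fit = fit_generalized(groups)
        D, d, n, r = _as_arrays(groups)
        X = np.column_stack([np.ones_like(D), D, D * d])
        assert fit.log_likelihood >= -_nll(truth, X, n, r) - 1e-6

    def test_single_schedule_unidentifiable(self):
        groups = [_group(40.0, 5, 0.2), _group(50.0, 5, 0.8)]
        with pytest.raises(ValueError):
            fit_generalized(groups)

    def test_b2_zero_truth_gives_unstable_alpha_beta(self):
        # generated with no fraction-dose effect: fitted b2 ~ 0, so the
        # constrained fit is used and flags the unconstrained optimum
        rng = np.random.default_rng(5)
        groups = self._make_groups(-15.0, 0.3, 0.0, rng, n_per=5000)
        fit = fit_generalized(groups)
        dose_only = fit_logistic(groups)
        # b2 statistically indistinguishable from zero -> alpha/beta blows up
        assert abs(fit.b2) < 3 * math.sqrt(fit.covariance[2, 2])
        assert fit.b1 / max(fit.b2, 1e-12) > 20.0
        if fit.method == "ml-constrained":
            assert fit.unconstrained is not None
        # BED50 then approximately equals the dose-only ED50
        bed50_est, _ = bed50_alpha_beta(fit)
        assert bed50_est.value == pytest.approx(ed50(dose_only).value, rel=0.05)

    def test_bed50_alpha_beta_point_values(self):
        from protonrbe.dose_response import GeneralizedFit

        fit = GeneralizedFit(-5.0, 0.04, 0.02, np.eye(3) * 1e-6, 0.0, True)
        bed50_est, ab_est = bed50_alpha_beta(fit)
        assert bed50_est.value == pytest.approx(125.0)
        assert ab_est.value == pytest.approx(2.0)

    def test_se_matches_bootstrap_diagonal_case(self):
        from protonrbe.dose_response import GeneralizedFit

        cov = np.diag([0.25, 1e-5, 2e-6])
        params = np.array([-16.56, 0.12, 0.036])
        fit = GeneralizedFit(*params, cov, 0.0, True)
        bed50_est, ab_est = bed50_alpha_beta(fit)
        rng = np.random.default_rng(2)
        draws = rng.multivariate_normal(params, cov, size=10_000)
        boot_bed = -draws[:, 0] / draws[:, 1]
        boot_ab = draws[:, 1] / draws[:, 2]
        assert bed50_est.se == pytest.approx(boot_bed.std(), rel=0.10)
        assert ab_est.se == pytest.approx(boot_ab.std(), rel=0.10)


class TestFieller:
    def test_vanishing_variance_collapses_to_ratio(self):
        ci = fieller_cl((10.0, 1e-9), (5.0, 1e-9))
        assert ci.lower == pytest.approx(2.0, abs=1e-6)
        assert ci.upper == pytest.approx(2.0, abs=1e-6)

    def test_matches_monte_carlo_quantiles(self):
        ci = fieller_cl((10.0, 1.0), (5.0, 0.5), level=0.90)
        rng = np.random.default_rng(0)
        r = rng.normal(10, 1, 100_000) / rng.normal(5, 0.5, 100_000)
        lo, hi = np.percentile(r, [5, 95])
        assert ci.lower == pytest.approx(lo, rel=0.02)
        assert ci.upper == pytest.approx(hi, rel=0.02)

    def test_perfectly_correlated_identical_estimates(self):
        ci = fieller_cl((5.0, 0.5), (5.0, 0.5), correlation=1.0)
        assert ci.lower == pytest.approx(1.0, abs=1e-9)
        assert ci.upper == pytest.approx(1.0, abs=1e-9)

    def test_unbounded_interval_signalled(self):
        # denominator indistinguishable from zero: g >= 1
        ci = fieller_cl((10.0, 1.0), (1.0, 2.0))
        assert not ci.bounded
        assert math.isinf(ci.lower) and math.isinf(ci.upper)

    def test_contains_point_ratio_when_bounded(self):
        ci = fieller_cl((57.0, 2.0), (51.3, 0.7), level=0.90)
        assert ci.bounded
        assert ci.lower < 57.0 / 51.3 < ci.upper


class TestSlopeRegression:
    def test_exact_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = slope_regression(x, [2 * v for v in x])
        assert res.slope == pytest.approx(2.0)
        assert res.p_value < 1e-6

    def test_hand_ols_four_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.1, 2.9, 4.2, 4.8])
        res = slope_regression(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        assert res.slope == pytest.approx(slope, rel=1e-9)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        x = np.arange(100, dtype=float)
        for _ in range(500):
            res = slope_regression(x, rng.standard_normal(100))
            pvals.append(res.p_value)
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            slope_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBuildDoseGroups:
    def test_groups_by_dose_and_schedule(self):
        recs = [_animal(i, 50.0, i < 2, 100 if i < 2 else 300) for i in range(5)]
        recs += [_animal(10 + i, 55.0, True, 150) for i in range(5)]
        groups = build_dose_groups(recs)
        assert len(groups) == 2
        assert groups[0].actuarial_rate == pytest.approx(0.4)
        assert groups[1].actuarial_rate == pytest.approx(1.0)
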