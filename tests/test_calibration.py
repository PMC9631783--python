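"""Poisson maximum-likelihood fitting of the linear-quadratic curve."""

import itertools
import warnings

import numpy as np
import pytest
from scipy import stats

from dicentrix import (
    CalibrationCurve,
    DicentricCalibrationModel,
    ValidationError,
    coefficient_z_tests,
    curve_confidence_band,
    fit_linear_quadratic,
    simulate_calibration_dataset,
)
from dicentrix.calibration import ConvergenceError


def _round_sig(x, sig):
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


class TestRefitOfPublishedTable:
    def test_coefficients_reproduce_published_curve(self, fitted):
        c, alpha, beta = fitted.params
        assert _round_sig(c, 2) == 0.00097
        assert _round_sig(alpha, 2) == 0.016
        assert _round_sig(beta, 2) == 0.018

    def test_standard_errors_reproduce_published_values(self, fitted):
        se_c, se_a, se_b = fitted.bse
        assert _round_sig(se_c, 2) == 0.00021
        assert _round_sig(se_a, 2) == 0.0022
        assert _round_sig(se_b, 2) == 0.0012

    def test_all_coefficients_significant(self, fitted):
        tests = coefficient_z_tests(fitted)
        assert (tests["pvalue"] < 0.05).all()
        # alpha z is its estimate over its SE
        assert tests.loc[1, "z"] == pytest.approx(
            fitted.params[1] / fitted.bse[1]
        )
        assert tests.loc[1, "z"] == pytest.approx(7.27, abs=0.2)

    def test_fit_is_non_significant_on_gof(self, fitted):
        gof = fitted.goodness_of_fit()
        assert gof.df == 6
        assert gof.pvalue > 0.05

    def test_fitted_yields_within_poisson_error_of_observed(self, fitted, calib_dists):
        for d in calib_dists:
            yhat = fitted.predict(d.dose)
            se = np.sqrt(max(d.total_dicentrics, 1)) / d.cells
            assert abs(yhat - d.dicentric_yield) < 3 * se

    def test_matches_independent_glm_fit(self, fitted, calib_dists):
        """Identity-link Poisson GLM fitted by statsmodels must agree."""
        sm = pytest.importorskip("statsmodels.api")
        dose = np.array([d.dose for d in calib_dists])
        cells = np.array([d.cells for d in calib_dists], dtype=float)
        x = np.array([d.total_dicentrics for d in calib_dists], dtype=float)
        design = cells[:, None] * np.column_stack([np.ones_like(dose), dose, dose**2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam = sm.families.Poisson(link=sm.families.links.Identity())
            res = sm.GLM(x, design, family=fam).fit()
        assert np.allclose(res.params, fitted.params, rtol=1e-5)
        assert np.allclose(res.bse, fitted.bse, rtol=1e-3)


class TestOptimizer:
    def test_noise_free_limit_recovers_generating_curve(self):
        # huge cell numbers with counts exactly on the curve
        truth = np.array([0.001, 0.02, 0.06])
        dose = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        cells = np.full(dose.size, 10**7)
        g = np.column_stack([np.ones_like(dose), dose, dose**2])
        counts = np.rint(cells * (g @ truth)).astype(int)
        res = DicentricCalibrationModel(dose, cells, counts).fit()
        assert np.allclose(res.params, truth, rtol=5e-4)

    def test_optimum_beats_grid_search(self):
        """Likelihood at the optimum >= every point of a grid around it."""
        dose = np.array([0.0, 1.0, 2.0, 4.0])
        cells = np.array([5000, 2000, 1000, 500])
        counts = np.array([6, 50, 120, 260])
        model = DicentricCalibrationModel(dose, cells, counts)
        res = model.fit()
        ll_opt = model.loglike(res.params)
        c0, a0, b0 = res.params
        grid = itertools.product(
            np.linspace(max(c0 - 5e-3, 0), c0 + 5e-3, 20),
            np.linspace(max(a0 - 0.02, 0), a0 + 0.02, 20),
            np.linspace(max(b0 - 0.02, 0), b0 + 0.02, 20),
        )
        assert all(model.loglike(np.array(p)) <= ll_opt + 1e-9 for p in grid)

    def test_observed_information_option_changes_ses_only(self, calib_dists):
        res = fit_linear_quadratic(calib_dists, information="observed")
        res_e = fit_linear_quadratic(calib_dists, information="expected")
        assert np.allclose(res.params, res_e.params, rtol=1e-8)
        assert not np.allclose(res.bse, res_e.bse)

    def test_too_few_dose_points_rejected(self):
        with pytest.raises(ValidationError):
            DicentricCalibrationModel([0, 1, 2], [100, 100, 100], [1, 5, 9])

    def test_iteration_cap_raises_with_last_iterate(self, calib_dists):
        with pytest.raises(ConvergenceError) as err:
            fit_linear_quadratic(calib_dists, maxiter=1, tol=0.0)
        assert err.value.last_params.shape == (3,)


class TestGoodnessOfFit:
    def test_perfect_fit_gives_zero_chi2(self):
        dose = np.array([0.0, 1.0, 2.0, 3.0])
        cells = np.full(4, 10**6)
        truth = np.array([0.001, 0.01, 0.02])
        g = np.column_stack([np.ones_like(dose), dose, dose**2])
        counts = np.rint(cells * (g @ truth)).astype(int)
        res = DicentricCalibrationModel(dose, cells, counts).fit()
        gof = res.goodness_of_fit()
        assert gof.statistic == pytest.approx(0.0, abs=1e-4)
        assert gof.pvalue == pytest.approx(1.0, abs=1e-4)

    def test_pearson_matches_hand_sum(self):
        dose = np.array([0.0, 1.0, 2.0, 4.0])
        cells = np.array([5000, 2000, 1000, 500])
        counts = np.array([6, 50, 120, 260])
        res = DicentricCalibrationModel(dose, cells, counts).fit()
        mu = res.fittedvalues
        hand = float(np.sum((counts - mu) ** 2 / mu))
        gof = res.goodness_of_fit(kind="pearson")
        assert gof.statistic == pytest.approx(hand)
        assert gof.df == 1
        assert gof.pvalue == pytest.approx(stats.chi2.sf(hand, 1))

    def test_deviance_variant_offered(self, fitted):
        dev = fitted.goodness_of_fit(kind="deviance")
        assert dev.kind == "deviance"
        assert dev.statistic == pytest.approx(4.13, abs=0.05)


class TestConfidenceBand:
    def test_band_at_zero_dose_reduces_to_intercept_se(self):
        cov = np.diag([1e-8, 1.6e-5, 9e-6])
        cv = CalibrationCurve(0.001, 0.02, 0.06, 1e-4, 4e-3, 3e-3, covariance=cov)
        lo, hi = curve_confidence_band(cv, 0.0, level=0.95)
        z = stats.norm.ppf(0.975)
        assert hi - cv.c == pytest.approx(z * 1e-4)
        assert cv.c - lo == pytest.approx(z * 1e-4)

    def test_diagonal_covariance_at_unit_dose(self):
        cov = np.diag([1e-8, 1.6e-5, 9e-6])
        cv = CalibrationCurve(0.001, 0.02, 0.06, covariance=cov)
        se = cv.yield_standard_error(1.0)
        assert se == pytest.approx(np.sqrt(1e-8 + 1.6e-5 + 9e-6))

    @pytest.mark.parametrize("scale", [1.5, 2.0, 4.0])
    def test_band_width_monotone_in_each_se(self, scale):
        base = np.array([1e-4, 4e-3, 3e-3])
        for i in range(3):
            ses = base.copy()
            ses[i] *= scale
            cv0 = CalibrationCurve(0.001, 0.02, 0.06, covariance=np.diag(base**2))
            cv1 = CalibrationCurve(0.001, 0.02, 0.06, covariance=np.diag(ses**2))
            for dose in (0.5, 1.0, 3.0):
                lo0, hi0 = curve_confidence_band(cv0, dose)
                lo1, hi1 = curve_confidence_band(cv1, dose)
                assert hi1 - lo1 >= hi0 - lo0


class TestParameterRecovery:
    def test_wald_interval_coverage_on_simulated_cohorts(self, fitted, calib_dists):
        """Refits of cohorts simulated from the fitted curve recover alpha and
        beta without bias and with near-nominal Wald coverage."""
        truth = fitted.curve
        doses = [d.dose for d in calib_dists]
        cells = [d.cells for d in calib_dists]
        n_rep = 120
        est = np.empty((n_rep, 3))
        cover = np.zeros(2)
        z = stats.norm.ppf(0.975)
        for rep in range(n_rep):
            dists = simulate_calibration_dataset(doses, cells, truth, seed=5000 + rep)
            res = fit_linear_quadratic(dists)
            est[rep] = res.params
            for j, k in enumerate((1, 2)):
                lo = res.params[k] - z * res.bse[k]
                hi = res.params[k] + z * res.bse[k]
                cover[j] += lo <= truth.params[k] <= hi
        cover /= n_rep
        for k in (1, 2):
            mc_se = est[:, k].std(ddof=1) / np.sqrt(n_rep)
            assert abs(est[:, k].mean() - truth.params[k]) < 2.5 * mc_se
        assert np.all(cover >= 0.90)
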