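"""Trend-model fitting: baselines, breakpoints, score test, predictions."""

import numpy as np
import pytest
from scipy import stats

import rangeshift.segmented as sg
from rangeshift.errors import (
    BoundaryConvergenceError,
    InsufficientDataError,
    RankDeficiencyError,
)
from rangeshift.errors import TestUndefinedError as UndefinedTestError

from conftest import DESIGN_YEARS, PSI_TRUE, SIGMA_TRUE, SLOPE_TRUE, margin_draw


class TestBaselines:
    def test_constant_fit_is_mean_and_degenerate_without_noise(self):
        f = sg.fit_baseline([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0],
                            "constant")
        assert f.coef_[0] == pytest.approx(5.0)
        assert f.degenerate_

    def test_linear_fit_recovers_exact_line(self):
        x = np.arange(10.0)
        f = sg.fit_baseline(x, 2 * x + 1, "linear")
        assert f.coef_ == pytest.approx([1.0, 2.0])

    def test_quadratic_fit_recovers_exact_polynomial(self):
        x = np.linspace(1985, 2021, 30)
        y = 167.78 - 0.5 * (x - 2000) + 0.147 * (x - 2000) ** 2
        f = sg.fit_baseline(x, y, "quadratic")
        assert f.predict(x) == pytest.approx(y)
        assert f.coef_[2] == pytest.approx(0.147)

    def test_centered_quadratic_reports_raw_scale(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 3)
        raw = sg.fit_baseline(margin_x, y, "quadratic")
        cen = sg.fit_baseline(margin_x, y, "quadratic", center=True)
        assert cen.coef_ == pytest.approx(raw.coef_, rel=1e-6)
        assert cen.nll_ == pytest.approx(raw.nll_, abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(RankDeficiencyError):
            sg.fit_baseline(np.full(8, 2000.0), np.arange(8.0), "linear")

    def test_tiny_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            sg.fit_baseline([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], "constant")

    def test_gaussian_nll_matches_normal_logpdf(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 11)
        f = sg.fit_baseline(margin_x, y, "linear")
        ll = stats.norm.logpdf(y, loc=f.predict(margin_x), scale=f.sigma_).sum()
        assert f.nll_ == pytest.approx(-ll, abs=1e-8)

    def test_binomial_constant_reproduces_logit_mean(self, rng):
        y = (rng.random(40) < 0.3).astype(float)
        f = sg.fit_baseline(np.arange(40.0), y, "constant", family="binomial")
        assert f.coef_[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-8)

    def test_binomial_separation_flagged(self):
        x = np.arange(1990.0, 2010.0)
        y = (x > 2000).astype(float)
        with pytest.warns(UserWarning, match="separation"):
            f = sg.fit_baseline(x, y, "linear", family="binomial")
        assert not f.converged_


class TestAgainstStatsmodels:
    """The in-package OLS/IRLS engines against the reference GLM fitter."""

    def test_gaussian_matches_ols(self, margin_x, margin_mean):
        sm = pytest.importorskip("statsmodels.api")
        y = margin_draw(margin_x, margin_mean, 21)
        f = sg.fit_baseline(margin_x, y, "quadratic")
        X = np.column_stack([np.ones_like(margin_x), margin_x, margin_x ** 2])
        ref = sm.OLS(y, X).fit()
        assert f.coef_ == pytest.approx(ref.params, rel=1e-6)
        assert f.se_ == pytest.approx(ref.bse, rel=1e-6)

    def test_binomial_matches_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        x = np.repeat(DESIGN_YEARS, 25)
        p = 1 / (1 + np.exp(-(-1.7 + 0.06 * (x - 1985))))
        y = (rng.random(len(x)) < p).astype(float)
        f = sg.fit_baseline(x, y, "linear", family="binomial")
        X = np.column_stack([np.ones_like(x), x])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert f.coef_ == pytest.approx(ref.params, rel=1e-6)
        assert f.se_ == pytest.approx(ref.bse, rel=1e-4)
        assert f.nll_ == pytest.approx(-ref.llf, abs=1e-8)


class TestSegmentedFit:
    def test_noiseless_hinge_recovered_exactly(self):
        x = np.arange(1985.0, 2022.0)
        y = np.where(x <= 2006, 160.0, 160.0 + 5 * (x - 2006))
        f = sg.fit_segmented(x, y, left_constrained=True)
        assert f.psi_ == pytest.approx(2006.0, abs=1e-6)
        assert f.coef_ == pytest.approx([160.0, 5.0], abs=1e-6)
        assert f.slopes_()["year2"] == pytest.approx(5.0, abs=1e-6)

    def test_noiseless_two_slope_recovered(self):
        x = np.arange(1985.0, 2022.0)
        y = 100 - 0.6 * (x - 1985) + 6.1 * np.maximum(x - 2005, 0)
        f = sg.fit_segmented(x, y, left_constrained=False)
        assert f.psi_ == pytest.approx(2005.0, abs=1e-6)
        assert f.slopes_()["year1"] == pytest.approx(-0.6, abs=1e-6)
        assert f.slopes_()["year2"] == pytest.approx(5.5, abs=1e-6)

    def test_derived_grid_oracle_half_year_spacing(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 42)
        f = sg.fit_segmented(margin_x, y, left_constrained=True)
        grid = np.arange(2003.0, 2019.01, 0.5)
        prof = sg.profile_psi(margin_x, y, left_constrained=True, psi_grid=grid)
        best = prof.loc[prof["nll"].idxmin()]
        assert abs(f.psi_ - best["psi"]) <= 0.5
        assert f.nll_ <= best["nll"] + 1e-9

    def test_explicit_start_matches_auto(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 8)
        auto = sg.fit_segmented(margin_x, y, left_constrained=True)
        manual = sg.fit_segmented(margin_x, y, left_constrained=True, psi0=2010.0)
        assert manual.psi_ == pytest.approx(auto.psi_, abs=1e-6)

    def test_likelihood_nesting(self, margin_x, margin_mean):
        for seed in range(8):
            y = margin_draw(margin_x, margin_mean, 100 + seed)
            two = sg.fit_segmented(margin_x, y, left_constrained=False)
            lh = sg.fit_segmented(margin_x, y, left_constrained=True)
            lin = sg.fit_baseline(margin_x, y, "linear")
            assert two.nll_ <= lh.nll_ + 1e-6
            assert two.nll_ <= lin.nll_ + 1e-6

    def test_too_few_distinct_years_rejected(self):
        x = np.repeat([1985.0, 2003.0, 2021.0], 10)
        y = np.random.default_rng(0).normal(size=30)
        with pytest.raises(InsufficientDataError):
            sg.fit_segmented(x, y)

    def test_boundary_optimum_flagged_and_strict_mode_raises(self):
        # decline only after the second-to-last year pushes psi to the bound
        rng = np.random.default_rng(2)
        x = np.repeat(DESIGN_YEARS, 25)
        p = 1 / (1 + np.exp(-(-1.6 + 0.07 * (x - 1985) - 0.8 * np.maximum(x - 2019, 0))))
        y = (rng.random(len(x)) < p).astype(float)
        f = sg.fit_segmented(x, y, family="binomial", left_constrained=False)
        assert f.psi_at_bound_
        assert f.psi_ == pytest.approx(2019.0)
        with pytest.raises(BoundaryConvergenceError, match="right"):
            sg.fit_segmented(x, y, family="binomial", left_constrained=False,
                             strict_interior=True)

    def test_segmented_report_roundtrip(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 7)
        f = sg.fit_segmented(margin_x, y, left_constrained=True)
        rep = f.to_report()
        names = [r["parameter"] for r in rep["parameters"]]
        assert "breakpoint_year" in names
        assert rep["np"] == 3 and rep["k_aicc"] == 4
        assert rep["slopes"]["year2"] == pytest.approx(f.slopes_()["year2"])


class TestProfilePsi:
    def test_noiseless_profile_minimized_at_true_breakpoint(self):
        x = np.arange(1985.0, 2022.0)
        y = np.where(x <= 2006, 160.0, 160.0 + 5 * (x - 2006))
        prof = sg.profile_psi(x, y, left_constrained=True,
                              psi_grid=[2000.0, 2006.0, 2012.0])
        assert prof["nll"].idxmin() == 1

    def test_profile_never_beats_free_fit(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 13)
        f = sg.fit_segmented(margin_x, y, left_constrained=True)
        prof = sg.profile_psi(margin_x, y, left_constrained=True,
                              psi_grid=np.linspace(2003, 2019, 81))
        assert prof["nll"].min() >= f.nll_ - 1e-9

    def test_profile_below_linear_fit(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 14)
        lin = sg.fit_baseline(margin_x, y, "linear")
        prof = sg.profile_psi(margin_x, y, left_constrained=False,
                              psi_grid=np.linspace(2004, 2018, 29))
        assert prof["nll"].min() <= lin.nll_ + 1e-9

    def test_matches_direct_refit_oracle(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 15)
        grid = np.linspace(2004, 2018, 15)
        prof = sg.profile_psi(margin_x, y, left_constrained=True, psi_grid=grid)
        for psi, nll in zip(prof["psi"], prof["nll"]):
            X = np.column_stack([np.ones_like(margin_x),
                                 np.maximum(margin_x - psi, 0)])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            n = len(y)
            expect = 0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1)
            assert nll == pytest.approx(expect, abs=1e-8)

    def test_empty_grid_rejected(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 16)
        with pytest.raises(Exception):
            sg.profile_psi(margin_x, y, psi_grid=[])


class TestScoreTest:
    def test_strong_hinge_detected(self, margin_x):
        rng = np.random.default_rng(1)
        y = 160 + 8 * np.maximum(margin_x - 2006, 0) + 5 * rng.standard_normal(30)
        r = sg.pscore_test(margin_x, y, left_constrained_null=True)
        assert r.p_value < 1e-3

    def test_perfect_fit_undefined(self, margin_x):
        with pytest.raises(UndefinedTestError):
            sg.pscore_test(margin_x, 2.0 * margin_x, left_constrained_null=False)

    def test_binomial_variant_runs(self):
        rng = np.random.default_rng(3)
        x = np.repeat(DESIGN_YEARS, 25)
        p = 1 / (1 + np.exp(-(-2.0 + 0.25 * np.maximum(x - 2006, 0))))
        y = (rng.random(len(x)) < p).astype(float)
        r = sg.pscore_test(x, y, family="binomial")
        assert r.p_value < 0.05

    def test_bootstrap_agrees_on_strong_signal(self, margin_x):
        rng = np.random.default_rng(6)
        y = 160 + 8 * np.maximum(margin_x - 2006, 0) + 5 * rng.standard_normal(30)
        rb = sg.pscore_bootstrap(margin_x, y, left_constrained=True,
                                 n_boot=199, seed=0)
        assert rb.p_value == pytest.approx(1 / 200)


class TestPrediction:
    def test_constant_model_flat_with_constant_width(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 30)
        f = sg.fit_baseline(margin_x, y, "constant")
        pred = f.predict_interval([1990.0, 2000.0, 2010.0])
        assert pred["mean"].nunique() == 1
        widths = pred["upper"] - pred["lower"]
        assert widths.max() - widths.min() < 1e-9

    def test_hinge_prediction_reproduces_observations(self):
        x = np.arange(1985.0, 2022.0)
        y = np.where(x <= 2006, 160.0, 160.0 + 5 * (x - 2006))
        f = sg.fit_segmented(x, y, left_constrained=True)
        assert f.predict(x) == pytest.approx(y, abs=1e-6)

    def test_binomial_interval_ordered_and_bounded(self):
        rng = np.random.default_rng(9)
        x = np.repeat(DESIGN_YEARS, 25)
        p = 1 / (1 + np.exp(-(-1.7 + 0.07 * (x - 1985))))
        y = (rng.random(len(x)) < p).astype(float)
        f = sg.fit_baseline(x, y, "linear", family="binomial")
        pred = f.predict_interval(np.linspace(1985, 2021, 50))
        assert ((pred["lower"] <= pred["mean"]) & (pred["mean"] <= pred["upper"])).all()
        assert (pred["lower"] >= 0).all() and (pred["upper"] <= 1).all()

    def test_far_extrapolation_warns(self, margin_x, margin_mean):
        y = margin_draw(margin_x, margin_mean, 31)
        f = sg.fit_baseline(margin_x, y, "linear")
        with pytest.warns(UserWarning, match="extrapolat"):
            f.predict_interval([1800.0])


class TestSklearnProtocol:
    def test_get_set_params_roundtrip(self):
        est = sg.TrendRegression(form="two_slope", family="binomial", tol=1e-6)
        params = est.get_params()
        clone = sg.TrendRegression(**params)
        assert clone.get_params() == params
        clone.set_params(form="linear")
        assert clone.form == "linear"

    def test_estimator_clonable_by_sklearn(self, margin_x, margin_mean):
        from sklearn.base import clone

        est = sg.TrendRegression(form="left_horizontal")
        y = margin_draw(margin_x, margin_mean, 40)
        est.fit(margin_x.reshape(-1, 1), y)
        fresh = clone(est)
        assert not hasattr(fresh, "coef_")
        assert est.score(margin_x.reshape(-1, 1), y) > 0.5
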