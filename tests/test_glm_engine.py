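"""Model-fitting layer: closed-form oracles, dispersion scaling, conditional
Poisson vs stratum-fixed-effects, spline basis, AIC, residual diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from coldharvest import glm_engine as ge


def two_group_design(n_per=2, mu0=100.0, mu1=121.0):
    y = np.array([mu0] * n_per + [mu1] * n_per)
    X = pd.DataFrame({"const": 1.0, "x": [0.0] * n_per + [1.0] * n_per})
    return y, X


class TestNaturalSpline:
    def test_df1_is_affine_in_t(self):
        t = np.arange(1, 58, dtype=float)
        b = ge.natural_spline_basis(t, 1)
        assert b.shape == (57, 1)
        r = np.corrcoef(b[:, 0], t)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("df", [2, 3, 5, 8])
    def test_linear_beyond_boundary_knots(self, df):
        """Second differences vanish outside the boundary knots: the basis
        construction (reproduced at fixed knots) is affine there, and inside
        the data range it agrees with natural_spline_basis."""
        t = np.arange(1, 58, dtype=float)
        tq = np.quantile(t, np.linspace(0, 1, df + 1))
        np.testing.assert_allclose(_eval_with_knots(t, tq), ge.natural_spline_basis(t, df))
        outside = np.concatenate([np.linspace(-30, -1, 9), np.linspace(60, 90, 9)])
        h = 0.5
        for x0 in outside:
            pts = np.array([x0 - h, x0, x0 + h])
            b = _eval_with_knots(pts, tq)
            second = b[0] - 2 * b[1] + b[2]
            np.testing.assert_allclose(second, 0.0, atol=1e-8)

    def test_tracks_ten_year_moving_average(self):
        """A 5-df spline fit over 57 points behaves like a ~10-year moving
        average of a smooth trend (correlation >= 0.95)."""
        t = np.arange(1, 58, dtype=float)
        trend = 0.3 * np.sin(2 * np.pi * t / 57) + 0.01 * t
        B = np.column_stack([np.ones_like(t), ge.natural_spline_basis(t, 5)])
        coef, *_ = np.linalg.lstsq(B, trend, rcond=None)
        fitted = B @ coef
        ma = pd.Series(trend).rolling(10, center=True, min_periods=5).mean().to_numpy()
        assert np.corrcoef(fitted, ma)[0, 1] > 0.95

    def test_df_out_of_range(self):
        with pytest.raises(ValueError):
            ge.natural_spline_basis(np.arange(10.0), 9)


def _eval_with_knots(x, knots):
    """Reference evaluation of the natural-spline columns at fixed knots."""
    kl, kp = knots[-1], knots[-2]

    def d(v, kj):
        return (np.maximum(v - kj, 0) ** 3 - np.maximum(v - kl, 0) ** 3) / (kl - kj)

    cols = [x]
    for kj in knots[:-2]:
        cols.append(d(x, kj) - d(x, kp))
    return np.column_stack(cols)


class TestLoglinear:
    def test_two_group_poisson_mle_is_log_ratio_of_means(self):
        y, X = two_group_design()
        fit = ge.fit_loglinear(y, X, "poisson")
        assert fit.params["x"] == pytest.approx(np.log(1.21), abs=1e-10)
        pct, lo, hi = fit.percent_increase("x")
        assert pct == pytest.approx(21.0, abs=1e-8)
        assert lo < pct < hi

    def test_intercept_only_mle_is_log_mean(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(50, 30).astype(float)
        X = pd.DataFrame({"const": np.ones(30)})
        fit = ge.fit_loglinear(y, X, "poisson")
        assert fit.params["const"] == pytest.approx(np.log(y.mean()), abs=1e-10)

    def test_true_poisson_dispersion_near_one(self):
        rng = np.random.default_rng(12345)
        y = rng.poisson(40, 5000).astype(float)
        X = pd.DataFrame({"const": np.ones(5000)})
        fit = ge.fit_loglinear(y, X, "quasipoisson")
        assert 0.9 < fit.dispersion < 1.1

    def test_quasipoisson_scales_se_by_sqrt_phi(self):
        rng = np.random.default_rng(7)
        n = 200
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=n)})
        y = rng.poisson(np.exp(3 + 0.2 * X["x"] + rng.normal(0, 0.3, n)))
        plain = ge.fit_loglinear(y, X, "poisson")
        quasi = ge.fit_loglinear(y, X, "quasipoisson")
        pd.testing.assert_series_equal(plain.params, quasi.params)
        np.testing.assert_allclose(quasi.bse, plain.bse * np.sqrt(quasi.dispersion))
        assert quasi.dispersion > 1.5  # lognormal mixing makes it overdispersed

    def test_negbin_approaches_poisson_as_overdispersion_vanishes(self):
        rng = np.random.default_rng(99)
        n = 2000
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=n)})
        y = rng.poisson(np.exp(2.0 + 0.15 * X["x"])).astype(float)
        nb = ge.fit_loglinear(y, X, "negbin")
        po = ge.fit_loglinear(y, X, "poisson")
        np.testing.assert_allclose(nb.params, po.params, atol=1e-3)

    def test_simple_family_is_ols_on_log_counts(self):
        y, X = two_group_design()
        fit = ge.fit_loglinear(y, X, "simple")
        assert fit.params["x"] == pytest.approx(np.log(1.21), abs=1e-10)
        assert np.isnan(ge.model_aic(fit))
        with pytest.raises(ValueError):
            ge.fit_loglinear(np.array([0.0, 1.0]), X.iloc[:2], "simple")

    def test_rank_deficiency_names_columns(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = pd.DataFrame({"const": 1.0, "a": [0, 1, 0, 1.0], "b": [0, 2, 0, 2.0]})
        with pytest.raises(ValueError, match="b"):
            ge.fit_loglinear(y, X, "poisson")

    def test_percent_increase_zero_at_zero_and_monotone(self):
        y, X = two_group_design(mu0=100, mu1=100)
        fit = ge.fit_loglinear(y, X, "poisson")
        assert fit.percent_increase("x")[0] == pytest.approx(0.0, abs=1e-8)
        betas = np.linspace(-0.5, 0.5, 11)
        pcts = 100 * np.expm1(betas)
        assert (np.diff(pcts) > 0).all()


class TestConditionalPoisson:
    def test_two_cell_closed_form(self):
        fit = ge.fit_conditional_poisson(
            np.array([10.0, 20.0]),
            pd.DataFrame({"x": [0.0, 1.0]}),
            np.array([0, 0]),
            scale_dispersion=False,
        )
        assert fit.params["x"] == pytest.approx(np.log(2.0), abs=1e-10)

    @pytest.mark.parametrize("n_strata,seed", [(6, 0), (10, 4)])
    def test_matches_stratum_fixed_effects_poisson(self, n_strata, seed):
        """Conditioning out stratum totals must reproduce the shared
        coefficients of a Poisson with one fixed effect per stratum."""
        rng = np.random.default_rng(seed)
        per = 5
        strata = np.repeat(np.arange(n_strata), per)
        X = pd.DataFrame(rng.normal(size=(n_strata * per, 2)), columns=["x1", "x2"])
        eta = 3.0 + 0.4 * rng.normal(size=n_strata)[strata] + 0.3 * X["x1"] - 0.2 * X["x2"]
        y = rng.poisson(np.exp(eta)).astype(float)
        cond = ge.fit_conditional_poisson(y, X, strata, scale_dispersion=False)
        dummies = pd.get_dummies(pd.Series(strata), prefix="s").astype(float)
        fe = sm.GLM(y, pd.concat([dummies, X], axis=1), family=sm.families.Poisson()).fit(
            tol=1e-12
        )
        np.testing.assert_allclose(
            cond.params.to_numpy(), np.asarray(fe.params)[-2:], atol=1e-6
        )

    def test_constant_exposure_within_strata_is_inestimable(self):
        strata = np.repeat([0, 1], 3)
        X = pd.DataFrame({"x": np.repeat([1.0, 2.0], 3)})
        y = np.array([3.0, 4, 5, 6, 7, 8])
        with pytest.raises(ValueError, match="inestimable"):
            ge.fit_conditional_poisson(y, X, strata)

    def test_degenerate_strata_dropped(self):
        strata = np.array([0, 0, 1, 2, 2])
        X = pd.DataFrame({"x": [0.0, 1.0, 0.5, 0.0, 1.0]})
        y = np.array([10.0, 20.0, 7.0, 0.0, 0.0])
        fit = ge.fit_conditional_poisson(y, X, strata, scale_dispersion=False)
        assert fit.n_strata == 1  # singleton and all-zero strata dropped
        assert fit.params["x"] == pytest.approx(np.log(2.0), abs=1e-8)


class TestAicAndResiduals:
    def test_saturated_single_observation_aic(self):
        fit = ge.fit_loglinear(np.array([1.0]), pd.DataFrame({"const": [1.0]}), "poisson")
        assert fit.loglik == pytest.approx(-1.0, abs=1e-10)
        assert ge.model_aic(fit) == pytest.approx(4.0, abs=1e-8)

    def test_noise_column_raises_aic_in_expectation(self):
        rng = np.random.default_rng(11)
        n = 80
        X = pd.DataFrame({"const": np.ones(n)})
        diffs = []
        for _ in range(40):
            y = rng.poisson(30, n).astype(float)
            base = ge.model_aic(ge.fit_loglinear(y, X, "poisson"))
            X2 = X.assign(noise=rng.normal(size=n))
            full = ge.model_aic(ge.fit_loglinear(y, X2, "poisson"))
            diffs.append(full - base)
        assert np.mean(diffs) > 0

    def test_saturated_residuals_zero(self):
        y, X = two_group_design()
        fit = ge.fit_loglinear(y, X, "poisson")
        np.testing.assert_allclose(ge.deviance_residuals(fit), 0.0, atol=1e-6)

    def test_white_noise_autocorrelation_band(self):
        """Under independence |lag-1 autocorrelation| stays within the
        +/-1.96/sqrt(n) band roughly 95% of the time."""
        rng = np.random.default_rng(2024)
        n, hits, reps = 57, 0, 300
        X = pd.DataFrame({"const": np.ones(n)})
        for _ in range(reps):
            y = rng.poisson(100, n).astype(float)
            fit = ge.fit_loglinear(y, X, "poisson")
            d = ge.residual_diagnostics(fit)
            hits += d["within_band"]
        assert 0.90 < hits / reps <= 1.0

    def test_mean_deviance_residual_near_zero_when_well_specified(self):
        rng = np.random.default_rng(5)
        n = 500
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=n)})
        y = rng.poisson(np.exp(3 + 0.1 * X["x"])).astype(float)
        fit = ge.fit_loglinear(y, X, "poisson")
        d = ge.residual_diagnostics(fit)
        assert abs(d["mean_residual"]) < 0.1
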