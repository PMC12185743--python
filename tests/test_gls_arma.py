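"""Unit tests for the GLS/ARMA(1,1) core."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import linalg

from wrackscale.gls_arma import (
    ArmaParams,
    arma11_acf,
    arma11_marginal_variance,
    correlation_matrix,
    fit_gls,
    residual_acf,
    sample_acf,
)
from wrackscale.synthetic_coast import simulate_arma11


class TestArmaParams:
    @pytest.mark.parametrize("phi,theta", [(1.0, 0.0), (-1.2, 0.0), (np.nan, 0.0)])
    def test_nonstationary_phi_rejected(self, phi, theta):
        with pytest.raises(ValueError, match="stationarity"):
            ArmaParams(phi, theta)

    @pytest.mark.parametrize("theta", [1.0, -1.0, 2.5])
    def test_noninvertible_theta_rejected(self, theta):
        with pytest.raises(ValueError, match="invertibility"):
            ArmaParams(0.0, theta)


class TestAcf:
    def test_white_noise(self):
        assert np.array_equal(arma11_acf(ArmaParams(0, 0), 3), [1, 0, 0, 0])

    def test_ar1_limit(self):
        np.testing.assert_allclose(
            arma11_acf(ArmaParams(0.5, 0.0), 3), [1, 0.5, 0.25, 0.125], rtol=0, atol=0
        )

    def test_closed_form_value(self):
        # rho(1) = (1 + 0.15)(0.8) / (1 + 0.3 + 0.09) = 0.92/1.39
        rho = arma11_acf(ArmaParams(0.5, 0.3), 2)
        assert rho[1] == pytest.approx(0.92 / 1.39, abs=1e-12)
        assert rho[2] == pytest.approx(0.5 * 0.92 / 1.39, abs=1e-12)

    def test_matches_simulated_series(self):
        x = simulate_arma11(200_000, 0.5, 0.3, 1.0, seed=7)
        emp = sample_acf(x, 2)
        np.testing.assert_allclose(emp[1:], arma11_acf(ArmaParams(0.5, 0.3), 2)[1:], atol=0.02)


class TestCorrelationMatrix:
    def test_identity_at_zero(self):
        assert np.array_equal(correlation_matrix(ArmaParams(0, 0), 5), np.eye(5))

    def test_n2_offdiagonal(self):
        R = correlation_matrix(ArmaParams(0.5, 0.3), 2)
        assert R[0, 1] == pytest.approx(0.92 / 1.39, abs=1e-12)
        assert R[1, 0] == R[0, 1] and R[0, 0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_positive_definite(self, seed):
        r = np.random.default_rng(seed)
        params = ArmaParams(r.uniform(-0.95, 0.95), r.uniform(-0.95, 0.95))
        R = correlation_matrix(params, 50)
        assert np.linalg.eigvalsh(R).min() > 0


class TestFitGls:
    def test_ols_exact_line(self):
        x = np.arange(5.0)
        y = 1.0 + 2.0 * x
        fit = fit_gls(y, np.column_stack([np.ones(5), x]), ["b0", "b1"], mode="ols")
        np.testing.assert_allclose(fit.beta, [1.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(fit.residuals_raw, 0.0, atol=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_fixed_zero_params_equals_ols(self, seed):
        r = np.random.default_rng(seed)
        n, p = 40, 3
        X = np.column_stack([np.ones(n), r.normal(size=(n, p - 1))])
        y = X @ r.normal(size=p) + r.normal(size=n)
        gls = fit_gls(y, X, mode="gls", fixed_params=ArmaParams(0.0, 0.0))
        ols = fit_gls(y, X, mode="ols")
        np.testing.assert_allclose(gls.beta, ols.beta, atol=1e-8)
        np.testing.assert_allclose(gls.se, ols.se, atol=1e-8)
        np.testing.assert_allclose(gls.t_values, ols.t_values, atol=1e-8)

    def test_ols_matches_statsmodels(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 2.0, -0.5] + rng.normal(size=n)
        fit = fit_gls(y, X, mode="ols")
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-10)
        np.testing.assert_allclose(fit.t_values, ref.tvalues, atol=1e-8)
        np.testing.assert_allclose(fit.p_values, ref.pvalues, atol=1e-10)
        assert fit.f_value == pytest.approx(ref.fvalue, rel=1e-10)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-12)

    def test_f_equals_t_squared_single_predictor(self, rng):
        """Holds exactly for plug-in (fixed-params / OLS) standard errors; the
        estimated-GLS path inflates se for correlation-parameter uncertainty,
        so it is exercised with fixed params here."""
        n = 50
        x = rng.normal(size=n)
        y = 1 + 0.5 * x + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        for kw in (dict(mode="ols"), dict(mode="gls", fixed_params=ArmaParams(0.3, 0.1))):
            fit = fit_gls(y, X, **kw)
            assert fit.f_value == pytest.approx(fit.t_values[1] ** 2, abs=1e-8)

    def test_whitening_consistency(self, rng):
        """Manual Cholesky whitening + OLS reproduces beta and whitened RSS."""
        n = 80
        params = ArmaParams(0.6, 0.2)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [2.0, 1.0] + simulate_arma11(n, 0.6, 0.2, 1.0, seed=rng)
        fit = fit_gls(y, X, mode="gls", fixed_params=params)
        L = linalg.cholesky(correlation_matrix(params, n), lower=True)
        Xw = linalg.solve_triangular(L, X, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
        beta_w, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_w, atol=1e-10)
        rss_w = float(np.sum((yw - Xw @ beta_w) ** 2))
        assert fit.whitened_rss == pytest.approx(rss_w, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_loglik_never_below_zero_params(self, seed):
        r = np.random.default_rng(seed)
        n = 100
        X = np.column_stack([np.ones(n), r.normal(size=n)])
        y = X @ [1.0, 0.5] + simulate_arma11(n, 0.5, -0.2, 1.0, seed=r)
        fit = fit_gls(y, X, mode="gls")
        ll0 = fit_gls(y, X, mode="gls", fixed_params=ArmaParams(0, 0)).loglik
        assert fit.loglik >= ll0 - 1e-9

    def test_phi_recovery(self):
        """Mean phi-hat over replicates close to the generating value."""
        phis = []
        master = np.random.default_rng(5150)
        for _ in range(30):
            n = 250
            y = 10.0 + simulate_arma11(n, 0.6, 0.2, 1.0, seed=master)
            X = np.column_stack([np.ones(n), master.normal(size=n)])
            phis.append(fit_gls(y, X, mode="gls").arma.phi)
        assert abs(np.mean(phis) - 0.6) < 0.1

    def test_aic_bookkeeping(self, rng):
        """AIC uses k = p+3 (GLS) / p+1 (OLS); a noise column cannot lower -2ll."""
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 1.0] + rng.normal(size=n)
        fit = fit_gls(y, X, mode="gls", fixed_params=ArmaParams(0, 0))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * (2 + 3))
        ofit = fit_gls(y, X, mode="ols")
        assert ofit.aic == pytest.approx(-2 * ofit.loglik + 2 * (2 + 1))
        Xbig = np.column_stack([X, rng.normal(size=n)])
        big = fit_gls(y, Xbig, mode="ols")
        assert big.loglik >= ofit.loglik - 1e-9

    def test_collinear_columns_named(self, rng):
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = rng.normal(size=n)
        with pytest.raises(ValueError, match="collinear"):
            fit_gls(y, X, names=["intercept", "a", "b"], mode="ols")

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="n > n_coef"):
            fit_gls(np.ones(4), np.ones((4, 2)), mode="ols")

    def test_boundary_warning_flag(self):
        r = np.random.default_rng(0)
        n = 100
        X = np.column_stack([np.ones(n), r.normal(size=n)])
        y = X @ [1.0, 0.5] + r.normal(size=n)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_gls(y, X, mode="gls", fixed_params=ArmaParams(0.9994, 0.0))
        assert fit.boundary_warning
        # interior estimates carry no flag
        assert not fit_gls(y, X, mode="ols").boundary_warning


class TestResidualAcf:
    def test_white_noise_inside_band(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            n = 200
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = X @ [1.0, 0.5] + rng.normal(size=n)
            fit = fit_gls(y, X, mode="ols")
            d = residual_acf(fit, 1)
            if abs(d["acf_normalized"][1]) <= d["band"]:
                hits += 1
        assert hits >= 90  # ~95% expected

    def test_constant_residuals_error(self):
        x = np.arange(10.0)
        fit = fit_gls(2 * x + 1, np.column_stack([np.ones(10), x]), mode="ols")
        with pytest.raises(ValueError, match="degenerate|constant"):
            residual_acf(fit, 3)

    def test_structure(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [0.0, 1.0] + rng.normal(size=n)
        d = residual_acf(fit_gls(y, X, mode="ols"), 5)
        assert len(d["acf_normalized"]) == 6 and len(d["acf_raw"]) == 6
        assert d["acf_raw"][0] == 1.0
        assert d["band"] == pytest.approx(1.96 / np.sqrt(n))


class TestMarginalVariance:
    def test_closed_form(self):
        v = arma11_marginal_variance(ArmaParams(0.5, 0.3), 2.0)
        assert v == pytest.approx(4.0 * 1.39 / 0.75)
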