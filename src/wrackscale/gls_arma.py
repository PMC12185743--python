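"""Generalized least squares with ARMA(1,1) residual correlation.

The regression model is ``y = X beta + eta`` where ``eta`` is a mean-zero
stationary ARMA(1,1) process over an ordinal index (here, alongshore segment
order).  Estimation maximizes the Gaussian profile log-likelihood over
``(phi, theta)``; for fixed correlation parameters the GLS estimator is
obtained by Cholesky whitening.  A plain OLS mode (identity correlation) is
provided by the same code path.

Everything here is implemented from first principles on top of numpy/scipy
linear algebra; no regression library is called.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "ArmaParams",
    "GlsFit",
    "arma11_acf",
    "arma11_marginal_variance",
    "correlation_matrix",
    "fit_gls",
    "residual_acf",
    "sample_acf",
]

_BOUND = 0.9995  # optimizer box half-width for (phi, theta)
_BOUNDARY_FLAG = 0.999  # |estimate| beyond this raises the boundary warning flag


@dataclass(frozen=True)
class ArmaParams:
    """AR(1) and MA(1) coefficients of the residual process.

    Both must lie strictly inside (-1, 1): ``|phi| < 1`` for stationarity,
    ``|theta| < 1`` for invertibility.
    """

    phi: float
    theta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi) or abs(self.phi) >= 1.0:
            raise ValueError(
                f"phi={self.phi!r} violates the stationarity bound |phi| < 1"
            )
        if not np.isfinite(self.theta) or abs(self.theta) >= 1.0:
            raise ValueError(
                f"theta={self.theta!r} violates the invertibility bound |theta| < 1"
            )


def arma11_acf(params: ArmaParams, max_lag: int) -> np.ndarray:
    """Autocorrelation function of a stationary ARMA(1,1) process.

    rho(0) = 1,
    rho(1) = (1 + phi*theta) * (phi + theta) / (1 + 2*phi*theta + theta^2),
    rho(k) = phi * rho(k-1) for k >= 2.

    Returns an array of length ``max_lag + 1``.
    """
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    phi, theta = params.phi, params.theta
    rho = np.empty(max_lag + 1)
    rho[0] = 1.0
    if max_lag >= 1:
        denom = 1.0 + 2.0 * phi * theta + theta * theta
        rho[1] = (1.0 + phi * theta) * (phi + theta) / denom
        for k in range(2, max_lag + 1):
            rho[k] = phi * rho[k - 1]
    return rho


def arma11_marginal_variance(params: ArmaParams, innovation_sd: float) -> float:
    """Closed-form marginal variance sd^2 (1 + 2 phi theta + theta^2) / (1 - phi^2)."""
    phi, theta = params.phi, params.theta
    return (
        innovation_sd**2 * (1.0 + 2.0 * phi * theta + theta * theta) / (1.0 - phi * phi)
    )


def correlation_matrix(params: ArmaParams, n: int) -> np.ndarray:
    """n x n ARMA(1,1) correlation matrix over the unit-spaced ordinal index."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return linalg.toeplitz(arma11_acf(params, n - 1))


@dataclass
class GlsFit:
    """Result of a GLS (or OLS) linear-model fit.

    ``aic = -2 loglik + 2 k`` with ``k = n_coef + 3`` in GLS mode (phi, theta,
    sigma^2 all estimated) and ``k = n_coef + 1`` in OLS mode.
    """

    beta: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    sigma2: float
    arma: ArmaParams
    loglik: float
    aic: float
    f_value: float
    f_p_value: float
    r2: float | None
    residuals_raw: np.ndarray
    residuals_normalized: np.ndarray
    names: list[str]
    n: int
    mode: str
    boundary_warning: bool = False
    whitened_rss: float = field(default=float("nan"))

    @property
    def n_coef(self) -> int:
        return len(self.beta)

    @property
    def df_resid(self) -> int:
        return self.n - self.n_coef

    def coef_table(self) -> dict[str, dict[str, float]]:
        """Per-predictor estimate / se / t-value / p-value mapping."""
        return {
            name: {
                "estimate": float(b),
                "se": float(s),
                "t_value": float(t),
                "p_value": float(p),
            }
            for name, b, s, t, p in zip(
                self.names, self.beta, self.se, self.t_values, self.p_values
            )
        }


def _as_matrix(X: np.ndarray, names: list[str] | None) -> tuple[np.ndarray, list[str]]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("names length must match the number of design columns")
    return X, list(names)


def _name_collinear_pair(X: np.ndarray, names: list[str]) -> str:
    """Best-effort identification of a collinear column pair for error messages."""
    p = X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = X.std(axis=0)
        const = sd < 1e-12
        if const.sum() > 1:
            bad = [names[j] for j in np.flatnonzero(const)]
            return f"{bad[0]!r} and {bad[1]!r} (both constant)"
        C = np.corrcoef(X, rowvar=False)
    for i in range(p):
        for j in range(i + 1, p):
            if abs(C[i, j]) > 1.0 - 1e-10:
                return f"{names[i]!r} and {names[j]!r}"
    return "an unidentified column combination"


def _profile_loglik(
    z: np.ndarray, params: ArmaParams
) -> tuple[float, np.ndarray, float, np.ndarray, float]:
    """Profile log-likelihood for stacked [X | y] = z at fixed (phi, theta).

    Returns (loglik, beta_hat, sigma2_hat, whitened [X|y], logdet R).
    """
    n = z.shape[0]
    R = correlation_matrix(params, n)
    L = linalg.cholesky(R, lower=True, check_finite=False)
    zw = linalg.solve_triangular(L, z, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Xw, yw = zw[:, :-1], zw[:, -1]
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < Xw.shape[1]:
        raise np.linalg.LinAlgError("rank deficient")
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    sigma2 = rss / n
    if sigma2 <= 0.0:
        sigma2 = np.finfo(float).tiny
    loglik = -0.5 * n * math.log(2.0 * math.pi * sigma2) - 0.5 * logdet - 0.5 * n
    return loglik, beta, sigma2, zw, logdet


_COARSE_GRID = (-0.8, -0.4, 0.0, 0.4, 0.8)


def _optimize_arma(z: np.ndarray) -> tuple[ArmaParams, float]:
    """Maximize the profile likelihood over (phi, theta).

    Deterministic two-stage search: a coarse 5 x 5 grid (which always includes
    (0, 0)) followed by one bounded Nelder-Mead polish from the best grid
    point.  The polish can only improve on the grid optimum, so the fitted
    log-likelihood is never below the (0, 0) value.
    """

    def negll(v: np.ndarray) -> float:
        phi = float(np.clip(v[0], -_BOUND, _BOUND))
        theta = float(np.clip(v[1], -_BOUND, _BOUND))
        try:
            ll = _profile_loglik(z, ArmaParams(phi, theta))[0]
        except np.linalg.LinAlgError:
            return 1e12
        return -ll

    best_v, best_f = np.zeros(2), negll(np.zeros(2))
    for phi0 in _COARSE_GRID:
        for theta0 in _COARSE_GRID:
            v = np.array([phi0, theta0])
            f = negll(v)
            if f < best_f:
                best_v, best_f = v, f
    res = optimize.minimize(
        negll,
        best_v,
        method="Nelder-Mead",
        bounds=[(-_BOUND, _BOUND), (-_BOUND, _BOUND)],
        options={"fatol": 1e-8, "xatol": 1e-6, "maxfev": 600},
    )
    if res.fun <= best_f:
        best_v, best_f = res.x, res.fun
    phi = float(np.clip(best_v[0], -_BOUND, _BOUND))
    theta = float(np.clip(best_v[1], -_BOUND, _BOUND))
    return ArmaParams(phi, theta), -best_f


def _plugin_se_correction(
    z: np.ndarray, params: ArmaParams, cov_beta: np.ndarray
) -> np.ndarray | None:
    """Kackar-Harville-style additive correction for estimated (phi, theta).

    The plug-in covariance ``sigma2 (X' R^-1 X)^-1`` ignores the sampling
    variability of the correlation parameters; for predictors that vary
    smoothly along the order index this understates the standard errors by
    several percent.  Delta method: Var(beta-hat) gains ``D V D'`` where
    ``D = d beta-hat / d(phi, theta)`` (central differences) and ``V`` is the
    inverse observed information of the profile likelihood.  Returns the
    corrected covariance, or None when the information matrix is not usable
    (e.g. boundary estimates).
    """
    v0 = np.array([params.phi, params.theta])
    h = 0.08
    n = z.shape[0]
    p = z.shape[1] - 1

    def eval_at(v: np.ndarray):
        """(loglik, beta, diag plug-in cov) at clipped v."""
        pp = ArmaParams(float(np.clip(v[0], -_BOUND, _BOUND)),
                        float(np.clip(v[1], -_BOUND, _BOUND)))
        ll, beta, sigma2, zw, _ = _profile_loglik(z, pp)
        Xw = zw[:, :-1]
        a = np.diag(linalg.inv(Xw.T @ Xw)) * sigma2 * n / (n - p)
        return ll, beta, a

    try:
        e0, e1 = np.eye(2)
        c0 = eval_at(v0)
        cpp = eval_at(v0 + h * e0)
        cpm = eval_at(v0 - h * e0)
        ctp = eval_at(v0 + h * e1)
        ctm = eval_at(v0 - h * e1)
        cx1 = eval_at(v0 + h * e0 + h * e1)
        cx2 = eval_at(v0 + h * e0 - h * e1)
        cx3 = eval_at(v0 - h * e0 + h * e1)
        cx4 = eval_at(v0 - h * e0 - h * e1)

        # observed information of the profile likelihood
        H = np.empty((2, 2))
        H[0, 0] = (cpp[0] - 2 * c0[0] + cpm[0]) / h**2
        H[1, 1] = (ctp[0] - 2 * c0[0] + ctm[0]) / h**2
        H[0, 1] = H[1, 0] = (cx1[0] - cx2[0] - cx3[0] + cx4[0]) / (4 * h**2)
        info = -H
        if np.linalg.eigvalsh(info).min() <= 0:
            return None
        V = np.linalg.inv(info)

        # first-order: variability of beta-hat through v-hat
        D = np.column_stack(
            [(cpp[1] - cpm[1]) / (2 * h), (ctp[1] - ctm[1]) / (2 * h)]
        )
        first = D @ V @ D.T

        # second-order (Jensen): plug-in cov is convex in v near the optimum
        d2a = np.empty((2, 2, p))
        d2a[0, 0] = (cpp[2] - 2 * c0[2] + cpm[2]) / h**2
        d2a[1, 1] = (ctp[2] - 2 * c0[2] + ctm[2]) / h**2
        d2a[0, 1] = d2a[1, 0] = (cx1[2] - cx2[2] - cx3[2] + cx4[2]) / (4 * h**2)
        jensen = 0.5 * np.einsum("kl,klj->j", V, d2a)

        out = cov_beta + first
        out[np.diag_indices(p)] += np.clip(jensen, 0.0, None)
        return out
    except (np.linalg.LinAlgError, ValueError):
        return None


def fit_gls(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    mode: str = "gls",
    fixed_params: ArmaParams | None = None,
    adjust_se: bool = True,
) -> GlsFit:
    """Fit a linear model with ARMA(1,1)-correlated (or iid) errors.

    Parameters
    ----------
    y
        Response vector, ordered by the alongshore index.
    X
        Design matrix (include the intercept column explicitly), same order.
    mode
        ``"gls"`` estimates (phi, theta) by profile maximum likelihood
        (or uses ``fixed_params`` when given); ``"ols"`` forces the identity
        correlation and additionally reports r^2.
    fixed_params
        Skip the correlation-parameter optimization and condition on these
        values (GLS mode only).

    adjust_se
        When (phi, theta) are estimated, add the delta-method correction for
        their sampling uncertainty to the coefficient covariance (see
        ``_plugin_se_correction``).  Ignored for OLS / fixed-params fits,
        whose plug-in errors are exact.

    Notes
    -----
    Standard errors use the small-sample scaling ``sigma2 * n/(n-p)`` on the
    whitened Gram inverse (plus the plug-in correction when estimating the
    correlation); t statistics are referred to a t distribution on ``n - p``
    degrees of freedom.  The overall regression F compares the
    fitted mean structure to an intercept-only model re-whitened at the same
    (phi, theta), on whitened sums of squares with ``(p-1, n-p)`` degrees of
    freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    X, names = _as_matrix(X, names)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have incompatible lengths")
    if mode not in ("gls", "ols"):
        raise ValueError(f"unknown mode {mode!r}")
    if n <= p + 2:
        raise ValueError(f"need n > n_coef + 2 observations (n={n}, n_coef={p})")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("design contains missing or non-finite values")

    z = np.column_stack([X, y])

    if mode == "ols":
        params = ArmaParams(0.0, 0.0)
    elif fixed_params is not None:
        params = fixed_params
    else:
        params, _ = _optimize_arma(z)

    try:
        loglik, beta, sigma2, zw, _ = _profile_loglik(z, params)
    except np.linalg.LinAlgError:
        pair = _name_collinear_pair(X, names)
        raise ValueError(
            f"singular whitened design (X' R^-1 X): collinear columns {pair}"
        ) from None

    Xw, yw = zw[:, :-1], zw[:, -1]
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)

    XtX = Xw.T @ Xw
    try:
        cov_unscaled = linalg.inv(XtX)
    except linalg.LinAlgError:
        pair = _name_collinear_pair(X, names)
        raise ValueError(
            f"singular whitened design (X' R^-1 X): collinear columns {pair}"
        ) from None

    df = n - p
    cov_beta = cov_unscaled * sigma2 * n / df
    if mode == "gls" and fixed_params is None and adjust_se:
        adjusted = _plugin_se_correction(z, params, cov_beta)
        if adjusted is not None:
            cov_beta = adjusted
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_values = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p_values = 2.0 * stats.t.sf(np.abs(t_values), df)

    # Overall F against the intercept-only null, refit at the same (phi, theta).
    has_intercept = any(np.allclose(X[:, j], X[0, j]) and X[0, j] != 0 for j in range(p))
    if p > 1 and has_intercept:
        icol = next(
            j for j in range(p) if np.allclose(X[:, j], X[0, j]) and X[0, j] != 0
        )
        x0w = Xw[:, icol]
        b0 = float(x0w @ yw) / float(x0w @ x0w)
        r0 = yw - x0w * b0
        rss0 = float(r0 @ r0)
        f_value = max(0.0, ((rss0 - rss) / (p - 1)) / (rss / df))
        f_p_value = float(stats.f.sf(f_value, p - 1, df))
    else:
        f_value, f_p_value = float("nan"), float("nan")

    if mode == "ols":
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        k = p + 1
    else:
        r2 = None
        k = p + 3
    aic = -2.0 * loglik + 2.0 * k

    residuals_raw = y - X @ beta
    residuals_normalized = resid_w / math.sqrt(sigma2)

    boundary = max(abs(params.phi), abs(params.theta)) > _BOUNDARY_FLAG
    if boundary:
        warnings.warn(
            "ARMA parameter estimate on the stationarity boundary "
            f"(phi={params.phi:.4f}, theta={params.theta:.4f})",
            stacklevel=2,
        )

    return GlsFit(
        beta=beta,
        se=se,
        t_values=t_values,
        p_values=np.asarray(p_values),
        sigma2=sigma2,
        arma=params,
        loglik=loglik,
        aic=aic,
        f_value=f_value,
        f_p_value=f_p_value,
        r2=r2,
        residuals_raw=residuals_raw,
        residuals_normalized=residuals_normalized,
        names=names,
        n=n,
        mode=mode,
        boundary_warning=boundary,
        whitened_rss=rss,
    )


def sample_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag (biased, standard normalization)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < max_lag + 2:
        raise ValueError("series too short for requested max_lag")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= n * (1e-12 * max(1.0, float(np.abs(x).max()))) ** 2:
        raise ValueError("degenerate input: series is constant, ACF undefined")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        out[k] = float(xc[k:] @ xc[:-k]) / denom
    return out


def residual_acf(fit: GlsFit, max_lag: int) -> dict[str, object]:
    """Sample ACFs of the fit's normalized and raw residuals.

    Returns the two ACF arrays plus the +-1.96/sqrt(n) white-noise band.  This
    is the diagnostic used to check that the ARMA structure absorbed the
    alongshore correlation: the raw-residual ACF shows the correlation, the
    normalized (whitened) one should sit inside the band.
    """
    band = 1.96 / math.sqrt(fit.n)
    return {
        "acf_normalized": sample_acf(fit.residuals_normalized, max_lag),
        "acf_raw": sample_acf(fit.residuals_raw, max_lag),
        "band": band,
        "n": fit.n,
    }
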