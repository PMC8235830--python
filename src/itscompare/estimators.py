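"""Six estimators for segmented regression with lag-1 autocorrelated errors.

All estimators share the mean model encoded in a
:class:`~itscompare.design.SegmentedDesign` and differ only in how they
handle the AR(1) error structure:

``OLS``
    no adjustment; model-based standard errors, t(N-p) inference.
``NW``
    OLS coefficients with a Newey-West (Bartlett kernel, maximum lag 1)
    heteroskedasticity-and-autocorrelation-consistent sandwich,
    small-sample factor N/(N-p), t(N-p) inference.
``PW``
    Prais-Winsten iterated feasible GLS: the lag-1 residual
    autocorrelation is plugged into the quasi-differencing transform
    (first row retained, scaled by sqrt(1-rho^2)) until the estimate of
    rho stabilises.
``REML`` / ``REML-Satt``
    restricted maximum likelihood for rho with sigma^2 profiled out;
    z-based inference, or t with Satterthwaite degrees of freedom
    (floored at 2) when the small-sample flag is set.
``ARIMA``
    exact Gaussian maximum likelihood for regression with AR(1) errors
    (stationary initial condition), z-based inference with standard
    errors from the outer product of gradients by default or,
    optionally, the observed information (numerical Hessian).

Every fit returns a uniform :class:`FitResult`.  Estimates of rho on
the boundary of (-1, 1) are flagged ``valid=False`` rather than
clamped, implementing the exclusion rule applied throughout the
comparison pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats

from .ar1 import log_det_scale, whiten
from .design import SegmentedDesign

__all__ = [
    "FitResult",
    "EstimationError",
    "fit_ols",
    "fit_newey_west",
    "fit_prais_winsten",
    "reml_profile_loglik",
    "fit_reml",
    "satterthwaite_df",
    "fit_arima",
    "fit_method",
    "METHODS",
]

METHODS = ("OLS", "NW", "PW", "REML", "REML-Satt", "ARIMA")

ALPHA = 0.05
RHO_BOUND_DELTA = 1e-6     # optimisation restricted to |rho| <= 1 - delta
RHO_BOUNDARY_MARGIN = 1e-5  # |rho_hat| >= 1 - margin counts as a boundary hit


class EstimationError(ValueError):
    """Raised for structurally infeasible fits (e.g. N <= p)."""


@dataclass
class FitResult:
    """Uniform per-method fit record.

    ``df`` holds the inference degrees of freedom per coefficient;
    ``inf`` encodes normal (z) inference.  ``rho_hat`` is ``None`` for
    methods that do not estimate autocorrelation as a model parameter
    (OLS, NW).  ``valid`` is ``False`` whenever the autocorrelation
    estimate falls outside the open interval (-1, 1) (boundary hits
    included); ``converged`` is ``False`` on iteration/optimiser
    failure.  ``degenerate`` marks zero-residual-variance fits whose
    p-values are reported as NaN.
    """

    method: str
    beta: np.ndarray
    se: np.ndarray
    df: np.ndarray
    ci: np.ndarray  # (p, 2)
    p: np.ndarray
    sigma2_hat: float
    rho_hat: Optional[float] = None
    rho_ci: Optional[Tuple[float, float]] = None
    rmse: Optional[float] = None
    converged: bool = True
    valid: bool = True
    n_iter: int = 0
    degenerate: bool = False
    internals: Optional["RemlInternals"] = field(default=None, repr=False)



def _is_degenerate(sigma2: float, y: np.ndarray) -> bool:
    """Zero residual variance up to floating-point rounding of the fit."""
    scale = max(1.0, float(y @ y) / len(y))
    return bool(sigma2 <= 1e-24 * scale)

def _check_shapes(design: SegmentedDesign, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    n, p = design.X.shape
    if len(y) != n:
        raise EstimationError(f"y has length {len(y)}, design has {n} rows")
    if n <= p:
        raise EstimationError(f"need N > p, got N={n}, p={p}")
    return y


def _inference(beta: np.ndarray, se: np.ndarray, df: np.ndarray,
               degenerate: bool) -> tuple[np.ndarray, np.ndarray]:
    """95% CIs and two-sided p-values; t with df entries (inf -> z)."""
    if degenerate:
        ci = np.column_stack([beta, beta])
        return ci, np.full_like(beta, np.nan)
    q = stats.t.ppf(1 - ALPHA / 2, df)
    ci = np.column_stack([beta - q * se, beta + q * se])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * stats.t.sf(np.abs(tval), df)
    return ci, p


def _ols_core(X: np.ndarray, y: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid


def fit_ols(design: SegmentedDesign, y: np.ndarray) -> FitResult:
    """Ordinary least squares with model-based standard errors.

    sigma2_hat = SSR/(N-p); ``rmse`` (its square root) is the
    standardisation divisor used throughout the comparison stage.
    Zero-residual data are permitted and flagged ``degenerate``.
    """
    y = _check_shapes(design, y)
    X = design.X
    n, p = X.shape
    beta, resid = _ols_core(X, y)
    sigma2 = float(resid @ resid) / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    degenerate = _is_degenerate(sigma2, y)
    df = np.full(p, n - p, dtype=float)
    ci, pvals = _inference(beta, se, df, degenerate)
    return FitResult(
        method="OLS", beta=beta, se=se, df=df, ci=ci, p=pvals,
        sigma2_hat=sigma2, rmse=float(np.sqrt(sigma2)), degenerate=degenerate,
    )


def fit_newey_west(design: SegmentedDesign, y: np.ndarray) -> FitResult:
    """OLS coefficients with lag-1 Newey-West standard errors.

    Bartlett kernel with maximum lag 1 puts weight 1/2 on the lag-1
    residual cross-products; the sandwich is scaled by the small-sample
    factor N/(N-p) and inference uses t(N-p).
    """
    y = _check_shapes(design, y)
    X = design.X
    n, p = X.shape
    ols = fit_ols(design, y)
    beta = ols.beta
    resid = y - X @ beta

    xe = X * resid[:, None]
    meat = xe.T @ xe
    lag1 = xe[1:].T @ xe[:-1]
    meat = meat + 0.5 * (lag1 + lag1.T)

    bread = np.linalg.inv(X.T @ X)
    cov = bread @ meat @ bread * (n / (n - p))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    df = np.full(p, n - p, dtype=float)
    ci, pvals = _inference(beta, se, df, ols.degenerate)
    return FitResult(
        method="NW", beta=beta, se=se, df=df, ci=ci, p=pvals,
        sigma2_hat=ols.sigma2_hat, rmse=ols.rmse, degenerate=ols.degenerate,
    )


def _gls_at_rho(X: np.ndarray, y: np.ndarray, rho: float):
    """GLS via the whitening transform: returns beta, whitened residuals, Xw."""
    Xw = whiten(X, rho)
    yw = whiten(y, rho)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    return beta, yw - Xw @ beta, Xw


def _lag1_autocorr(e: np.ndarray) -> float:
    denom = float(e @ e)
    if denom == 0.0:
        return 0.0
    return float(e[1:] @ e[:-1]) / denom


def fit_prais_winsten(design: SegmentedDesign, y: np.ndarray, tol: float = 1e-6,
                      max_iter: int = 100, fixed_rho: Optional[float] = None
                      ) -> FitResult:
    """Prais-Winsten iterated feasible GLS.

    Alternates (a) lag-1 sample autocorrelation of the original-scale
    residuals and (b) OLS on quasi-differenced data until rho moves by
    less than ``tol``.  ``fixed_rho`` skips the iteration and performs a
    single GLS step at a known rho (used for oracle cross-checks).  The
    whitening is the identity at rho=0, so a fit with ``fixed_rho=0``
    reproduces OLS exactly.
    """
    y = _check_shapes(design, y)
    X = design.X
    n, p = X.shape

    if fixed_rho is not None:
        rho = float(fixed_rho)
        beta, rw, Xw = _gls_at_rho(X, y, rho)
        n_iter = 0
        converged = True
    else:
        beta, resid = _ols_core(X, y)
        rho = _lag1_autocorr(resid)
        converged = False
        n_iter = 0
        rw = Xw = None
        for n_iter in range(1, max_iter + 1):
            if abs(rho) >= 1 - RHO_BOUNDARY_MARGIN:
                break
            beta, rw, Xw = _gls_at_rho(X, y, rho)
            rho_new = _lag1_autocorr(y - X @ beta)
            if abs(rho_new - rho) < tol:
                rho = rho_new
                converged = True
                break
            rho = rho_new
        if converged and abs(rho) < 1 - RHO_BOUNDARY_MARGIN:
            # refresh the GLS quantities at the final rho
            beta, rw, Xw = _gls_at_rho(X, y, rho)

    valid = abs(rho) < 1 - RHO_BOUNDARY_MARGIN

    if Xw is not None:
        sigma2 = float(rw @ rw) / (n - p)
        cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        sigma2 = np.nan
        se = np.full(p, np.nan)

    degenerate = bool(np.isfinite(sigma2)) and _is_degenerate(sigma2, y)
    df = np.full(p, n - p, dtype=float)
    ci, pvals = _inference(beta, se, df, degenerate)
    return FitResult(
        method="PW", beta=beta, se=se, df=df, ci=ci, p=pvals,
        sigma2_hat=sigma2, rho_hat=float(rho), converged=converged or fixed_rho is not None,
        valid=valid, n_iter=n_iter, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# REML


def reml_profile_loglik(rho: float, design: SegmentedDesign, y: np.ndarray) -> float:
    """Restricted log-likelihood at ``rho`` with sigma^2 profiled out.

    Up to an additive constant:
        -0.5 * [ (N-p) log sigma2_hat(rho) + log det V(rho)
                 + log det(X' V(rho)^-1 X) ]
    with V the AR(1) covariance scale and sigma2_hat(rho) the GLS
    residual sum of squares divided by N-p.  Computed via the exact
    whitening transform; log det V = -log(1-rho^2).
    """
    if not abs(rho) < 1:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    y = _check_shapes(design, y)
    X = design.X
    n, p = X.shape
    _, rw, Xw = _gls_at_rho(X, y, rho)
    s2 = float(rw @ rw) / (n - p)
    _, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
    return -0.5 * ((n - p) * np.log(s2) + log_det_scale(rho, n) + logdet_xtx)


def _reml_full_loglik(sigma2: float, rho: float, design: SegmentedDesign,
                      y: np.ndarray) -> float:
    """Restricted log-likelihood as a function of both variance parameters."""
    X = design.X
    n, p = X.shape
    _, rw, Xw = _gls_at_rho(X, y, rho)
    s = float(rw @ rw)
    _, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
    return -0.5 * ((n - p) * np.log(sigma2) + log_det_scale(rho, n)
                   + logdet_xtx + s / sigma2)


@dataclass
class RemlInternals:
    """Quantities needed for Satterthwaite degrees of freedom.

    ``varcov_varparams`` is the asymptotic covariance of (sigma2_hat,
    rho_hat) from the observed REML information (1x1 when rho was held
    fixed).
    """

    design: SegmentedDesign
    y: np.ndarray
    sigma2: float
    rho: float
    rho_fixed: bool
    varcov_varparams: np.ndarray


def _numeric_hessian(f, x0: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with per-coordinate steps."""
    k = len(x0)
    h = np.diag(steps)
    H = np.empty((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                H[i, i] = (f(x0 + h[i]) - 2 * f0 + f(x0 - h[i])) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + h[i] + h[j]) - f(x0 + h[i] - h[j])
                    - f(x0 - h[i] + h[j]) + f(x0 - h[i] - h[j])
                ) / (4 * steps[i] * steps[j])
    return H


def _reml_varparam_cov(design: SegmentedDesign, y: np.ndarray, sigma2: float,
                       rho: float, rho_fixed: bool) -> np.ndarray:
    """Inverse observed information of the restricted likelihood."""
    if rho_fixed:
        def f1(x):
            return _reml_full_loglik(x[0], rho, design, y)
        steps = np.array([sigma2 * 1.2e-4])
        H = _numeric_hessian(f1, np.array([sigma2]), steps)
    else:
        def f2(x):
            return _reml_full_loglik(x[0], x[1], design, y)
        rho_step = min(1.2e-4 * (1 + abs(rho)), (1 - abs(rho)) / 3)
        steps = np.array([sigma2 * 1.2e-4, rho_step])
        H = _numeric_hessian(f2, np.array([sigma2, rho]), steps)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular REML information matrix") from exc
    if not np.all(np.isfinite(cov)):
        raise EstimationError("singular REML information matrix")
    return cov


def satterthwaite_df(contrast: np.ndarray, internals: RemlInternals) -> float:
    """Satterthwaite effective degrees of freedom for c'beta_hat.

    nu = 2 * Var(c'beta_hat)^2 / (g' A g) where g is the gradient of
    Var(c'beta_hat) with respect to the variance parameters (sigma2,
    rho) and A their asymptotic covariance from the REML information.
    The result is returned unfloored; the caller applies the floor.
    """
    c = np.asarray(contrast, dtype=float)
    X = internals.design.X

    def var_of_contrast(sigma2: float, rho: float) -> float:
        Xw = whiten(X, rho)
        cov_beta = sigma2 * np.linalg.inv(Xw.T @ Xw)
        return float(c @ cov_beta @ c)

    v0 = var_of_contrast(internals.sigma2, internals.rho)
    g_sigma2 = v0 / internals.sigma2  # Var is linear in sigma2
    if internals.rho_fixed:
        g = np.array([g_sigma2])
    else:
        h = min(1e-5 * (1 + abs(internals.rho)), (1 - abs(internals.rho)) / 3)
        g_rho = (var_of_contrast(internals.sigma2, internals.rho + h)
                 - var_of_contrast(internals.sigma2, internals.rho - h)) / (2 * h)
        g = np.array([g_sigma2, g_rho])
    denom = float(g @ internals.varcov_varparams @ g)
    if denom <= 0:
        raise EstimationError("non-positive Satterthwaite denominator "
                              "(degenerate information matrix)")
    return 2.0 * v0 * v0 / denom


def fit_reml(design: SegmentedDesign, y: np.ndarray, satterthwaite: bool = False,
             fixed_rho: Optional[float] = None, df_floor: float = 2.0) -> FitResult:
    """REML estimation of rho with GLS coefficients.

    rho maximises the profiled restricted log-likelihood over
    (-1+delta, 1-delta); coefficients and standard errors come from GLS
    at rho_hat with the REML variance (divisor N-p).  Without the
    Satterthwaite flag, inference is normal-based (z); with it,
    per-coefficient Satterthwaite degrees of freedom are used, floored
    at ``df_floor``.  A Wald confidence interval for rho (from the
    curvature of the profile likelihood, truncated to (-1, 1)) is
    attached.  Boundary solutions are flagged ``valid=False``.
    """
    y = _check_shapes(design, y)
    X = design.X
    n, p = X.shape
    method = "REML-Satt" if satterthwaite else "REML"

    converged = True
    if fixed_rho is not None:
        rho = float(fixed_rho)
    else:
        lo, hi = -1 + RHO_BOUND_DELTA, 1 - RHO_BOUND_DELTA
        res = optimize.minimize_scalar(
            lambda r: -reml_profile_loglik(r, design, y),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        rho = float(res.x)
        converged = bool(res.success)
    valid = abs(rho) < 1 - RHO_BOUNDARY_MARGIN

    beta, rw, Xw = _gls_at_rho(X, y, rho)
    sigma2 = float(rw @ rw) / (n - p)
    degenerate = _is_degenerate(sigma2, y)
    if degenerate:
        se = np.zeros(p)
    else:
        cov_beta = sigma2 * np.linalg.inv(Xw.T @ Xw)
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))

    rho_ci = None
    if fixed_rho is None and valid and not degenerate:
        h = 1e-4 * (1 + abs(rho))
        h = min(h, (1 - abs(rho)) / 2) or 1e-8
        ll = reml_profile_loglik
        curv = (ll(rho + h, design, y) - 2 * ll(rho, design, y)
                + ll(rho - h, design, y)) / h**2
        if curv < 0:
            se_rho = float(np.sqrt(-1.0 / curv))
            z = stats.norm.ppf(1 - ALPHA / 2)
            rho_ci = (max(rho - z * se_rho, -1.0), min(rho + z * se_rho, 1.0))

    internals = None
    if satterthwaite and not degenerate and valid:
        varcov = _reml_varparam_cov(design, y, sigma2, rho, fixed_rho is not None)
        internals = RemlInternals(design=design, y=y, sigma2=sigma2, rho=rho,
                                  rho_fixed=fixed_rho is not None,
                                  varcov_varparams=varcov)
        df = np.empty(p)
        for j in range(p):
            c = np.zeros(p)
            c[j] = 1.0
            df[j] = max(satterthwaite_df(c, internals), df_floor)
    else:
        df = np.full(p, np.inf)

    ci, pvals = _inference(beta, se, df, degenerate)
    return FitResult(
        method=method, beta=beta, se=se, df=df, ci=ci, p=pvals,
        sigma2_hat=sigma2, rho_hat=float(rho), rho_ci=rho_ci,
        converged=converged, valid=valid, degenerate=degenerate,
        internals=internals,
    )


# ---------------------------------------------------------------------------
# ARIMA(1,0,0) with regressors: exact Gaussian maximum likelihood


def _arima_loglik_contributions(theta: np.ndarray, X: np.ndarray,
                                y: np.ndarray) -> np.ndarray:
    """Per-observation exact log-likelihood via prediction-error form.

    theta = (beta..., rho, sigma2).  The first observation is evaluated
    under the stationary distribution N(x_1'beta, sigma2/(1-rho^2));
    subsequent observations condition on the previous error.
    """
    p = X.shape[1]
    beta, rho, sigma2 = theta[:p], theta[p], theta[p + 1]
    if not (abs(rho) < 1) or sigma2 <= 0:
        return np.full(len(y), -np.inf)
    e = y - X @ beta
    v = np.full(len(y), sigma2)
    v[0] = sigma2 / (1 - rho**2)
    innov = e.copy()
    innov[1:] = e[1:] - rho * e[:-1]
    return -0.5 * (np.log(2 * np.pi * v) + innov**2 / v)


def fit_arima(design: SegmentedDesign, y: np.ndarray,
              se_method: str = "opg") -> FitResult:
    """Regression with AR(1) errors by exact Gaussian maximum likelihood.

    The likelihood is profiled: for each rho, the GLS coefficients and
    the ML variance (divisor N) are optimal, reducing the search to a
    bounded scalar problem.  Standard errors default to the outer
    product of per-observation score vectors (the covariance the
    classical AR(1)-regression software computes by default);
    ``se_method='hessian'`` switches to the observed information
    (numerical Hessian of the full log-likelihood).  Both give z-based
    confidence intervals and p-values.
    """
    if se_method not in ("hessian", "opg"):
        raise ValueError(f"se_method must be 'hessian' or 'opg', got {se_method!r}")
    y = _check_shapes(design, y)
    X = design.X
    n, p = X.shape

    def neg_profile(rho: float) -> float:
        _, rw, _ = _gls_at_rho(X, y, rho)
        s2 = float(rw @ rw) / n
        if s2 <= 0:
            return np.inf
        return 0.5 * (n * np.log(s2) + log_det_scale(rho, n))

    lo, hi = -1 + RHO_BOUND_DELTA, 1 - RHO_BOUND_DELTA
    res = optimize.minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    rho = float(res.x)
    converged = bool(res.success)
    valid = abs(rho) < 1 - RHO_BOUNDARY_MARGIN

    beta, rw, _ = _gls_at_rho(X, y, rho)
    sigma2 = float(rw @ rw) / n
    degenerate = _is_degenerate(sigma2, y)

    if degenerate:
        se = np.zeros(p)
    else:
        theta = np.concatenate([beta, [rho, sigma2]])

        if se_method == "hessian":
            def total_ll(th):
                return float(np.sum(_arima_loglik_contributions(th, X, y)))
            scale = np.concatenate([
                np.maximum(np.abs(beta), 1.0) * 1.2e-4,
                [1.2e-4 * (1 + abs(rho)), sigma2 * 1.2e-4],
            ])
            H = _numeric_hessian(total_ll, theta, scale)
            try:
                cov = np.linalg.inv(-H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(-H)
        else:
            k = len(theta)
            scores = np.zeros((n, k))
            for j in range(k):
                h = 1e-6 * max(abs(theta[j]), 1.0)
                up, dn = theta.copy(), theta.copy()
                up[j] += h
                dn[j] -= h
                scores[:, j] = (_arima_loglik_contributions(up, X, y)
                                - _arima_loglik_contributions(dn, X, y)) / (2 * h)
            opg = scores.T @ scores
            try:
                cov = np.linalg.inv(opg)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(opg)
        diag = np.diag(cov)[:p]
        if np.any(~np.isfinite(diag)) or np.any(diag < 0):
            converged = False
            se = np.full(p, np.nan)
        else:
            se = np.sqrt(diag)

    df = np.full(p, np.inf)
    ci, pvals = _inference(beta, se, df, degenerate)
    return FitResult(
        method="ARIMA", beta=beta, se=se, df=df, ci=ci, p=pvals,
        sigma2_hat=sigma2, rho_hat=float(rho), converged=converged,
        valid=valid, degenerate=degenerate,
    )


def fit_method(method: str, design: SegmentedDesign, y: np.ndarray, **kwargs) -> FitResult:
    """Dispatch a fit by method name (one of :data:`METHODS`)."""
    dispatch = {
        "OLS": fit_ols,
        "NW": fit_newey_west,
        "PW": fit_prais_winsten,
        "REML": lambda d, v, **kw: fit_reml(d, v, satterthwaite=False, **kw),
        "REML-Satt": lambda d, v, **kw: fit_reml(d, v, satterthwaite=True, **kw),
        "ARIMA": fit_arima,
    }
    if method not in dispatch:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return dispatch[method](design, y, **kwargs)
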