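"""Independent brute-force oracles used only by the tests.

Everything here works from first principles with dense linear algebra
(explicit normal equations, dense covariance inverses and determinants,
literal double sums), deliberately avoiding the whitening-transform
code paths of the package under test.
"""

import numpy as np
from scipy import optimize


def dense_ar1_scale(rho: float, n: int) -> np.ndarray:
    """sigma2-free AR(1) covariance scale: rho**|i-j| / (1 - rho**2)."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :]) / (1.0 - rho**2)


def normal_equation_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Explicit solve of X'X b = X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def dense_gls(X: np.ndarray, y: np.ndarray, rho: float):
    """GLS with an explicit dense AR(1) covariance inverse.

    Returns (beta, se, sigma2_hat) with the REML-style divisor N - p.
    """
    n, p = X.shape
    V = dense_ar1_scale(rho, n)
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    r = y - X @ beta
    sigma2 = float(r @ Vinv @ r) / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(A)))
    return beta, se, sigma2


def dense_reml_loglik(rho: float, X: np.ndarray, y: np.ndarray) -> float:
    """Literal restricted log-likelihood with dense determinants."""
    n, p = X.shape
    V = dense_ar1_scale(rho, n)
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    r = y - X @ beta
    s2 = float(r @ Vinv @ r) / (n - p)
    _, ld_v = np.linalg.slogdet(V)
    _, ld_a = np.linalg.slogdet(A)
    return -0.5 * ((n - p) * np.log(s2) + ld_v + ld_a)


def dense_reml_rho(X: np.ndarray, y: np.ndarray, bound: float = 1 - 1e-6) -> float:
    """REML rho by bounded maximisation of the dense restricted likelihood."""
    res = optimize.minimize_scalar(lambda r: -dense_reml_loglik(r, X, y),
                                   bounds=(-bound, bound), method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


def newey_west_se(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lag-1 Bartlett HAC standard errors via an explicit double sum."""
    n, p = X.shape
    beta = normal_equation_ols(X, y)
    e = y - X @ beta
    S = np.zeros((p, p))
    for t in range(n):
        S += e[t] * e[t] * np.outer(X[t], X[t])
    for t in range(1, n):  # Bartlett weight 1 - 1/(L+1) = 1/2 at lag 1
        cross = np.outer(X[t], X[t - 1]) + np.outer(X[t - 1], X[t])
        S += 0.5 * e[t] * e[t - 1] * cross
    bread = np.linalg.inv(X.T @ X)
    cov = bread @ S @ bread * (n / (n - p))
    return np.sqrt(np.diag(cov))


def iid_restricted_loglik(X: np.ndarray, y: np.ndarray) -> float:
    """Restricted log-likelihood with identity covariance (rho = 0)."""
    n, p = X.shape
    beta = normal_equation_ols(X, y)
    r = y - X @ beta
    s2 = float(r @ r) / (n - p)
    _, ld_a = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(s2) + ld_a)


def huitema_mckean_design(n: int, t_i: int) -> np.ndarray:
    """Textbook segmented design built element by element from the rules."""
    rows = []
    for t in range(1, n + 1):
        d = 1.0 if t >= t_i else 0.0
        rows.append([1.0, float(t), d, (t - t_i) * d if t > t_i else 0.0])
    return np.array(rows)
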