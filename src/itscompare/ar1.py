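"""Stationary lag-1 autoregressive error structure.

With innovation variance ``sigma2`` and coefficient ``rho`` in (-1, 1),
the errors e_t = rho * e_{t-1} + w_t have stationary covariance
``sigma2 * V(rho)`` where ``V = R / (1 - rho**2)`` and ``R_ij =
rho**|i-j|`` is the correlation matrix.  Quasi-differencing (the
Prais-Winsten transform) whitens this structure exactly, which every
generalised estimator in this package exploits; the dense matrices here
exist for the structure itself and for brute-force cross-checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["correlation_matrix", "covariance_scale", "whiten", "log_det_scale"]


def correlation_matrix(rho: float, n: int) -> np.ndarray:
    """The n x n matrix with entries rho**|i-j| (identity at rho=0)."""
    if not abs(rho) < 1:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def covariance_scale(rho: float, n: int) -> np.ndarray:
    """V(rho) = R(rho) / (1 - rho**2): errors have covariance sigma2 * V."""
    return correlation_matrix(rho, n) / (1.0 - rho**2)


def log_det_scale(rho: float, n: int) -> float:
    """log det V(rho) = -log(1 - rho**2), independent of n."""
    if not abs(rho) < 1:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    return -float(np.log1p(-rho * rho))


def whiten(a: np.ndarray, rho: float) -> np.ndarray:
    """Apply the Prais-Winsten transform P along axis 0.

    P has first row sqrt(1-rho**2)*e_1 and subsequent rows
    e_t - rho*e_{t-1}; it satisfies P V P' = I, so OLS on transformed
    data is exact GLS under the AR(1) structure.  At rho=0 the input is
    returned unchanged (bit-for-bit).
    """
    if not abs(rho) < 1:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    a = np.asarray(a, dtype=float)
    if rho == 0.0:
        return a
    out = a.copy()
    out[0] = np.sqrt(1.0 - rho * rho) * a[0]
    out[1:] = a[1:] - rho * a[:-1]
    return out
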