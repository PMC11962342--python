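"""Two-equation seemingly unrelated regression by feasible GLS.

The cost and effect equations share no parameters but their errors
correlate (sicker patients cost more and gain fewer QALYs), so joint
feasible generalized least squares is more efficient than
equation-by-equation OLS and — because each equation keeps its own
baseline covariate — adjusts incremental costs and effects for baseline
imbalance at the same time.

Estimation is two-step FGLS: OLS per equation, residual cross-covariance
estimated with denominator n, then GLS on the stacked system.  With
identical regressor matrices in both equations FGLS collapses to OLS
exactly (the classical degeneracy), which doubles as a numerical check.
An optional iterated mode re-estimates the covariance until the
coefficients settle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EstimationError(RuntimeError):
    """Singular design or non-invertible residual covariance."""


@dataclass
class SureFit:
    """FGLS result for the two-equation system."""

    beta1: np.ndarray  # cost-equation coefficients
    beta2: np.ndarray  # effect-equation coefficients
    sigma: np.ndarray  # 2x2 residual covariance (denominator n)
    converged: bool
    n: int
    n_iter: int


def sure_fit(
    y1: np.ndarray,
    X1: np.ndarray,
    y2: np.ndarray,
    X2: np.ndarray,
    iterate: bool = False,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> SureFit:
    """Fit the two-equation SUR system by (optionally iterated) FGLS.

    ``X1``/``X2`` are full design matrices including the constant; both
    equations observe the same n patients.  Raises
    :class:`EstimationError` on a singular design.
    """
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    n = len(y1)
    if len(y2) != n or X1.shape[0] != n or X2.shape[0] != n:
        raise ValueError("equations must observe the same patients")
    if np.isnan(y1).any() or np.isnan(y2).any() or np.isnan(X1).any() or np.isnan(X2).any():
        raise ValueError("SUR requires complete (post-imputation) data")
    p1, p2 = X1.shape[1], X2.shape[1]
    if n <= max(p1, p2):
        raise EstimationError("fewer observations than coefficients")

    for X, label in ((X1, "cost"), (X2, "effect")):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise EstimationError(f"singular design in the {label} equation")

    b1, *_ = np.linalg.lstsq(X1, y1, rcond=None)
    b2, *_ = np.linalg.lstsq(X2, y2, rcond=None)

    n_steps = max_iter if iterate else 1
    converged = not iterate
    it = 0
    for it in range(1, n_steps + 1):
        r1 = y1 - X1 @ b1
        r2 = y2 - X2 @ b2
        sigma = np.array(
            [[r1 @ r1, r1 @ r2], [r1 @ r2, r2 @ r2]], dtype=float
        ) / n
        det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
        if not np.isfinite(det) or det <= 0:
            raise EstimationError("residual covariance is not positive definite")
        s_inv = np.array(
            [[sigma[1, 1], -sigma[0, 1]], [-sigma[0, 1], sigma[0, 0]]]
        ) / det

        A = np.block(
            [
                [s_inv[0, 0] * X1.T @ X1, s_inv[0, 1] * X1.T @ X2],
                [s_inv[1, 0] * X2.T @ X1, s_inv[1, 1] * X2.T @ X2],
            ]
        )
        rhs = np.concatenate(
            [
                s_inv[0, 0] * X1.T @ y1 + s_inv[0, 1] * X1.T @ y2,
                s_inv[1, 0] * X2.T @ y1 + s_inv[1, 1] * X2.T @ y2,
            ]
        )
        try:
            beta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular stacked system: {exc}") from exc
        new_b1, new_b2 = beta[:p1], beta[p1:]
        delta = max(
            np.max(np.abs(new_b1 - b1), initial=0.0),
            np.max(np.abs(new_b2 - b2), initial=0.0),
        )
        b1, b2 = new_b1, new_b2
        if iterate and delta < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break

    r1 = y1 - X1 @ b1
    r2 = y2 - X2 @ b2
    sigma = np.array([[r1 @ r1, r1 @ r2], [r1 @ r2, r2 @ r2]], dtype=float) / n
    return SureFit(beta1=b1, beta2=b2, sigma=sigma, converged=converged, n=n, n_iter=it)
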