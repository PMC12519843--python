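"""Damped Gauss-Newton / Levenberg-Marquardt least squares.

A single deterministic engine backs every nonlinear fit in the package
(candidate allometric forms, the age-group dummy model, and the
GLS-whitened inner problem of the SUR system).  It exposes the accepted
residual-sum-of-squares trajectory so callers and tests can verify that
accepted steps never increase the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LMResult", "levenberg_marquardt", "jacobian_covariance"]


@dataclass
class LMResult:
    """Outcome of a Levenberg-Marquardt minimisation."""

    x: np.ndarray
    rss: float
    converged: bool
    n_iter: int
    #: RSS at the start plus after every *accepted* step (non-increasing).
    rss_history: list[float] = field(default_factory=list)
    jac: np.ndarray | None = None
    message: str = ""


def levenberg_marquardt(
    residual_fn,
    jac_fn,
    x0,
    *,
    max_iter: int = 200,
    xtol: float = 1e-10,
    ftol: float = 1e-12,
    lam0: float = 1e-3,
    lam_up: float = 10.0,
    lam_down: float = 0.1,
    lam_max: float = 1e12,
) -> LMResult:
    """Minimise ``sum(residual_fn(x)**2)`` from ``x0``.

    Parameters
    ----------
    residual_fn, jac_fn
        Residual vector ``r(x)`` (length m) and its Jacobian ``J(x)``
        (m x p).  Residuals are *observed minus predicted* or any sign
        convention consistent between the two.
    xtol, ftol
        Declare convergence when the relative parameter change of an
        accepted step falls below ``xtol`` or the relative RSS change
        below ``ftol``.

    Non-finite trial residuals are treated as a rejected step (the damping
    parameter grows), which keeps e.g. power-law fits away from invalid
    regions without special casing.
    """
    x = np.asarray(x0, dtype=float).copy()
    if x.ndim != 1:
        raise ValueError("x0 must be a one-dimensional parameter vector")
    r = np.asarray(residual_fn(x), dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals are not finite at the starting point")
    rss = float(r @ r)
    history = [rss]
    lam = lam0
    converged = False
    message = "maximum number of iterations reached"
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        J = np.asarray(jac_fn(x), dtype=float)
        g = J.T @ r
        H = J.T @ J
        d = np.diag(H).copy()
        d[d <= 0] = 1.0  # guard flat directions of the damping scale
        accepted = False
        while lam <= lam_max:
            try:
                step = np.linalg.solve(H + lam * np.diag(d), -g)
            except np.linalg.LinAlgError:
                lam *= lam_up
                continue
            x_try = x + step
            r_try = np.asarray(residual_fn(x_try), dtype=float)
            if np.all(np.isfinite(r_try)):
                rss_try = float(r_try @ r_try)
                if rss_try <= rss:
                    accepted = True
                    break
            lam *= lam_up
        if not accepted:
            converged = True  # damping exhausted: already at a minimum
            message = "no acceptable step found (damping exhausted)"
            break

        dx_rel = float(np.max(np.abs(step) / (np.abs(x) + 1e-30)))
        drss_rel = (rss - rss_try) / max(rss, 1e-300)
        x, r, rss = x_try, r_try, rss_try
        history.append(rss)
        lam = max(lam * lam_down, 1e-14)
        if dx_rel < xtol or drss_rel < ftol:
            converged = True
            message = "converged"
            break

    return LMResult(
        x=x,
        rss=rss,
        converged=converged,
        n_iter=n_iter,
        rss_history=history,
        jac=np.asarray(jac_fn(x), dtype=float),
        message=message,
    )


def _bread(H: np.ndarray) -> np.ndarray:
    """Inverse of ``J'J``; pseudo-inverse with inflated null-space diagonal
    when rank-deficient, so unidentifiable parameters surface as huge
    (or infinite) standard errors rather than exceptions."""
    p = H.shape[0]
    try:
        Hinv = np.linalg.inv(H)
        if not np.all(np.isfinite(Hinv)) or np.linalg.cond(H) > 1e14:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        Hinv = np.linalg.pinv(H)
        if np.linalg.matrix_rank(H) < p:
            diag_fix = np.diag(Hinv).copy()
            diag_fix[diag_fix < 1e-12] = np.inf
            Hinv = Hinv - np.diag(np.diag(Hinv)) + np.diag(diag_fix)
    return Hinv


def jacobian_covariance(
    jac: np.ndarray,
    rss: float,
    n: int,
    *,
    scale: bool = True,
    residuals: np.ndarray | None = None,
) -> np.ndarray:
    """Parameter covariance from the final Jacobian.

    With ``residuals`` given, returns the heteroscedasticity-robust
    sandwich ``(J'J)^-1 (J' diag(r^2) J) (J'J)^-1`` — appropriate here
    because biomass errors are multiplicative (spread grows with tree
    size) while the fits are unweighted.  Otherwise the classic
    ``sigma2 * (J'J)^-1`` with ``sigma2 = rss/(n-p)``; ``scale=False``
    drops the scaling for pre-whitened residuals (the GLS stage of the
    SUR estimator).
    """
    p = jac.shape[1]
    H = jac.T @ jac
    Hinv = _bread(H)
    if residuals is not None:
        if not np.all(np.isfinite(Hinv)):
            return Hinv  # rank-deficient: keep the inflated diagonal as-is
        meat = (jac.T * np.asarray(residuals, dtype=float) ** 2) @ jac
        return Hinv @ meat @ Hinv
    sigma2 = rss / max(n - p, 1) if scale else 1.0
    return sigma2 * Hinv
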