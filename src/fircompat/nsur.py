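"""Additivity-constrained nonlinear seemingly unrelated regression (NSUR).

The four component allometries (bark, trunk, branch, leaf — each an
age-group dummy power model) are estimated *jointly*: their error terms
are cross-correlated within a tree, so generalised least squares with the
estimated 4x4 residual covariance is more efficient than fitting each
equation alone.  The total is not a fifth equation: it is the identity

    total = bark + trunk + branch + leaf,

enforced structurally at prediction time.  Estimating it as an equation
would make the residual covariance singular, since its residuals are an
exact linear combination of the component residuals.

Estimator: iterated feasible GLS (IFGLS).  Starting from equationwise
fits, alternate (i) residual-covariance estimation ``Sigma = R'R / n``
and (ii) damped Gauss-Newton minimisation of the stacked GLS criterion
``sum_i r_i' Sigma^-1 r_i`` (implemented by whitening each tree's 4-vector
of residuals with the Cholesky factor of ``Sigma``), until the relative
parameter change between outer iterations falls below tolerance.
Convergence is declared on the parameters; ``Sigma`` at the final iterate
is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._optimize import _bread as _optimize_bread
from ._optimize import jacobian_covariance, levenberg_marquardt
from .dummy_models import DummyModelFit, fit_dummy
from .published import AGE_GROUPS, COMPONENTS

log = logging.getLogger(__name__)

__all__ = ["SURSystemFit", "estimate_sigma", "fit_nsur", "predict_system"]

_N_SCALES = len(AGE_GROUPS)
_P_PER_EQ = _N_SCALES + 2  # scales + exp_lh + exp_lcd
_N_EQ = len(COMPONENTS)


@dataclass(frozen=True)
class SURSystemFit:
    """Jointly estimated parameters of the four-equation system.

    ``sigma`` is the 4x4 residual covariance (component order
    :data:`fircompat.published.COMPONENTS`); ``param_cov`` the 28x28 GLS
    parameter covariance in the same block order (5 scales then the two
    exponents per component).
    """

    scales: dict[str, dict[int, float]]
    exponents: dict[str, tuple[float, float]]
    se_scales: dict[str, dict[int, float]]
    se_exponents: dict[str, tuple[float, float]]
    sigma: np.ndarray
    param_cov: np.ndarray = field(repr=False)
    n: int
    outer_iterations: int
    converged: bool
    #: (criterion before, criterion after) for each outer GLS stage.
    gls_history: tuple[tuple[float, float], ...] = field(default=(), repr=False)

    @property
    def k(self) -> int:
        return _N_EQ * _P_PER_EQ

    def component_rss(self, frame: pd.DataFrame) -> dict[str, float]:
        pred = predict_system(self, frame["lh"], frame["lcd"], frame["age_group"])
        return {
            c: float(np.sum((frame[f"m_{c}"].to_numpy(dtype=float) - pred[c]) ** 2))
            for c in COMPONENTS
        }

    def predict(self, frame: pd.DataFrame) -> dict[str, np.ndarray]:
        return predict_system(self, frame["lh"], frame["lcd"], frame["age_group"])

    def to_dict(self) -> dict:
        return {
            "components": list(COMPONENTS),
            "scales": {c: {int(g): v for g, v in s.items()}
                       for c, s in self.scales.items()},
            "exponents": {c: list(e) for c, e in self.exponents.items()},
            "se_scales": {c: {int(g): v for g, v in s.items()}
                          for c, s in self.se_scales.items()},
            "se_exponents": {c: list(e) for c, e in self.se_exponents.items()},
            "sigma": np.asarray(self.sigma).tolist(),  # row-major 4x4
            "n": self.n,
            "outer_iterations": self.outer_iterations,
            "converged": self.converged,
        }


def predict_system(fit, lh, lcd, age_group) -> dict[str, np.ndarray]:
    """Predict every component and the total (= exact sum of components)."""
    lh = np.asarray(lh, dtype=float)
    lcd = np.asarray(lcd, dtype=float)
    if np.any(lh <= 0) or np.any(lcd <= 0):
        raise ValueError("covariates must be strictly positive")
    ag = np.atleast_1d(np.asarray(age_group, dtype=int))
    out: dict[str, np.ndarray] = {}
    for c in COMPONENTS:
        e_lh, e_lcd = fit.exponents[c]
        scale = np.array([fit.scales[c][int(g)] for g in ag])
        out[c] = scale * lh ** e_lh * lcd ** e_lcd
    out["total"] = out["bark"] + out["trunk"] + out["branch"] + out["leaf"]
    return out


def estimate_sigma(residuals: np.ndarray, *, divisor: str = "n") -> np.ndarray:
    """Residual covariance ``R'R / n`` from an (n x 4) residual matrix.

    Symmetric PSD by construction.  ``divisor="n"`` is the default
    (simple, deterministic); ``"n-p"`` subtracts the per-equation
    parameter count for a bias-adjusted variant.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[1] != _N_EQ:
        raise ValueError(f"residual matrix must be n x {_N_EQ}")
    n = R.shape[0]
    if n < 5:
        raise ValueError("need at least 5 residual rows to estimate Sigma")
    denom = n if divisor == "n" else max(n - _P_PER_EQ, 1)
    return R.T @ R / denom


def _chol_inv_factor(sigma: np.ndarray, ridge_scale: float = 1e-8):
    """Lower-triangular ``Linv`` with ``Linv' Linv = Sigma^-1``; ridge on failure."""
    sigma = np.asarray(sigma, dtype=float)
    tau = ridge_scale * float(np.trace(sigma)) / sigma.shape[0]
    attempt = sigma
    for k in range(8):
        try:
            L = np.linalg.cholesky(attempt)
            if np.min(np.diag(L)) > 1e-12 * np.max(np.diag(L)):
                if k > 0:
                    log.warning("residual covariance near-singular; "
                                "ridge %g applied", tau * 10 ** (k - 1))
                return np.linalg.inv(L)
        except np.linalg.LinAlgError:
            pass
        attempt = sigma + tau * (10 ** k) * np.eye(sigma.shape[0])
    raise np.linalg.LinAlgError("residual covariance could not be factorised")


def fit_nsur(
    train: pd.DataFrame,
    *,
    start: dict[str, DummyModelFit] | None = None,
    max_outer: int = 100,
    outer_xtol: float = 1e-8,
    max_inner: int = 100,
    sigma_divisor: str = "n",
    fixed_sigma: np.ndarray | None = None,
    se_method: str = "robust",
) -> SURSystemFit:
    """Fit the additive system by iterated feasible GLS.

    ``start`` optionally supplies equationwise dummy-model fits (one per
    component); otherwise they are fitted here.  Requires all five age
    groups, strictly positive covariates, and at least 50 trees.

    ``fixed_sigma`` runs plain GLS with a *known* error covariance
    instead of iterating on the estimate — e.g. a diagonal matrix, in
    which case the criterion separates by equation and the estimates must
    coincide with equationwise least squares (the oracle check for the
    whitening machinery).  The reported ``sigma`` is then still the
    residual covariance at the solution.
    """
    if len(train) < 50:
        raise ValueError("NSUR needs at least 50 trees")
    groups = tuple(sorted(train["age_group"].unique()))
    if groups != AGE_GROUPS:
        missing = sorted(set(AGE_GROUPS) - set(groups))
        raise ValueError(f"age group(s) {missing} absent; use a stratified split")
    lh = train["lh"].to_numpy(dtype=float)
    lcd = train["lcd"].to_numpy(dtype=float)
    if np.any(lh <= 0) or np.any(lcd <= 0):
        raise ValueError("covariates must be strictly positive")
    n = len(train)
    Y = np.column_stack([train[f"m_{c}"].to_numpy(dtype=float) for c in COMPONENTS])
    g_idx = train["age_group"].to_numpy(dtype=int) - 1
    onehot = np.zeros((n, _N_SCALES))
    onehot[np.arange(n), g_idx] = 1.0
    log_lh, log_lcd = np.log(lh), np.log(lcd)

    if start is None:
        start = {c: fit_dummy(train, c) for c in COMPONENTS}
    theta = np.concatenate([
        np.concatenate([
            [start[c].scales[g] for g in AGE_GROUPS],
            [start[c].exp_lh, start[c].exp_lcd],
        ])
        for c in COMPONENTS
    ])

    def unpack(theta):
        return theta.reshape(_N_EQ, _P_PER_EQ)

    def mean_matrix(theta):
        blocks = unpack(theta)
        M = np.empty((n, _N_EQ))
        for j in range(_N_EQ):
            scales, b, c = blocks[j, :_N_SCALES], blocks[j, -2], blocks[j, -1]
            M[:, j] = scales[g_idx] * lh ** b * lcd ** c
        return M

    def jac_blocks(theta):
        """Per-equation (n x 7) Jacobians of the mean."""
        blocks = unpack(theta)
        out = []
        for j in range(_N_EQ):
            scales, b, c = blocks[j, :_N_SCALES], blocks[j, -2], blocks[j, -1]
            pw = lh ** b * lcd ** c
            f = scales[g_idx] * pw
            out.append(np.column_stack([onehot * pw[:, None], f * log_lh, f * log_lcd]))
        return out

    gls_history: list[tuple[float, float]] = []
    converged = False
    outer = 0
    Linv = np.eye(_N_EQ)
    if fixed_sigma is not None:
        max_outer = 1
    for outer in range(1, max_outer + 1):
        R = Y - mean_matrix(theta)
        sigma_hat = (np.asarray(fixed_sigma, dtype=float) if fixed_sigma is not None
                     else estimate_sigma(R, divisor=sigma_divisor))
        Linv = _chol_inv_factor(sigma_hat)

        def whitened_resid(th):
            return ((Y - mean_matrix(th)) @ Linv.T).ravel()

        def whitened_jac(th):
            Js = jac_blocks(th)
            # d(whitened residual)/d(theta): rows (tree, eq), cols 28
            J = np.zeros((n, _N_EQ, _N_EQ * _P_PER_EQ))
            for j in range(_N_EQ):
                # whitening mixes equations: row block i gets Linv[i, j] * J_j
                for i in range(_N_EQ):
                    w = Linv[i, j]
                    if w != 0.0:
                        J[:, i, j * _P_PER_EQ:(j + 1) * _P_PER_EQ] += -w * Js[j]
            return J.reshape(n * _N_EQ, -1)

        crit_start = float(whitened_resid(theta) @ whitened_resid(theta))
        res = levenberg_marquardt(
            whitened_resid, whitened_jac, theta,
            max_iter=max_inner, xtol=1e-12, ftol=1e-14,
        )
        gls_history.append((crit_start, res.rss))
        dtheta = float(np.max(np.abs(res.x - theta) / (np.abs(theta) + 1e-30)))
        theta = res.x
        if dtheta < outer_xtol:
            converged = True
            break
    if fixed_sigma is not None:
        converged = res.converged
    if not converged:
        log.warning("IFGLS did not converge within %d outer iterations "
                    "(last relative change %.3g)", max_outer, dtheta)

    R = Y - mean_matrix(theta)
    sigma_hat = estimate_sigma(R, divisor=sigma_divisor)
    # GLS parameter covariance from the whitened Jacobian at the optimum;
    # by default tree-clustered sandwich form, robust to the size-dependent
    # (multiplicative) error spread that the plain GLS covariance ignores
    Linv = _chol_inv_factor(sigma_hat)
    Js = jac_blocks(theta)
    Jw3 = np.zeros((n, _N_EQ, _N_EQ * _P_PER_EQ))
    for j in range(_N_EQ):
        for i in range(_N_EQ):
            w = Linv[i, j]
            if w != 0.0:
                Jw3[:, i, j * _P_PER_EQ:(j + 1) * _P_PER_EQ] += w * Js[j]
    Jw = Jw3.reshape(n * _N_EQ, -1)
    if se_method == "robust":
        Rw = R @ Linv.T
        scores = np.einsum("nep,ne->np", Jw3, Rw)
        bread = _optimize_bread(Jw.T @ Jw)
        param_cov = bread @ (scores.T @ scores) @ bread
    else:
        param_cov = jacobian_covariance(Jw, float("nan"), n, scale=False)

    blocks = unpack(theta)
    se_blocks = np.sqrt(np.clip(np.diag(param_cov), 0.0, None)).reshape(
        _N_EQ, _P_PER_EQ
    )
    scales = {c: {g: float(blocks[j, g - 1]) for g in AGE_GROUPS}
              for j, c in enumerate(COMPONENTS)}
    exponents = {c: (float(blocks[j, -2]), float(blocks[j, -1]))
                 for j, c in enumerate(COMPONENTS)}
    se_scales = {c: {g: float(se_blocks[j, g - 1]) for g in AGE_GROUPS}
                 for j, c in enumerate(COMPONENTS)}
    se_exponents = {c: (float(se_blocks[j, -2]), float(se_blocks[j, -1]))
                    for j, c in enumerate(COMPONENTS)}
    return SURSystemFit(
        scales=scales,
        exponents=exponents,
        se_scales=se_scales,
        se_exponents=se_exponents,
        sigma=sigma_hat,
        param_cov=param_cov,
        n=n,
        outer_iterations=outer,
        converged=converged,
        gls_history=tuple(gls_history),
    )
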