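"""Age-group dummy-variable power model.

Stand age enters the power allometry as a categorical factor: each of the
five age groups gets its own scale coefficient while the height and
crown-diameter exponents are shared,

    BM = (sum_i b0_i * S_i) * LH**b * LCD**c,

where ``S_i`` is the 0/1 indicator of age group ``i``.  All five scales
are estimated directly (no reference-category reparameterisation): the
multiplicative form has no separate intercept, so the usual "n-1 dummies"
rule for linear encodings does not apply and the published fits report
one scale per group.  The base power model is the equal-scales special
case, which makes the two models nested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._optimize import jacobian_covariance, levenberg_marquardt
from .base_models import fit_base
from .published import AGE_GROUPS

log = logging.getLogger(__name__)

__all__ = ["AgeDummyVector", "encode_age", "DummyModelFit", "predict_dummy", "fit_dummy"]

AgeDummyVector = np.ndarray  # length-5 0/1 vector, exactly one 1


def encode_age(age_group: int) -> AgeDummyVector:
    """Unit indicator vector for an age group in 1..5."""
    if age_group not in AGE_GROUPS:
        raise ValueError(f"age_group must be in 1..5, got {age_group!r}")
    v = np.zeros(5, dtype=int)
    v[age_group - 1] = 1
    return v


@dataclass(frozen=True)
class DummyModelFit:
    """Per-group scale coefficients with shared power exponents."""

    component: str
    scales: dict[int, float]
    exp_lh: float
    exp_lcd: float
    se_scales: dict[int, float]
    se_exp_lh: float
    se_exp_lcd: float
    n: int
    converged: bool
    n_iter: int
    rss: float
    rss_history: tuple[float, ...] = field(default=(), repr=False)

    @property
    def groups(self) -> tuple[int, ...]:
        return tuple(sorted(self.scales))

    @property
    def k(self) -> int:
        return len(self.scales) + 2

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return predict_dummy(self, frame["lh"], frame["lcd"], frame["age_group"])

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "scales": {int(g): v for g, v in self.scales.items()},
            "exp_lh": self.exp_lh, "exp_lcd": self.exp_lcd,
            "se_scales": {int(g): v for g, v in self.se_scales.items()},
            "se_exp_lh": self.se_exp_lh, "se_exp_lcd": self.se_exp_lcd,
            "n": self.n, "converged": self.converged,
            "n_iter": self.n_iter, "rss": self.rss,
        }


def predict_dummy(fit, lh, lcd, age_group) -> np.ndarray:
    """Evaluate ``b0[group] * lh**b * lcd**c`` (vectorised).

    ``fit`` needs ``scales``, ``exp_lh``, ``exp_lcd`` attributes; unknown
    age groups or non-positive covariates are domain errors.
    """
    lh = np.asarray(lh, dtype=float)
    lcd = np.asarray(lcd, dtype=float)
    ag = np.atleast_1d(np.asarray(age_group, dtype=int))
    if np.any(lh <= 0) or np.any(lcd <= 0):
        raise ValueError("covariates must be strictly positive")
    unknown = sorted(set(ag.tolist()) - set(fit.scales))
    if unknown:
        raise ValueError(f"no scale coefficient for age group(s) {unknown}")
    scale = np.array([fit.scales[int(g)] for g in ag])
    out = scale * lh ** fit.exp_lh * lcd ** fit.exp_lcd
    return float(out[0]) if np.isscalar(age_group) and out.size == 1 else out


def fit_dummy(
    train: pd.DataFrame,
    component: str,
    *,
    allow_missing_groups: bool = False,
    max_iter: int = 200,
    se_method: str = "robust",
) -> DummyModelFit:
    """Joint nonlinear least squares over (scales, b, c).

    Initialised from the base power fit on the same data (every group
    scale starts at the pooled ``a``), so the optimiser starts at the
    equal-scales special case and the training RSS can only improve on
    the base model's.  By default all five age groups must be present
    (use a stratified split); ``allow_missing_groups=True`` fits only the
    groups present, omitting scales for absent ones.
    """
    col = component if component in train.columns else f"m_{component}"
    if col not in train.columns:
        raise ValueError(f"component column {component!r} not found")
    groups = tuple(sorted(train["age_group"].unique()))
    if not allow_missing_groups and groups != AGE_GROUPS:
        missing = sorted(set(AGE_GROUPS) - set(groups))
        raise ValueError(
            f"age group(s) {missing} absent from training data; "
            "use a split stratified by age_group"
        )
    n_params = len(groups) + 2
    if len(train) < n_params:
        raise ValueError(
            f"underdetermined: {len(train)} observations for {n_params} parameters"
        )

    lh = train["lh"].to_numpy(dtype=float)
    lcd = train["lcd"].to_numpy(dtype=float)
    y = train[col].to_numpy(dtype=float)
    g_idx = np.searchsorted(np.asarray(groups), train["age_group"].to_numpy())
    onehot = np.zeros((len(train), len(groups)))
    onehot[np.arange(len(train)), g_idx] = 1.0

    base = fit_base(train, "power", component, max_iter=max_iter)
    p0 = np.concatenate([
        np.full(len(groups), base.params["a"]),
        [base.params["b"], base.params["c"]],
    ])

    def mean(p):
        scales, b, c = p[:-2], p[-2], p[-1]
        return scales[g_idx] * lh ** b * lcd ** c

    def jac(p):
        scales, b, c = p[:-2], p[-2], p[-1]
        pw = lh ** b * lcd ** c
        f = scales[g_idx] * pw
        return np.column_stack([onehot * pw[:, None], f * np.log(lh), f * np.log(lcd)])

    res = levenberg_marquardt(
        lambda p: y - mean(p), lambda p: -jac(p), p0, max_iter=max_iter
    )
    cov = jacobian_covariance(
        res.jac, res.rss, y.size,
        residuals=(y - mean(res.x)) if se_method == "robust" else None,
    )
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if not res.converged:
        log.warning("dummy model fit for %s did not converge (%s)",
                    component, res.message)
    return DummyModelFit(
        component=component,
        scales={int(g): float(v) for g, v in zip(groups, res.x[:-2])},
        exp_lh=float(res.x[-2]),
        exp_lcd=float(res.x[-1]),
        se_scales={int(g): float(v) for g, v in zip(groups, se[:-2])},
        se_exp_lh=float(se[-2]),
        se_exp_lcd=float(se[-1]),
        n=int(y.size),
        converged=res.converged,
        n_iter=res.n_iter,
        rss=float(res.rss),
        rss_history=tuple(res.rss_history),
    )
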