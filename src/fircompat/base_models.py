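"""Candidate single-equation allometric forms: fitting, selection, screening.

Four candidate mean functions relate a biomass component ``BM`` (kg) to
LiDAR tree height ``LH`` and crown diameter ``LCD`` (m), with the sign
conventions of the source tables implemented exactly as printed:

    logistic:     BM = a / (1 + b * exp(-c*LH - d*LCD))      (4 parameters)
    linear:       BM = a*LH + b*LCD - c                      (3)
    exponential:  BM = a * exp(-b*LH - c*LCD)                (3)
    power:        BM = a * LH**b * LCD**c                    (3)

Fitting is unweighted nonlinear least squares via the package's damped
Gauss-Newton / Levenberg-Marquardt engine, with deterministic log-linear
initial values.  Candidate covariates pass through forward-backward
stepwise selection (AIC on the log-linearised power model) followed by a
variance-inflation-factor screen (VIF > 5 excluded).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._optimize import jacobian_covariance, levenberg_marquardt
from .metrics import aic as _aic

log = logging.getLogger(__name__)

__all__ = [
    "ModelForm", "FORMS", "BaseModelFit", "SplitSpec", "split",
    "compute_vif", "stepwise_select", "fit_base", "fit_from_params",
    "rank_models",
]


# ---------------------------------------------------------------------------
# Mean functions, Jacobians, initialisers
# ---------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _logistic_f(p, lh, lcd):
    a, b, c, d = p
    return a / (1.0 + b * np.exp(-c * lh - d * lcd))


def _logistic_jac(p, lh, lcd):
    a, b, c, d = p
    u = np.exp(-c * lh - d * lcd)
    den = 1.0 + b * u
    return np.column_stack([
        1.0 / den,
        -a * u / den ** 2,
        a * b * u * lh / den ** 2,
        a * b * u * lcd / den ** 2,
    ])


def _logistic_init(lh, lcd, y):
    a = 1.05 * float(np.max(y))
    pos = y > 0
    z = np.log(a / y[pos] - 1.0)
    beta = _ols(np.column_stack([np.ones(pos.sum()), lh[pos], lcd[pos]]), z)
    return np.array([a, math.exp(beta[0]), -beta[1], -beta[2]])


def _linear_f(p, lh, lcd):
    a, b, c = p
    return a * lh + b * lcd - c


def _linear_jac(p, lh, lcd):
    return np.column_stack([lh, lcd, -np.ones_like(lh)])


def _linear_init(lh, lcd, y):
    beta = _ols(np.column_stack([lh, lcd, -np.ones_like(lh)]), y)
    return np.asarray(beta, dtype=float)


def _exponential_f(p, lh, lcd):
    a, b, c = p
    return a * np.exp(-b * lh - c * lcd)


def _exponential_jac(p, lh, lcd):
    a, b, c = p
    e = np.exp(-b * lh - c * lcd)
    return np.column_stack([e, -a * lh * e, -a * lcd * e])


def _exponential_init(lh, lcd, y):
    pos = y > 0
    beta = _ols(np.column_stack([np.ones(pos.sum()), lh[pos], lcd[pos]]),
                np.log(y[pos]))
    return np.array([math.exp(beta[0]), -beta[1], -beta[2]])


def _power_f(p, lh, lcd):
    a, b, c = p
    return a * lh ** b * lcd ** c


def _power_jac(p, lh, lcd):
    a, b, c = p
    base = lh ** b * lcd ** c
    f = a * base
    return np.column_stack([base, f * np.log(lh), f * np.log(lcd)])


def _power_init(lh, lcd, y):
    pos = y > 0
    beta = _ols(np.column_stack([np.ones(pos.sum()),
                                 np.log(lh[pos]), np.log(lcd[pos])]),
                np.log(y[pos]))
    return np.array([math.exp(beta[0]), beta[1], beta[2]])


@dataclass(frozen=True)
class ModelForm:
    """One candidate mean function with its Jacobian and initialiser."""

    name: str
    param_names: tuple[str, ...]
    func: callable
    jac: callable
    init: callable
    positive_covariates: bool = False

    @property
    def n_params(self) -> int:
        return len(self.param_names)


FORMS: dict[str, ModelForm] = {
    "logistic": ModelForm("logistic", ("a", "b", "c", "d"),
                          _logistic_f, _logistic_jac, _logistic_init),
    "linear": ModelForm("linear", ("a", "b", "c"),
                        _linear_f, _linear_jac, _linear_init),
    "exponential": ModelForm("exponential", ("a", "b", "c"),
                             _exponential_f, _exponential_jac, _exponential_init),
    "power": ModelForm("power", ("a", "b", "c"),
                       _power_f, _power_jac, _power_init,
                       positive_covariates=True),
}


@dataclass(frozen=True)
class BaseModelFit:
    """One fitted candidate form for one biomass response."""

    form: str
    component: str
    params: dict[str, float]
    se: dict[str, float]
    n: int
    converged: bool
    n_iter: int
    rss: float
    rss_history: tuple[float, ...] = field(default=(), repr=False)

    @property
    def k(self) -> int:
        return len(self.params)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        form = FORMS[self.form]
        p = np.array([self.params[name] for name in form.param_names])
        return form.func(p, frame["lh"].to_numpy(dtype=float),
                         frame["lcd"].to_numpy(dtype=float))

    def to_dict(self) -> dict:
        return {
            "form": self.form, "component": self.component,
            "params": self.params, "se": self.se, "n": self.n,
            "converged": self.converged, "n_iter": self.n_iter, "rss": self.rss,
        }


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """7:3 train/test split, stratified by age group by default."""

    train_fraction: float = 0.7
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def split(df: pd.DataFrame, spec: SplitSpec = SplitSpec()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition; deterministic given seed.

    The per-stratum training count is ``round(train_fraction * n)``, so
    the training share is within one tree of the target in every stratum.
    A stratum too small to contribute a test tree goes wholly to training
    with a warning.
    """
    if len(df) < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(spec.seed)
    strata = df.groupby("age_group", sort=True).indices if spec.stratify \
        else {"all": np.arange(len(df))}
    train_idx, test_idx = [], []
    for key, idx in strata.items():
        idx = np.asarray(idx)
        perm = rng.permutation(idx.size)
        n_train = int(math.floor(spec.train_fraction * idx.size + 0.5))
        if n_train == idx.size:
            log.warning("stratum %r too small for a test share; placed wholly in train", key)
        train_idx.append(idx[perm[:n_train]])
        test_idx.append(idx[perm[n_train:]])
    train = df.iloc[np.sort(np.concatenate(train_idx))].reset_index(drop=True)
    test_concat = np.concatenate(test_idx) if test_idx else np.array([], dtype=int)
    test = df.iloc[np.sort(test_concat)].reset_index(drop=True)
    return train, test


# ---------------------------------------------------------------------------
# Collinearity screening and stepwise selection
# ---------------------------------------------------------------------------

def compute_vif(df: pd.DataFrame, predictors: list[str]) -> dict[str, float]:
    """Variance inflation factors ``1 / (1 - R^2_j)``.

    ``R^2_j`` comes from regressing predictor j on the remaining
    predictors plus an intercept.  Exact collinearity reports ``inf``.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = df.loc[:, predictors].to_numpy(dtype=float)
    n = X.shape[0]
    if n <= len(predictors):
        raise ValueError("need more observations than predictors")
    out = {}
    for j, name in enumerate(predictors):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta = _ols(others, y)
        resid = y - others @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0.0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - float(resid @ resid) / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _ols_aic(X: np.ndarray, y: np.ndarray) -> float:
    beta = _ols(X, y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        return -math.inf
    return _aic(rss, y.size, X.shape[1])


def stepwise_select(
    df: pd.DataFrame,
    response: str,
    candidates: list[str],
    *,
    vif_threshold: float = 5.0,
) -> list[str]:
    """Forward-backward stepwise selection on the log-linearised power model.

    Works on ``ln(response) ~ ln(candidate...)`` with the AIC criterion,
    then removes predictors whose VIF (on the log scale) exceeds
    ``vif_threshold``, dropping the worst offender iteratively.  Returns
    the selected predictor names in candidate order; an empty list (with a
    warning) if nothing improves on the intercept-only model.
    """
    if not candidates:
        raise ValueError("candidate predictor list is empty")
    y = df[response].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("log-linearisation requires a strictly positive response")
    logs = {}
    for c in candidates:
        x = df[c].to_numpy(dtype=float)
        if np.any(x <= 0):
            raise ValueError(f"log-linearisation requires positive predictor {c!r}")
        logs[c] = np.log(x)
    ly = np.log(y)
    ones = np.ones(len(df))

    def design(names):
        return np.column_stack([ones] + [logs[c] for c in names])

    selected: list[str] = []
    current_aic = _ols_aic(design(selected), ly)
    improved = True
    while improved:
        improved = False
        moves = [("add", c) for c in candidates if c not in selected]
        moves += [("drop", c) for c in selected]
        best = (current_aic, None)
        for action, c in moves:
            trial = selected + [c] if action == "add" else [s for s in selected if s != c]
            a = _ols_aic(design(trial), ly)
            if a < best[0] - 1e-12:
                best = (a, (action, c))
        if best[1] is not None:
            action, c = best[1]
            selected = selected + [c] if action == "add" else [s for s in selected if s != c]
            current_aic = best[0]
            improved = True

    if not selected:
        log.warning("stepwise selection: no candidate improves on the intercept")
        return []

    selected = [c for c in candidates if c in selected]
    # VIF screen on the log scale; ties drop the later candidate
    while len(selected) >= 2:
        vifs = compute_vif(pd.DataFrame({c: logs[c] for c in selected}), selected)
        worst = max(selected, key=lambda c: (vifs[c], selected.index(c)))
        if vifs[worst] > vif_threshold:
            log.warning("excluding %r (VIF %.3f > %.1f)", worst, vifs[worst], vif_threshold)
            selected = [c for c in selected if c != worst]
        else:
            break
    return selected


# ---------------------------------------------------------------------------
# Fitting and ranking
# ---------------------------------------------------------------------------

def fit_base(
    train: pd.DataFrame,
    form: str | ModelForm,
    component: str,
    *,
    x0: np.ndarray | None = None,
    max_iter: int = 200,
    se_method: str = "robust",
) -> BaseModelFit:
    """Fit one candidate form to one component by nonlinear least squares.

    Standard errors come from the Jacobian-based covariance at the
    optimum — by default the heteroscedasticity-robust sandwich, since
    biomass scatter grows with tree size (``se_method="classic"`` gives
    the homoscedastic ``sigma2 (J'J)^-1``).  A rank-deficient Jacobian
    (unidentifiable parameters, e.g. a logistic with no covariate effect)
    surfaces as huge standard errors rather than an exception.
    Non-convergence returns a fit flagged ``converged=False``.
    """
    mform = FORMS[form] if isinstance(form, str) else form
    if len(train) == 0:
        raise ValueError("training data are empty")
    col = component if component in train.columns else f"m_{component}"
    if col not in train.columns:
        raise ValueError(f"component column {component!r} not found")
    lh = train["lh"].to_numpy(dtype=float)
    lcd = train["lcd"].to_numpy(dtype=float)
    y = train[col].to_numpy(dtype=float)
    if mform.positive_covariates and (np.any(lh <= 0) or np.any(lcd <= 0)):
        bad = list(np.flatnonzero((lh <= 0) | (lcd <= 0))[:20])
        raise ValueError(
            f"power form requires strictly positive covariates; offending rows {bad}"
        )

    p0 = np.asarray(x0, dtype=float) if x0 is not None else mform.init(lh, lcd, y)
    res = levenberg_marquardt(
        lambda p: y - mform.func(p, lh, lcd),
        lambda p: -mform.jac(p, lh, lcd),
        p0,
        max_iter=max_iter,
    )
    resid = y - mform.func(res.x, lh, lcd)
    cov = jacobian_covariance(
        res.jac, res.rss, y.size,
        residuals=resid if se_method == "robust" else None,
    )
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if not res.converged:
        log.warning("%s/%s fit did not converge in %d iterations (%s)",
                    mform.name, component, res.n_iter, res.message)
    return BaseModelFit(
        form=mform.name,
        component=component,
        params=dict(zip(mform.param_names, map(float, res.x))),
        se=dict(zip(mform.param_names, map(float, se))) if res.converged else {},
        n=int(y.size),
        converged=res.converged,
        n_iter=res.n_iter,
        rss=float(res.rss),
        rss_history=tuple(res.rss_history),
    )


def fit_from_params(form: str, component: str, params: dict[str, float]) -> BaseModelFit:
    """Wrap externally supplied coefficients (e.g. published reference
    fits) in a :class:`BaseModelFit` so they ride the same prediction path."""
    names = FORMS[form].param_names
    missing = [p for p in names if p not in params]
    if missing:
        raise ValueError(f"missing parameters for form {form!r}: {missing}")
    return BaseModelFit(
        form=form, component=component,
        params={p: float(params[p]) for p in names},
        se={}, n=0, converged=True, n_iter=0, rss=float("nan"),
    )


def rank_models(
    fits: list[BaseModelFit],
    *,
    delta_aic_tie: float = 2.0,
) -> tuple[pd.DataFrame, str]:
    """Rank converged fits of the same data by AIC; parsimony tie-break.

    If the two best forms are within ``delta_aic_tie`` AIC units, the one
    with fewer parameters is selected (a logistic/power near-tie resolves
    to the 3-parameter power form).  Non-converged fits are excluded with
    a logged reason.  Returns (ranking table, selected form name).
    """
    usable = []
    for f in fits:
        if not f.converged:
            log.warning("excluding non-converged %s fit from ranking", f.form)
            continue
        usable.append(f)
    if not usable:
        raise ValueError("no converged fits to rank")
    ns = {f.n for f in usable}
    if len(ns) != 1:
        raise ValueError("fits were not computed on the same data (differing n)")

    rows = [{"form": f.form, "k": f.k, "rss": f.rss,
             "aic": _aic(f.rss, f.n, f.k)} for f in usable]
    table = pd.DataFrame(rows).sort_values(["aic", "k"]).reset_index(drop=True)
    selected = table.loc[0, "form"]
    if len(table) >= 2:
        top, runner = table.iloc[0], table.iloc[1]
        if runner["aic"] - top["aic"] <= delta_aic_tie and runner["k"] < top["k"]:
            selected = runner["form"]
    return table, str(selected)
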