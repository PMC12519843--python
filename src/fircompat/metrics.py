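"""Goodness-of-fit metrics and model-comparison reporting.

The metric definitions follow the conventions of the source allometry
literature exactly, two of which differ from the most common textbook
forms and are therefore pinned by tests:

* ``rmse`` uses an ``n - 1`` denominator, not ``n``;
* ``tre`` (total relative error) is the absolute form
  ``sum|y - yhat| / sum(y)`` — a signed variant is provided separately.

Information criteria use the Gaussian maximum likelihood concentrated
over the error variance, ``sigma2_hat = RSS / n``:

    ln L = -(n/2) * (ln(2*pi*RSS/n) + 1)
    AIC  = 2k - 2 ln L,      BIC = k ln n - 2 ln L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FitMetrics", "r_squared", "rmse", "tre", "tre_signed",
    "gaussian_loglik", "aic", "bic", "evaluate", "compare_report",
]


@dataclass(frozen=True)
class FitMetrics:
    """Metrics of one model on one dataset. ``tre`` is a fraction; the
    percent rendering (as published tables print it) is ``100 * tre``."""

    r2: float
    rmse: float
    tre: float
    aic: float
    bic: float
    n: int
    k: int


def _check_pair(observed, predicted):
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have the same length")
    return y, yhat


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - RSS/TSS`` (may be negative)."""
    y, yhat = _check_pair(observed, predicted)
    if y.size < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("R^2 undefined: observed values are all equal")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / tss


def rmse(observed, predicted) -> float:
    """Root mean squared error with the ``n - 1`` denominator."""
    y, yhat = _check_pair(observed, predicted)
    if y.size < 2:
        raise ValueError("RMSE with an n-1 denominator needs n >= 2")
    return math.sqrt(float(np.sum((y - yhat) ** 2)) / (y.size - 1))


def tre(observed, predicted) -> float:
    """Total relative error ``sum|y - yhat| / sum(y)`` (absolute form)."""
    y, yhat = _check_pair(observed, predicted)
    total = float(np.sum(y))
    if total <= 0:
        raise ValueError("TRE requires a strictly positive observed total")
    return float(np.sum(np.abs(y - yhat))) / total


def tre_signed(observed, predicted) -> float:
    """Signed variant ``sum(y - yhat) / sum(y)`` (bias, not error, measure)."""
    y, yhat = _check_pair(observed, predicted)
    total = float(np.sum(y))
    if total <= 0:
        raise ValueError("TRE requires a strictly positive observed total")
    return float(np.sum(y - yhat)) / total


def gaussian_loglik(rss: float, n: int) -> float:
    """Concentrated Gaussian log-likelihood at ``sigma2_hat = rss / n``."""
    if rss <= 0:
        raise ValueError("degenerate fit: RSS must be strictly positive "
                         "(zero RSS implies an unbounded likelihood)")
    if n < 1:
        raise ValueError("n must be positive")
    return -(n / 2.0) * (math.log(2.0 * math.pi * rss / n) + 1.0)


def aic(rss: float, n: int, k: int) -> float:
    """Akaike information criterion ``2k - 2 ln L``; requires ``n > k``."""
    if n <= k:
        raise ValueError("AIC requires more observations than parameters")
    return 2.0 * k - 2.0 * gaussian_loglik(rss, n)


def bic(rss: float, n: int, k: int) -> float:
    """Bayesian information criterion ``k ln n - 2 ln L``."""
    if n <= k:
        raise ValueError("BIC requires more observations than parameters")
    return k * math.log(n) - 2.0 * gaussian_loglik(rss, n)


def evaluate(observed, predicted, k: int) -> FitMetrics:
    """All metrics of one prediction vector against observations."""
    y, yhat = _check_pair(observed, predicted)
    rss = float(np.sum((y - yhat) ** 2))
    return FitMetrics(
        r2=r_squared(y, yhat),
        rmse=rmse(y, yhat),
        tre=tre(y, yhat),
        aic=aic(rss, y.size, k),
        bic=bic(rss, y.size, k),
        n=int(y.size),
        k=int(k),
    )


def compare_report(
    models: dict[str, tuple],
    train: pd.DataFrame,
    test: pd.DataFrame,
    response: str,
    *,
    baseline: str | None = None,
) -> pd.DataFrame:
    """Tabulate train/test metrics for several models plus relative changes.

    ``models`` maps a model name to ``(predict_fn, k)`` where
    ``predict_fn(frame) -> yhat`` and ``k`` is the parameter count.  All
    models are evaluated on the *same* train and test frames; relative
    changes ``(new - old)/old * 100`` in R^2 and RMSE are reported against
    ``baseline`` (default: the first model).
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    if baseline is None:
        baseline = next(iter(models))
    if baseline not in models:
        raise ValueError(f"baseline {baseline!r} not among the models")

    rows = []
    for name, (predict_fn, k) in models.items():
        for split_name, frame in (("train", train), ("test", test)):
            yhat = np.asarray(predict_fn(frame), dtype=float)
            if yhat.shape[0] != len(frame):
                raise ValueError(
                    f"model {name!r} returned {yhat.shape[0]} predictions "
                    f"for {len(frame)} rows"
                )
            m = evaluate(frame[response], yhat, k)
            rows.append({
                "model": name, "split": split_name, "response": response,
                "n": m.n, "k": m.k, "r2": m.r2, "rmse": m.rmse, "tre": m.tre,
            })
    report = pd.DataFrame(rows)

    base = report[report["model"] == baseline].set_index("split")
    report["d_r2_pct"] = [
        (row.r2 - base.loc[row.split, "r2"]) / base.loc[row.split, "r2"] * 100.0
        for row in report.itertuples()
    ]
    report["d_rmse_pct"] = [
        (row.rmse - base.loc[row.split, "rmse"]) / base.loc[row.split, "rmse"] * 100.0
        for row in report.itertuples()
    ]
    return report
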