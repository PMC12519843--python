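"""Tree-level records: schema, validation, and CSV round-trip.

The canonical in-memory container is a :class:`pandas.DataFrame` with one
row per tree and the columns of :data:`TREE_COLUMNS`.  Units are fixed:
metres for the LiDAR covariates, kilograms (dry mass) for biomass.  The
total column is structurally the sum of the four components — rows that
violate additivity beyond tolerance are data errors, not noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .published import AGE_GROUPS, COMPONENTS

log = logging.getLogger(__name__)

__all__ = [
    "TREE_COLUMNS",
    "COMPONENT_COLUMNS",
    "TreeRecord",
    "TreeDataError",
    "validate_tree_frame",
    "load_tree_csv",
    "write_tree_csv",
]

#: CSV / DataFrame schema, in column order.
TREE_COLUMNS = (
    "tree_id", "plot_id", "age_group", "lh", "lcd",
    "m_bark", "m_trunk", "m_branch", "m_leaf", "m_total",
)
COMPONENT_COLUMNS = tuple(f"m_{c}" for c in COMPONENTS)

#: Relative tolerance for the structural identity total == sum(components).
ADDITIVITY_RTOL = 1e-9


class TreeDataError(ValueError):
    """Malformed tree-level data (schema or per-row invariant violation)."""


@dataclass(frozen=True)
class TreeRecord:
    """One tree: identifiers, LiDAR covariates and component biomasses.

    ``age_group`` is the stand-development class 1 (young, 1-10 y) through
    5 (over-mature, >36 y).  ``m_total`` must equal the sum of the four
    components to within :data:`ADDITIVITY_RTOL`.
    """

    tree_id: str
    plot_id: str
    age_group: int
    lh: float
    lcd: float
    m_bark: float
    m_trunk: float
    m_branch: float
    m_leaf: float
    m_total: float


def validate_tree_frame(
    df: pd.DataFrame,
    *,
    additivity_rtol: float = ADDITIVITY_RTOL,
    lh_bounds: tuple[float, float] | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Validate per-row invariants; drop (or raise on) offending rows.

    Checks, per row: age group in 1..5; positive covariates; non-negative
    component biomasses; additivity of the total; and uniqueness of
    ``(plot_id, tree_id)`` — the second occurrence of a duplicate is
    rejected.  Diagnostics name the offending row numbers (0-based
    positions in ``df``).

    Returns the validated frame (a copy, with offending rows removed).
    """
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise TreeDataError(f"missing required columns: {missing}")
    out = df.loc[:, list(TREE_COLUMNS)].copy()

    numeric_cols = list(TREE_COLUMNS[2:])
    for c in numeric_cols:
        out[c] = pd.to_numeric(out[c], errors="coerce")

    problems: list[str] = []
    bad = pd.Series(False, index=out.index)

    def flag(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        mask = mask & ~bad
        if mask.any():
            rows = [int(i) for i in np.flatnonzero(mask.to_numpy())[:20]]
            problems.append(f"{reason}: rows {rows}" +
                            (" ..." if int(mask.sum()) > 20 else ""))
            bad |= mask

    flag(out[numeric_cols].isna().any(axis=1), "non-numeric field")
    flag(~out["age_group"].isin(AGE_GROUPS), "age_group outside 1..5")
    flag((out["lh"] <= 0) | (out["lcd"] <= 0), "non-positive covariate")
    if lh_bounds is not None:
        lo, hi = lh_bounds
        flag((out["lh"] < lo) | (out["lh"] > hi),
             f"lh outside configured bounds [{lo}, {hi}]")
    comp = out[list(COMPONENT_COLUMNS)]
    flag((comp < 0).any(axis=1), "negative component biomass")
    comp_sum = comp.sum(axis=1)
    denom = np.maximum(np.abs(out["m_total"].to_numpy()), 1e-300)
    flag(pd.Series(np.abs(out["m_total"].to_numpy() - comp_sum.to_numpy()) / denom,
                   index=out.index) > additivity_rtol,
         "total does not equal the sum of components (additivity)")
    flag(out.duplicated(subset=["plot_id", "tree_id"], keep="first"),
         "duplicate tree_id within plot")

    if problems:
        msg = "; ".join(problems)
        if strict:
            raise TreeDataError(msg)
        log.warning("rejected %d invalid row(s): %s", int(bad.sum()), msg)
        out = out.loc[~bad]

    out = out.astype({"age_group": int})
    return out.reset_index(drop=True)


def load_tree_csv(path: str | Path, *, strict: bool = False) -> pd.DataFrame:
    """Read a tree CSV, validating schema and per-row invariants.

    Invalid rows are rejected with logged row-number diagnostics
    (``strict=True`` raises instead).  A malformed header always raises.
    """
    df = pd.read_csv(path, dtype={"tree_id": str, "plot_id": str})
    if list(df.columns[: len(TREE_COLUMNS)]) != list(TREE_COLUMNS):
        raise TreeDataError(
            f"unexpected header in {path}: expected columns {list(TREE_COLUMNS)}, "
            f"got {list(df.columns)}"
        )
    return validate_tree_frame(df, strict=strict)


def write_tree_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tree frame to CSV ('.' decimal, UTF-8, 12 significant digits)."""
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise TreeDataError(f"missing required columns: {missing}")
    df.loc[:, list(TREE_COLUMNS)].to_csv(
        path, index=False, float_format="%.12g", encoding="utf-8"
    )


def records_to_frame(records) -> pd.DataFrame:
    """Build a tree frame from an iterable of :class:`TreeRecord`."""
    return pd.DataFrame([r.__dict__ for r in records], columns=list(TREE_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[TreeRecord]:
    return [TreeRecord(**row) for row in df.loc[:, list(TREE_COLUMNS)].to_dict("records")]
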