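"""Total allometry and ratio disaggregation from DBH and height.

National biomass standards for Chinese fir express total aboveground
biomass as a power law in diameter at breast height ``D`` (cm) and tree
height ``H`` (m),

    M_A = a0 * D**a1 * H**a2,

and split it into stem, bark, branch and leaf mass with fixed ratios
``g1, g2, g3`` of bark, branch and leaf biomass to stem biomass:

    (stem, bark, branch, leaf) = M_A * (1, g1, g2, g3) / (1 + g1 + g2 + g3).

The disaggregation conserves mass exactly for every input.  The standard's
own coefficient values are not distributed with this package; parameters
are user-supplied (a clearly labelled synthetic placeholder set ships for
tests and examples only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AllocationParams", "total_agb", "disaggregate", "PLACEHOLDER_PARAMS"]


@dataclass(frozen=True)
class AllocationParams:
    """Parameters of the total power law and the component ratios.

    ``per_group`` optionally overrides ``(g1, g2, g3)`` by age group; by
    default one shared ratio set applies to all trees.
    """

    a0: float
    a1: float
    a2: float
    g1: float
    g2: float
    g3: float
    per_group: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("a0 must be strictly positive")
        for name in ("g1", "g2", "g3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for g, ratios in self.per_group.items():
            if len(ratios) != 3 or any(r < 0 for r in ratios):
                raise ValueError(f"per_group[{g}] must be three non-negative ratios")

    def ratios(self, age_group: int | None = None) -> tuple[float, float, float]:
        if age_group is not None and age_group in self.per_group:
            return self.per_group[age_group]
        return (self.g1, self.g2, self.g3)

    @classmethod
    def from_json(cls, path: str | Path) -> "AllocationParams":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        per_group = {int(k): tuple(v) for k, v in obj.get("per_group", {}).items()}
        return cls(obj["a0"], obj["a1"], obj["a2"],
                   obj["g1"], obj["g2"], obj["g3"], per_group)

    def to_json(self, path: str | Path) -> None:
        obj = {k: getattr(self, k) for k in ("a0", "a1", "a2", "g1", "g2", "g3")}
        if self.per_group:
            obj["per_group"] = {str(k): list(v) for k, v in self.per_group.items()}
        Path(path).write_text(json.dumps(obj, indent=2), encoding="utf-8")


#: Synthetic placeholder coefficients, for tests and worked examples only.
#: These are NOT the national-standard values (which are user-supplied).
PLACEHOLDER_PARAMS = AllocationParams(
    a0=0.089, a1=2.0, a2=0.6, g1=0.18, g2=0.22, g3=0.12
)


def total_agb(d, h, p: AllocationParams):
    """Total aboveground biomass (kg) from DBH ``d`` (cm) and height ``h`` (m).

    Strictly increasing in both covariates whenever ``a1, a2 > 0``.
    Accepts scalars or arrays; non-positive inputs are a domain error.
    """
    d = np.asarray(d, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(d <= 0) or np.any(h <= 0):
        raise ValueError("DBH and height must be strictly positive")
    out = p.a0 * d ** p.a1 * h ** p.a2
    return float(out) if out.ndim == 0 else out


def disaggregate(m_a, p: AllocationParams, age_group: int | None = None):
    """Split total biomass into (stem, bark, branch, leaf), conserving mass.

    The four outputs sum to ``m_a`` exactly: the residual share of the
    first component is computed by subtraction rather than by its own
    ratio, so floating-point round-off cannot break additivity.
    """
    m_a = np.asarray(m_a, dtype=float)
    if np.any(m_a < 0):
        raise ValueError("total biomass must be non-negative")
    g1, g2, g3 = p.ratios(age_group)
    denom = 1.0 + g1 + g2 + g3  # >= 1 always
    bark = m_a * (g1 / denom)
    branch = m_a * (g2 / denom)
    leaf = m_a * (g3 / denom)
    stem = m_a - bark - branch - leaf  # exact conservation
    if m_a.ndim == 0:
        return (float(stem), float(bark), float(branch), float(leaf))
    return (stem, bark, branch, leaf)
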