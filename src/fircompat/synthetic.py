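"""Synthetic Chinese-fir stand generator.

The field data behind the published Chinese-fir allometries are withheld,
so every downstream stage of this package is exercised on generated
tree-level data that carry the same statistical structure the analysis
assumes:

* five stand-age groups, with per-group power-law component allometries
  in LiDAR tree height ``lh`` and crown diameter ``lcd`` (defaults are the
  published SUR system coefficients, :data:`fircompat.published.SUR_SYSTEM_FIT`);
* right-skewed, positivity-respecting covariates — ``lh`` from a truncated
  lognormal per age group (group medians increase with age), ``lcd`` as a
  power function of ``lh`` with lognormal scatter;
* multiplicative lognormal component errors, mean one, with a Gaussian
  copula inducing cross-component correlation — the correlation that makes
  joint (SUR) estimation genuinely different from equationwise fitting;
* exact additivity: the total is always computed as the sum of the four
  components, never generated independently.

Draw order is part of the format contract: groups are generated in age
order 1..5, and within a group the draws are (1) lh, (2) the lcd noise,
(3) the n-by-4 component error matrix.  A single seeded
:class:`numpy.random.Generator` threads through all draws, so output is
byte-identical for identical (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .allocation import AllocationParams, disaggregate, total_agb
from .published import AGE_GROUPS, COMPONENTS, SUR_SYSTEM_FIT
from .records import TREE_COLUMNS

__all__ = [
    "ComponentTruth",
    "CovariateModel",
    "GeneratorConfig",
    "DbhHeightModel",
    "default_truth",
    "default_config",
    "component_mean",
    "true_components",
    "generate_stand",
    "generate_from_allocation",
    "summarize_by_age_group",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class ComponentTruth:
    """Power-law allometry for one component: per-group scale, shared exponents."""

    scales: dict[int, float]
    exp_lh: float
    exp_lcd: float


@dataclass(frozen=True)
class CovariateModel:
    """Per-group truncated-lognormal ``lh`` and a power-law ``lcd | lh``.

    ``ln lh ~ Normal(ln median[g], sigma_log)`` truncated to ``lh_bounds``;
    ``lcd = lcd_coef * lh**lcd_exp * LogNormal(-s^2/2, s)`` with
    ``s = lcd_sigma_log`` (mean-one noise).  Group medians increase with
    age; the pooled mean and envelope land inside the published LiDAR
    metric summary.
    """

    lh_median: dict[int, float] = field(
        default_factory=lambda: {1: 10.0, 2: 12.5, 3: 14.5, 4: 16.5, 5: 17.5}
    )
    lh_sigma_log: float = 0.25
    lh_bounds: tuple[float, float] = (2.7, 31.7)
    lcd_coef: float = 0.23
    lcd_exp: float = 0.9
    lcd_sigma_log: float = 0.45

    def validate(self) -> None:
        lo, hi = self.lh_bounds
        if not (0 < lo < hi):
            raise ConfigurationError("lh bounds must satisfy 0 < lower < upper")
        for g in AGE_GROUPS:
            med = self.lh_median.get(g)
            if med is None or not (lo < med < hi):
                raise ConfigurationError(
                    f"lh_median for age group {g} must lie inside {self.lh_bounds}"
                )
        if self.lh_sigma_log <= 0 or self.lcd_sigma_log < 0:
            raise ConfigurationError("log-scale spreads must be positive")
        if self.lcd_coef <= 0:
            raise ConfigurationError("lcd_coef must be strictly positive")


def default_truth() -> dict[str, ComponentTruth]:
    """Published SUR system coefficients as the generating allometry."""
    return {
        c: ComponentTruth(
            scales=dict(SUR_SYSTEM_FIT[c]["scales"]),
            exp_lh=SUR_SYSTEM_FIT[c]["exp_lh"],
            exp_lcd=SUR_SYSTEM_FIT[c]["exp_lcd"],
        )
        for c in COMPONENTS
    }


def _default_corr() -> np.ndarray:
    return np.full((4, 4), 0.5) + 0.5 * np.eye(4)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic stand.

    Defaults reproduce the published study conditions: 20,836 trees in
    five age groups (7,481 young and 1,885 over-mature as reported; the
    unreported middle groups interpolated to the reported total), the
    published system allometry as truth, residual coefficient of
    variation 0.30 per component and pairwise error correlation 0.5.
    """

    n_per_age_group: dict[int, int] = field(
        default_factory=lambda: {1: 7481, 2: 4600, 3: 3600, 4: 3270, 5: 1885}
    )
    covariates: CovariateModel = field(default_factory=CovariateModel)
    truth: dict[str, ComponentTruth] = field(default_factory=default_truth)
    error_cv: dict[str, float] = field(
        default_factory=lambda: {c: 0.30 for c in COMPONENTS}
    )
    error_corr: np.ndarray = field(default_factory=_default_corr)
    seed: int = 0
    trees_per_plot: int = 157  # ~ published 20,836 trees / 133 plots

    def validate(self) -> None:
        for g in AGE_GROUPS:
            n = self.n_per_age_group.get(g)
            if n is None or n < 0:
                raise ConfigurationError(f"n_per_age_group[{g}] must be >= 0")
        self.covariates.validate()
        for c in COMPONENTS:
            if c not in self.truth:
                raise ConfigurationError(f"missing truth for component {c!r}")
            t = self.truth[c]
            for g in AGE_GROUPS:
                if t.scales.get(g, 0.0) <= 0:
                    raise ConfigurationError(
                        f"truth scale for {c!r}, age group {g} must be > 0"
                    )
            if self.error_cv.get(c, -1.0) < 0:
                raise ConfigurationError(f"error CV for {c!r} must be >= 0")
        R = np.asarray(self.error_corr, dtype=float)
        if R.shape != (4, 4):
            raise ConfigurationError("error correlation matrix must be 4x4")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ConfigurationError("error correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ConfigurationError("error correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ConfigurationError(
                "error correlation matrix must be positive semidefinite"
            )

    # -- YAML-friendly (de)serialisation ---------------------------------
    def to_dict(self) -> dict:
        return {
            "n_per_age_group": {int(k): int(v) for k, v in self.n_per_age_group.items()},
            "covariates": {
                "lh_median": {int(k): float(v) for k, v in self.covariates.lh_median.items()},
                "lh_sigma_log": self.covariates.lh_sigma_log,
                "lh_bounds": list(self.covariates.lh_bounds),
                "lcd_coef": self.covariates.lcd_coef,
                "lcd_exp": self.covariates.lcd_exp,
                "lcd_sigma_log": self.covariates.lcd_sigma_log,
            },
            "truth": {
                c: {
                    "scales": {int(k): float(v) for k, v in t.scales.items()},
                    "exp_lh": t.exp_lh,
                    "exp_lcd": t.exp_lcd,
                }
                for c, t in self.truth.items()
            },
            "error_cv": {c: float(v) for c, v in self.error_cv.items()},
            "error_corr": np.asarray(self.error_corr, dtype=float).tolist(),
            "seed": int(self.seed),
            "trees_per_plot": int(self.trees_per_plot),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "GeneratorConfig":
        base = cls()
        cov = obj.get("covariates", {})
        covariates = CovariateModel(
            lh_median={int(k): float(v)
                       for k, v in cov.get("lh_median", base.covariates.lh_median).items()},
            lh_sigma_log=float(cov.get("lh_sigma_log", base.covariates.lh_sigma_log)),
            lh_bounds=tuple(cov.get("lh_bounds", base.covariates.lh_bounds)),
            lcd_coef=float(cov.get("lcd_coef", base.covariates.lcd_coef)),
            lcd_exp=float(cov.get("lcd_exp", base.covariates.lcd_exp)),
            lcd_sigma_log=float(cov.get("lcd_sigma_log", base.covariates.lcd_sigma_log)),
        )
        truth = base.truth
        if "truth" in obj:
            truth = {
                c: ComponentTruth(
                    scales={int(k): float(v) for k, v in t["scales"].items()},
                    exp_lh=float(t["exp_lh"]),
                    exp_lcd=float(t["exp_lcd"]),
                )
                for c, t in obj["truth"].items()
            }
        return cls(
            n_per_age_group={int(k): int(v)
                             for k, v in obj.get("n_per_age_group",
                                                 base.n_per_age_group).items()},
            covariates=covariates,
            truth=truth,
            error_cv={c: float(v) for c, v in obj.get("error_cv", base.error_cv).items()},
            error_corr=np.asarray(obj.get("error_corr", base.error_corr), dtype=float),
            seed=int(obj.get("seed", base.seed)),
            trees_per_plot=int(obj.get("trees_per_plot", base.trees_per_plot)),
        )


def default_config(**overrides) -> GeneratorConfig:
    """The study-condition default configuration, with field overrides."""
    return replace(GeneratorConfig(), **overrides)


# ---------------------------------------------------------------------------
# Mean structure
# ---------------------------------------------------------------------------

def component_mean(truth: ComponentTruth, lh, lcd, age_group):
    """Deterministic component biomass: ``scale[g] * lh**b * lcd**c``."""
    lh = np.asarray(lh, dtype=float)
    lcd = np.asarray(lcd, dtype=float)
    if np.any(lh <= 0) or np.any(lcd <= 0):
        raise ValueError("covariates must be strictly positive")
    ag = np.asarray(age_group)
    scale = np.vectorize(lambda g: truth.scales[int(g)])(ag).astype(float)
    out = scale * lh ** truth.exp_lh * lcd ** truth.exp_lcd
    return float(out) if out.ndim == 0 else out


def true_components(config: GeneratorConfig, lh, lcd, age_group) -> dict[str, np.ndarray]:
    """Noise-free component means (plus total) under the config's truth."""
    out = {c: component_mean(config.truth[c], lh, lcd, age_group) for c in COMPONENTS}
    out["total"] = sum(out[c] for c in COMPONENTS)
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _corr_factor(R: np.ndarray) -> np.ndarray:
    """Factor F with F @ F.T == R, valid for any PSD correlation matrix."""
    w, V = np.linalg.eigh(np.asarray(R, dtype=float))
    if w.min() < -1e-10:
        raise ConfigurationError("error correlation matrix is not positive semidefinite")
    return V * np.sqrt(np.clip(w, 0.0, None))


def _draw_lh(rng: np.random.Generator, n: int, cov: CovariateModel, group: int) -> np.ndarray:
    mu = math.log(cov.lh_median[group])
    s = cov.lh_sigma_log
    lo = (math.log(cov.lh_bounds[0]) - mu) / s
    hi = (math.log(cov.lh_bounds[1]) - mu) / s
    z = stats.truncnorm.rvs(lo, hi, size=n, random_state=rng)
    return np.exp(mu + s * z)


def generate_stand(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a tree frame under ``config`` (deterministic given seed).

    Component biomass = per-group power-law mean x correlated mean-one
    lognormal error; the total column is the exact sum of the four
    component columns.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    F = _corr_factor(config.error_corr)
    sigma = np.array(
        [math.sqrt(math.log1p(config.error_cv[c] ** 2)) for c in COMPONENTS]
    )

    frames = []
    for g in AGE_GROUPS:
        n = config.n_per_age_group[g]
        if n == 0:
            continue
        lh = _draw_lh(rng, n, config.covariates, g)
        z_lcd = rng.standard_normal(n)
        s = config.covariates.lcd_sigma_log
        lcd = (config.covariates.lcd_coef * lh ** config.covariates.lcd_exp
               * np.exp(s * z_lcd - 0.5 * s * s))
        Z = rng.standard_normal((n, 4)) @ F.T  # Gaussian copula, corr R
        mult = np.exp(Z * sigma - 0.5 * sigma ** 2)  # mean-one lognormal

        data = {
            "tree_id": [f"AG{g}_{i:05d}" for i in range(n)],
            "plot_id": [f"P{g}_{i // config.trees_per_plot + 1:03d}" for i in range(n)],
            "age_group": np.full(n, g, dtype=int),
            "lh": lh,
            "lcd": lcd,
        }
        for j, c in enumerate(COMPONENTS):
            data[f"m_{c}"] = component_mean(config.truth[c], lh, lcd, g) * mult[:, j]
        frame = pd.DataFrame(data)
        frame["m_total"] = (frame["m_bark"] + frame["m_trunk"]
                            + frame["m_branch"] + frame["m_leaf"])
        frames.append(frame)

    if not frames:
        return pd.DataFrame(columns=list(TREE_COLUMNS))
    return pd.concat(frames, ignore_index=True).loc[:, list(TREE_COLUMNS)]


@dataclass(frozen=True)
class DbhHeightModel:
    """Field-covariate model for the allocation generation path.

    DBH (cm) is lognormal; height follows a power law in DBH with
    lognormal scatter; the LiDAR proxies are height and a crown-diameter
    power law in DBH, each with multiplicative noise (``proxy_sigma_log=0``
    switches the noise off).
    """

    dbh_median: float = 14.0
    dbh_sigma_log: float = 0.35
    dbh_bounds: tuple[float, float] = (2.0, 60.0)
    height_coef: float = 1.6
    height_exp: float = 0.75
    height_sigma_log: float = 0.10
    crown_coef: float = 0.35
    crown_exp: float = 0.70
    proxy_sigma_log: float = 0.05


def generate_from_allocation(
    n: int,
    alloc: AllocationParams,
    model: DbhHeightModel | None = None,
    seed: int = 0,
    *,
    max_retries: int = 1000,
) -> pd.DataFrame:
    """Generate trees whose biomass follows the allocation equations.

    Draws (DBH, height), computes the total from the power law and the
    components from the ratio split (additivity exact), then attaches
    ``lh``/``lcd`` as noisy proxies of height and crown diameter.  Extra
    columns ``dbh`` and ``height`` are included after the standard schema.
    Draws outside the DBH bounds are redrawn up to ``max_retries`` times.
    """
    model = model or DbhHeightModel()
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(columns=list(TREE_COLUMNS) + ["dbh", "height"])

    dbh = np.empty(0)
    for _ in range(max_retries):
        draw = model.dbh_median * np.exp(
            model.dbh_sigma_log * rng.standard_normal(n - dbh.size)
        )
        ok = draw[(draw >= model.dbh_bounds[0]) & (draw <= model.dbh_bounds[1])]
        dbh = np.concatenate([dbh, ok])
        if dbh.size >= n:
            dbh = dbh[:n]
            break
    else:
        raise RuntimeError(
            f"could not draw {n} DBH values inside {model.dbh_bounds} "
            f"after {max_retries} rounds"
        )

    s_h = model.height_sigma_log
    height = (model.height_coef * dbh ** model.height_exp
              * np.exp(s_h * rng.standard_normal(n) - 0.5 * s_h * s_h))
    total = total_agb(dbh, height, alloc)
    stem, bark, branch, leaf = disaggregate(total, alloc)

    s_p = model.proxy_sigma_log
    lh = height * np.exp(s_p * rng.standard_normal(n) - 0.5 * s_p * s_p)
    crown = model.crown_coef * dbh ** model.crown_exp
    lcd = crown * np.exp(s_p * rng.standard_normal(n) - 0.5 * s_p * s_p)

    # age classes assigned from DBH quintiles: a plausible stand-in for the
    # stand-age record the allocation path has no access to
    qs = np.quantile(dbh, [0.2, 0.4, 0.6, 0.8])
    age_group = 1 + np.searchsorted(qs, dbh)

    df = pd.DataFrame({
        "tree_id": [f"AL_{i:05d}" for i in range(n)],
        "plot_id": ["P_alloc_001"] * n,
        "age_group": age_group.astype(int),
        "lh": lh,
        "lcd": lcd,
        "m_bark": bark,
        "m_trunk": stem,
        "m_branch": branch,
        "m_leaf": leaf,
        "dbh": dbh,
        "height": height,
    })
    df["m_total"] = df["m_bark"] + df["m_trunk"] + df["m_branch"] + df["m_leaf"]
    return df.loc[:, list(TREE_COLUMNS) + ["dbh", "height"]]


def summarize_by_age_group(df: pd.DataFrame) -> pd.DataFrame:
    """Per-(age group, component) max/min/mean/SD table.

    SD uses the n-1 denominator; a group with fewer than two trees reports
    SD as NaN (undefined), never zero.  Mirrors the layout of the
    published field-biomass summary.
    """
    if len(df) == 0:
        raise ValueError("cannot summarise an empty record set")
    rows = []
    for g, sub in df.groupby("age_group", sort=True):
        for comp in COMPONENTS + ("total",):
            x = sub[f"m_{comp}"].to_numpy(dtype=float)
            rows.append({
                "age_group": int(g),
                "component": comp,
                "n": x.size,
                "max": float(x.max()),
                "min": float(x.min()),
                "mean": float(x.mean()),
                "sd": float(np.std(x, ddof=1)) if x.size >= 2 else float("nan"),
            })
    return pd.DataFrame(rows)
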