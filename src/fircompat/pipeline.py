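"""End-to-end orchestration: simulate → split → base-model selection →
dummy model → NSUR → evaluation report.

A run consumes a :class:`PipelineConfig` (usually from YAML), executes
the stages in order, and writes every artifact — tree CSVs, fit JSONs,
the ranking and report CSVs, a metrics JSON and a run log — into a run
directory.  Each artifact embeds provenance (seed, config hash), and a
rerun with an identical config is numerically identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import base_models, dummy_models, metrics, nsur, synthetic
from .published import ALL_RESPONSES, COMPONENTS
from .records import load_tree_csv, write_tree_csv

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_DEFAULT_FORMS = ("logistic", "linear", "exponential", "power")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Either ``input_csv`` (existing tree data) or ``generator`` (synthetic
    stand settings, :class:`fircompat.synthetic.GeneratorConfig` as a
    dict) must be provided.  ``seed`` drives every stochastic stage:
    the generator uses ``seed`` and the splitter ``seed + 1``.
    """

    input_csv: str | None = None
    generator: dict | None = None
    train_fraction: float = 0.7
    components: tuple[str, ...] = ALL_RESPONSES
    forms: tuple[str, ...] = _DEFAULT_FORMS
    seed: int = 42
    sigma_divisor: str = "n"
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError("exactly one of input_csv or generator must be set")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(f"input file not found: {self.input_csv}")
        unknown = set(self.forms) - set(base_models.FORMS)
        if unknown:
            raise ValueError(f"unknown model form(s): {sorted(unknown)}")
        unknown = set(self.components) - set(ALL_RESPONSES)
        if unknown:
            raise ValueError(f"unknown component(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            obj = yaml.safe_load(fh) or {}
        kwargs = {k: obj[k] for k in (
            "input_csv", "generator", "train_fraction", "seed",
            "sigma_divisor", "log_level",
        ) if k in obj}
        if "components" in obj:
            kwargs["components"] = tuple(obj["components"])
        if "forms" in obj:
            kwargs["forms"] = tuple(obj["forms"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "input_csv": self.input_csv,
            "generator": self.generator,
            "train_fraction": self.train_fraction,
            "components": list(self.components),
            "forms": list(self.forms),
            "seed": self.seed,
            "sigma_divisor": self.sigma_divisor,
            "log_level": self.log_level,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True), encoding="utf-8")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full analysis; returns the run directory.

    Stage order: data acquisition (load or simulate), stratified 7:3
    split, per-component candidate-form comparison with AIC ranking,
    age-group dummy model, NSUR system, and a combined evaluation report.
    A stage failure aborts with the stage named; artifacts written up to
    that point are left in place for debugging.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("fircompat")
    root.addHandler(handler)
    root.setLevel(config.log_level)

    provenance = {"seed": config.seed, "config_sha256_16": config.digest()}
    (outdir / "config_used.yaml").write_text(
        yaml.safe_dump({**config.to_dict(), "provenance": provenance}),
        encoding="utf-8",
    )
    stage = "setup"
    try:
        # -- data -----------------------------------------------------------
        stage = "data"
        if config.input_csv is not None:
            trees = load_tree_csv(config.input_csv)
            log.info("loaded %d trees from %s", len(trees), config.input_csv)
        else:
            gen_cfg = synthetic.GeneratorConfig.from_dict(
                {**(config.generator or {}), "seed": config.seed}
            )
            trees = synthetic.generate_stand(gen_cfg)
            write_tree_csv(trees, outdir / "stand.csv")
            log.info("generated %d trees", len(trees))
        synthetic.summarize_by_age_group(trees).to_csv(
            outdir / "summary_by_age_group.csv", index=False)

        stage = "split"
        train, test = base_models.split(
            trees, base_models.SplitSpec(config.train_fraction, seed=config.seed + 1)
        )
        write_tree_csv(train, outdir / "train.csv")
        write_tree_csv(test, outdir / "test.csv")

        stage = "base_models"
        fits_dir = outdir / "fits"
        fits_dir.mkdir(exist_ok=True)
        base_fits: dict[str, dict[str, base_models.BaseModelFit]] = {}
        selections = {}
        for comp in config.components:
            base_fits[comp] = {}
            for form in config.forms:
                fit = base_models.fit_base(train, form, comp)
                base_fits[comp][form] = fit
                _write_json(fits_dir / f"base_{form}_{comp}.json",
                            {**fit.to_dict(), "provenance": provenance})
            ranking, selected = base_models.rank_models(list(base_fits[comp].values()))
            ranking.to_csv(outdir / f"ranking_{comp}.csv", index=False)
            selections[comp] = selected
            log.info("selected base form for %s: %s", comp, selected)
        _write_json(outdir / "selected_forms.json", selections)

        stage = "dummy_models"
        dummy_fits = {}
        for comp in config.components:
            dfit = dummy_models.fit_dummy(train, comp)
            dummy_fits[comp] = dfit
            _write_json(fits_dir / f"dummy_{comp}.json",
                        {**dfit.to_dict(), "provenance": provenance})

        stage = "nsur"
        starts = {c: dummy_fits[c] for c in COMPONENTS if c in dummy_fits}
        sur_fit = nsur.fit_nsur(
            train,
            start=starts if len(starts) == len(COMPONENTS) else None,
            sigma_divisor=config.sigma_divisor,
        )
        _write_json(fits_dir / "sur_system.json",
                    {**sur_fit.to_dict(), "provenance": provenance})

        stage = "report"
        rows = []
        for comp in config.components:
            models: dict[str, tuple] = {
                form: (fit.predict, fit.k) for form, fit in base_fits[comp].items()
            }
            models["dummy"] = (dummy_fits[comp].predict, dummy_fits[comp].k)
            models["sur"] = (
                (lambda frame, c=comp: sur_fit.predict(frame)[
                    c if c != "total" else "total"]),
                7,
            )
            report = metrics.compare_report(
                models, train, test, f"m_{comp}", baseline=selections[comp]
            )
            report.insert(0, "component", comp)
            rows.append(report)
        report = pd.concat(rows, ignore_index=True)
        report.to_csv(outdir / "report.csv", index=False)
        _write_json(outdir / "metrics.json", {
            "provenance": provenance,
            "selected_forms": selections,
            "metrics": report.drop(columns=["component"]).assign(
                component=report["component"]).to_dict("records"),
        })
    except Exception:
        log.exception("pipeline stage %r failed; partial artifacts kept in %s",
                      stage, outdir)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
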