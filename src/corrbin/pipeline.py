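"""Config-driven end-to-end runs: simulate -> fit -> compare -> report.

A YAML config names either a generator parameterization or an existing
cohort CSV, the model list, and the output directory.  One top-level seed
fans out to per-stage seeds through numpy's SeedSequence spawning, so the
simulation and the comparison draw from isolated streams; the manifest
records everything needed to reproduce the run bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .cohort import GeneratorParams, default_addhealth_params, generate, read_cohort, write_cohort
from .compare import MODEL_NAMES, ComparisonReport, default_model_configs, run_comparison

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run description."""

    generator: Optional[dict] = None  # GeneratorParams overrides, or {} for defaults
    cohort_path: Optional[str] = None
    models: list = field(default_factory=lambda: list(MODEL_NAMES))
    seed: int = 0
    outdir: str = "corrbin_run"
    fast: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.generator is None) == (self.cohort_path is None):
            raise ConfigError(
                "config must set exactly one of 'generator' and 'cohort_path'"
            )
        if not self.models:
            raise ConfigError("config field 'models' must be a non-empty list")
        unknown = [m for m in self.models if m not in MODEL_NAMES]
        if unknown:
            raise ConfigError(
                f"config field 'models' names unknown model(s) {unknown}; "
                f"valid names: {list(MODEL_NAMES)}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("config field 'seed' must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config field(s): {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            "generator": self.generator,
            "cohort_path": self.cohort_path,
            "models": list(self.models),
            "seed": int(self.seed),
            "outdir": str(self.outdir),
            "fast": self.fast,
            "log_level": self.log_level,
        }


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(2)
    return {
        "simulate": int(children[0].generate_state(1)[0] % (2**31)),
        "compare": int(children[1].generate_state(1)[0] % (2**31)),
    }


def _build_params(overrides: dict, seed: int) -> GeneratorParams:
    params = default_addhealth_params(seed=seed)
    for key, val in (overrides or {}).items():
        if key == "beta":
            params.beta.update(val)
        elif hasattr(params, key):
            setattr(params, key, val)
        else:
            raise ConfigError(f"unknown generator field {key!r}")
    params.seed = seed
    return params


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Execute the full pipeline and write all artifacts under the outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    if config.generator is not None:
        params = _build_params(config.generator, seeds["simulate"])
        cohort = generate(params)
        cohort_file = outdir / "cohort.csv"
        write_cohort(cohort, cohort_file)
    else:
        cohort = read_cohort(config.cohort_path)
        cohort_file = Path(config.cohort_path)

    configs = default_model_configs(cohort, fast=config.fast)
    report = run_comparison(
        cohort, configs=configs, seed=seeds["compare"], models=tuple(config.models)
    )

    report.auc_table.to_csv(outdir / "auc_table.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                "auc": report.auc_table.to_dict(orient="records"),
                "seed": report.seed,
                "meta": report.meta,
            },
            fh,
            indent=1,
        )
    if report.coefficients is not None:
        report.coefficients.to_csv(outdir / "coefficients.csv")
    manifest = {
        "tool": "corrbin",
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "cohort": str(cohort_file),
        "outputs": ["cohort.csv", "auc_table.csv", "report.json", "coefficients.csv"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return report


def replay_manifest(path) -> ComparisonReport:
    """Re-run a pipeline from its manifest (reproduces all outputs)."""
    with open(path) as fh:
        manifest = json.load(fh)
    cfg = RunConfig(**manifest["config"])
    return run_pipeline(cfg)
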