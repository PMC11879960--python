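"""Run configuration: one validated object wiring every pipeline stage.

Configs are YAML (or JSON) mappings with nested blocks mirroring the stage
parameter objects; unknown keys are rejected with a close-match suggestion,
and the effective (defaults-merged) config is echoed into each run's output
directory for provenance.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cohort as cohort_mod
from . import experiments as exp_mod
from . import preprocess as prep_mod
from .health import (ACTIVITIES, INTENSITIES, FitnessWeights, MetricNorms,
                     ResponseParams)
from .optimize import DecisionSpace, OptimizerConfig

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class ExperimentSettings:
    algorithms: tuple = ("ga", "pso", "aco", "sa", "de", "abc")
    n_replicates: int = 10
    confidence: float = 0.95
    perturbations: tuple = (-0.05, 0.05)
    sensitivity_algorithm: str = "aco"
    sensitivity_seeds: tuple = (0, 1, 2)
    convergence_seeds: tuple = (0,)


@dataclass(frozen=True)
class RunConfig:
    cohort: cohort_mod.CohortSpec = field(default_factory=cohort_mod.CohortSpec)
    preprocess: prep_mod.PreprocessConfig = field(default_factory=prep_mod.PreprocessConfig)
    space: DecisionSpace = field(default_factory=DecisionSpace)
    response: ResponseParams = field(default_factory=ResponseParams)
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    norms: MetricNorms = field(default_factory=MetricNorms)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    experiment: ExperimentSettings = field(default_factory=ExperimentSettings)
    seed: int = 0
    outdir: str = "runs/default"


_BLOCKS = {
    "cohort": cohort_mod.CohortSpec,
    "preprocess": prep_mod.PreprocessConfig,
    "space": DecisionSpace,
    "response": ResponseParams,
    "weights": FitnessWeights,
    "norms": MetricNorms,
    "optimizer": OptimizerConfig,
    "experiment": ExperimentSettings,
}
_TUPLE_KEYS = {"age_range", "t_bounds", "n_range", "iqr_features", "algorithms",
               "perturbations", "sensitivity_seeds", "convergence_seeds",
               "delta_bmi", "delta_f", "calories", "delta_hr"}


def _reject_unknown(given: dict, allowed, where: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, list(allowed), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {where}{suggestion}")


def _coerce(cls, data: dict, where: str):
    names = [f.name for f in dataclasses.fields(cls)]
    _reject_unknown(data, names, where)
    kwargs = {}
    for k, v in data.items():
        if k == "met_table":
            v = {(a, i): float(v[a][i]) for a in ACTIVITIES for i in INTENSITIES}
        elif k == "category_orders":
            v = {kk: tuple(vv) for kk, vv in v.items()}
        elif k in _TUPLE_KEYS and isinstance(v, (list, tuple)):
            v = tuple(v)
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def config_from_dict(data: dict | None) -> RunConfig:
    data = dict(data or {})
    _reject_unknown(data, list(_BLOCKS) + ["seed", "outdir"], "run config")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            block = data[name]
            if not isinstance(block, dict):
                raise ConfigError(f"config block {name!r} must be a mapping")
            kwargs[name] = _coerce(cls, block, name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "outdir" in data:
        kwargs["outdir"] = str(data["outdir"])
    return RunConfig(**kwargs)


def config_to_dict(config: RunConfig) -> dict:
    def unstruct(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: unstruct(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            if obj and isinstance(next(iter(obj)), tuple):   # met_table
                out: dict = {}
                for (a, i), v in obj.items():
                    out.setdefault(a, {})[i] = float(v)
                return out
            return {k: unstruct(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [unstruct(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj
    return unstruct(config)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run config; empty file → all defaults."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministically derive n independent sub-seeds (< 2^31) from one
    global seed via numpy's SeedSequence."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint32)]


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, stages=("synth", "preprocess", "compare",
                                            "sensitivity")) -> dict:
    """Execute the configured stages, writing every artifact plus a MANIFEST
    and the effective config into ``config.outdir``.

    Returns the manifest dict. Raises the originating exception (with the
    stage name attached) on failure; partial outputs and a MANIFEST marked
    incomplete are left on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(config, outdir / "effective_config.yaml")
    manifest: dict = {"complete": False, "seed": config.seed, "stages": {}}
    seeds = spawn_seeds(config.seed, 4)

    def note(stage: str, files: list, t0: float) -> None:
        manifest["stages"][stage] = {"files": files, "seconds": round(time.time() - t0, 3)}
        with open(outdir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    clean = None
    try:
        if "synth" in stages:
            t0 = time.time()
            spec = dataclasses.replace(config.cohort, seed=seeds[0])
            raw = cohort_mod.generate_cohort(spec)
            cohort_mod.write_cohort_csv(raw, outdir / "cohort.csv")
            logger.info("synth: %d students (seed %d)", len(raw), seeds[0])
            note("synth", ["cohort.csv"], t0)
        if "preprocess" in stages:
            t0 = time.time()
            raw = cohort_mod.read_cohort_csv(outdir / "cohort.csv")
            clean, report = prep_mod.preprocess_cohort(raw, config.preprocess)
            cohort_mod.write_cohort_csv(clean, outdir / "cohort_clean.csv")
            report.to_json(outdir / "preprocess_report.json")
            logger.info("preprocess: %d -> %d records", report.n_in, report.n_out)
            note("preprocess", ["cohort_clean.csv", "preprocess_report.json"], t0)
        if clean is None and ({"compare", "sensitivity"} & set(stages)):
            clean = cohort_mod.read_cohort_csv(outdir / "cohort_clean.csv")
        if "compare" in stages:
            t0 = time.time()
            exp = config.experiment
            summary = exp_mod.summary_experiment(
                clean, exp.algorithms, config.space, config.optimizer,
                config.weights, config.response, config.norms,
                n_replicates=exp.n_replicates, confidence=exp.confidence,
                seeds=spawn_seeds(seeds[1], exp.n_replicates))
            summary.to_csv(outdir / "summary.csv")
            with open(outdir / "summary.json", "w") as fh:
                json.dump(summary.to_dict(), fh, indent=2)
            ranks = exp_mod.rank_algorithms(summary)
            ranks.to_csv(outdir / "ranks.csv")
            traj = exp_mod.convergence_experiment(
                clean, exp.algorithms, config.space, config.optimizer,
                config.weights, config.response, config.norms,
                seeds=[spawn_seeds(seeds[1], 1)[0]])
            traj.to_csv(outdir / "trajectories.csv", index=False)
            logger.info("compare: %d algorithms x %d replicates",
                        len(exp.algorithms), exp.n_replicates)
            note("compare", ["summary.csv", "summary.json", "ranks.csv",
                             "trajectories.csv"], t0)
        if "sensitivity" in stages:
            t0 = time.time()
            exp = config.experiment
            sens = exp_mod.sensitivity_experiment(
                clean, config.space, config.optimizer, config.weights,
                config.response, config.norms,
                perturbations=exp.perturbations,
                algorithm=exp.sensitivity_algorithm,
                seeds=spawn_seeds(seeds[2], len(exp.sensitivity_seeds)))
            sens.to_csv(outdir / "sensitivity.csv")
            with open(outdir / "sensitivity.json", "w") as fh:
                json.dump(sens.to_dict(), fh, indent=2)
            logger.info("sensitivity: done")
            note("sensitivity", ["sensitivity.csv", "sensitivity.json"], t0)
    except Exception as exc:
        failed = [s for s in stages if s not in manifest["stages"]]
        raise RuntimeError(f"stage {failed[0] if failed else '?'} failed: {exc}") from exc
    manifest["complete"] = True
    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
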