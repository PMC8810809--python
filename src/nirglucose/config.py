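"""Run configuration for the command-line workflow.

A single YAML file drives every command; keys mirror the dataclasses of the
simulation (`OpticalModelConfig`, `GlucoseMixture`, `CohortDistributions`) and
training (`TrainingConfig`) layers, so any default can be overridden from the
file.  The seed is explicit and a manifest (config hash + seed) accompanies
every simulated dataset so reruns are byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .cohort import CohortDistributions, GlucoseMixture, OpticalModelConfig
from .network import TrainingConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a workflow run needs: cohort sizes, generator, training,
    evaluation settings.

    Train and test cohorts are generated from disjoint person pools (distinct
    sub-seeds and id prefixes), mirroring an evaluation cohort of subjects not
    included in model training.
    """

    seed: int = 0
    n_train: int = 401
    n_test: int = 234
    samples_per_person: int = 1
    optical: OpticalModelConfig = field(default_factory=OpticalModelConfig)
    cohort: CohortDistributions = field(default_factory=CohortDistributions)
    glucose: GlucoseMixture = field(default_factory=GlucoseMixture)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    threshold: float = 126.0
    cv_folds: int = 10
    bland_altman_mode: str = "percent"
    filter_window: int = 5
    monitor_baseline: float = 95.0
    monitor_duration: float = 480.0

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        return {
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "samples_per_person": self.samples_per_person,
            "optical": enc(self.optical),
            "cohort": enc(self.cohort),
            "glucose": enc(self.glucose),
            "training": enc(self.training),
            "threshold": self.threshold,
            "cv_folds": self.cv_folds,
            "bland_altman_mode": self.bland_altman_mode,
            "filter_window": self.filter_window,
            "monitor_baseline": self.monitor_baseline,
            "monitor_duration": self.monitor_duration,
        }


def _build(cls, section: dict, what: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {what} config keys: {sorted(unknown)}")
    coerced = {}
    for k, v in section.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path=None, seed=None, **overrides) -> RunConfig:
    """Load a RunConfig from YAML; ``seed`` (if given) overrides the file.

    The seed propagates into the optical and training sections unless those
    sections set their own.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides)

    optical = dict(raw.pop("optical", {}))
    cohort = dict(raw.pop("cohort", {}))
    glucose = dict(raw.pop("glucose", {}))
    training = dict(raw.pop("training", {}))

    top = {k: v for k, v in raw.items()}
    if seed is not None:
        top["seed"] = seed
    run_seed = int(top.get("seed", 0))
    optical.setdefault("seed", run_seed)
    training.setdefault("seed", run_seed)

    valid_top = {f.name for f in dataclasses.fields(RunConfig)} - {
        "optical", "cohort", "glucose", "training"
    }
    unknown = set(top) - valid_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(
        optical=_build(OpticalModelConfig, optical, "optical"),
        cohort=_build(CohortDistributions, cohort, "cohort"),
        glucose=_build(GlucoseMixture, glucose, "glucose"),
        training=_build(TrainingConfig, training, "training"),
        **top,
    )


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration, for run manifests."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
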