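"""Run configuration: one YAML file driving simulate -> preprocess -> evaluate.

The configuration is deliberately flat and fully serializable so every
artifact a run writes can echo the resolved configuration plus a content
hash, making sweeps reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .networks import NetworkSpec, TrainingConfig
from .preprocessing import PreprocessingConfig
from .simulate import SimulationConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Validation failure, reported with the offending field path."""


def _build_section(cls, data: dict, path: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown field(s) {sorted(unknown)}")
    # YAML lists arrive as lists; dataclasses expect tuples for frozen-ish fields
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class RunConfig:
    """Everything an end-to-end evaluation run needs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    #: None selects the per-architecture default recipe for each network
    training: TrainingConfig | None = None
    classifiers: tuple[str, ...] = ("cnn1", "cca")
    n_folds: int = 10
    train_shifts_ms: tuple[float, ...] = (60, 30, 20, 15, 12, 10)
    test_shift_ms: float = 10.0
    seed: int = 0
    output_dir: str = "ssvepkit_output"

    def __post_init__(self) -> None:
        known = {"cnn1", "cnn2", "nn", "cca", "cca_knn", "msi"}
        bad = set(self.classifiers) - known
        if bad:
            raise ConfigError(f"classifiers: unknown method(s) {sorted(bad)}")
        if self.n_folds < 1:
            raise ConfigError("n_folds: must be >= 1")

    def network_spec(self, architecture: str) -> NetworkSpec:
        sim, pre = self.simulation, self.preprocessing
        return NetworkSpec(
            architecture=architecture,
            n_fs=pre.n_bins,
            n_ch=sim.n_channels,
            n_classes=len(sim.class_frequencies),
        )

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "preprocessing": self.preprocessing.to_dict(),
            "training": None
            if self.training is None
            else {
                k: getattr(self.training, k)
                for k in self.training.__dataclass_fields__
            },
            "classifiers": list(self.classifiers),
            "n_folds": self.n_folds,
            "train_shifts_ms": list(self.train_shifts_ms),
            "test_shift_ms": self.test_shift_ms,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown or invalid fields raise :class:`ConfigError` naming the field
    path, so typos fail loudly instead of silently using defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    sections = {
        "simulation": SimulationConfig,
        "preprocessing": PreprocessingConfig,
        "training": TrainingConfig,
    }
    kwargs = {}
    for name, cls in sections.items():
        if name in raw:
            section = raw.pop(name)
            if not isinstance(section, dict):
                raise ConfigError(f"{name}: expected a mapping")
            kwargs[name] = _build_section(cls, section, name)
    allowed = set(RunConfig.__dataclass_fields__) - set(sections)
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"top level: unknown field(s) {sorted(unknown)}")
    kwargs.update({k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
    return RunConfig(**kwargs)


def config_hash(cfg: RunConfig) -> str:
    """Stable content hash of the resolved configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
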