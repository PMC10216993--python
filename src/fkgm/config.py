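"""YAML run configuration and seed management.

One ``run.yaml`` drives every pipeline stage.  Absent keys fall back to the
published hyper-parameter defaults (embedding 64, 3 layers, lr 1e-4, batch
2048, 300 epochs, dropout 0.1, health weight 0.1); unknown keys are
rejected loudly.  A single global seed fans out deterministically into
independent per-module streams via :func:`derive_seed`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .synthetic import SynthConfig
from .training import TrainingConfig

__all__ = ["ConfigError", "RunConfig", "parse_config", "derive_seed", "config_hash"]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values in a run config."""


@dataclass
class Paths:
    kg: str = "kg.tsv"
    train: str = "train.tsv"
    test: str = "test.tsv"
    nutrients: str = "nutrients.csv"
    roles: str | None = None
    out: str = "out"


@dataclass
class RunConfig:
    """Top-level run configuration: paths + training + synth + evaluation."""

    paths: Paths = field(default_factory=Paths)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    eval_k: list[int] = field(default_factory=lambda: [20])
    group_size: int = 500
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in '{name}' section: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from None


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; empty file = all defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys: {sorted(unknown)}")
    sections = {
        "paths": _build(Paths, raw.get("paths", {}), "paths"),
        "training": _build(TrainingConfig, raw.get("training", {}), "training"),
        "synth": _build(SynthConfig, raw.get("synth", {}), "synth"),
    }
    cfg = RunConfig(
        **sections,
        eval_k=list(raw.get("eval_k", [20])),
        group_size=int(raw.get("group_size", 500)),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    if any(k < 1 for k in cfg.eval_k):
        raise ConfigError("eval_k entries must be >= 1")
    if cfg.group_size < 1:
        raise ConfigError("group_size must be >= 1")
    return cfg


def derive_seed(master: int, name: str) -> int:
    """Deterministic per-purpose seed below 2^31 derived from the global seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a configuration (for run manifests)."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
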