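"""Run configuration: YAML file + CLI overrides, precedence CLI > file > defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .similarity import MODELS
from .synthetic import SimSpec

__all__ = ["RunConfig", "load_run_config", "simspec_from_dict"]


@dataclass
class RunConfig:
    """Everything one IS-RSA run needs; see ``examples/`` for a YAML template."""

    timecourses: str
    behavior: str
    output_dir: str
    network_map: str | None = None
    columns: dict = field(default_factory=dict)  # canonical -> file column name
    score_column: str | None = None
    models: tuple[str, ...] = ("annak", "nn")
    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    qc_mean_fd: float | None = 0.15
    qc_max_displacement: float | None = None
    split_half: bool = False
    familywise_reps: int = 10_000
    include: tuple[str, ...] | None = None
    exclude: tuple[str, ...] | None = None
    transpose: bool = False

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}; expected subset of {MODELS}")
        for label, p in (("timecourses", self.timecourses), ("behavior", self.behavior)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        if self.network_map is not None and not Path(self.network_map).exists():
            raise FileNotFoundError(f"network_map path does not exist: {self.network_map}")


def load_run_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    qc = data.pop("qc", None)
    if qc:
        data.setdefault("qc_mean_fd", qc.get("mean_fd", 0.15))
        data.setdefault("qc_max_displacement", qc.get("max_displacement"))
    data.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("models", "include", "exclude"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    unknown = set(data) - {f.name for f in RunConfig.__dataclass_fields__.values()}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def simspec_from_dict(data: Mapping[str, Any], seed: int | None = None) -> SimSpec:
    """Build a SimSpec from a YAML-style mapping.

    Node structure may be given either as explicit ``node_models`` /
    ``coupling`` lists or as a compact ``nodes`` list of blocks, e.g.::

        nodes:
          - {model: annak, coupling: 0.8, count: 5}
          - {model: "null", count: 15}
    """
    data = dict(data)
    if "nodes" in data:
        models: list[str] = []
        coupling: list[float] = []
        for block in data.pop("nodes"):
            count = int(block.get("count", 1))
            models += [str(block["model"])] * count
            coupling += [float(block.get("coupling", 0.0))] * count
        data["node_models"] = tuple(models)
        data["coupling"] = tuple(coupling)
        data.setdefault("n_nodes", len(models))
    if "score_distribution" in data and isinstance(data["score_distribution"], Mapping):
        sd = dict(data["score_distribution"])
        data["score_distribution"] = (sd.pop("name"), sd)
    for key in ("node_models", "coupling", "age_range"):
        if key in data:
            data[key] = tuple(data[key])
    if seed is not None:
        data["seed"] = seed
    return SimSpec(**data)
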