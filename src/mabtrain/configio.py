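"""Loading of train configs, deviation schedules and packaged fixtures."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .simulator import DeviationSpec, ProcessConfig
from .topology import TrainTopology, build_topology

__all__ = [
    "load_train_config",
    "load_schedule",
    "load_process_config",
    "packaged_config",
    "packaged_schedule",
]


def packaged_config() -> Path:
    """Path of the packaged default train config (7 units, 6 tanks, 60 h)."""
    return Path(resources.files("mabtrain") / "config" / "default_train.yaml")


def packaged_schedule() -> Path:
    """Path of the packaged five-scenario deviation schedule."""
    return Path(resources.files("mabtrain") / "config" / "deviations_60h.yaml")


def load_train_config(path) -> TrainTopology:
    """Build a validated topology from a YAML train config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return build_topology(doc)


def load_process_config(path) -> ProcessConfig:
    """Read the optional ``process:`` block of a train config, if present."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    block = doc.get("process", {}) if isinstance(doc, dict) else {}
    known = {f for f in ProcessConfig.__dataclass_fields__}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown process parameters: {sorted(unknown)}")
    return ProcessConfig(**block)


def load_schedule(path) -> list[DeviationSpec]:
    """Read a deviation schedule: a YAML list under ``deviations:``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = []
    for d in doc.get("deviations", []):
        out.append(
            DeviationSpec(
                scenario=int(d["scenario"]),
                type=d["type"],
                unit=d["unit"],
                onset_cycle=int(d["onset_cycle"]),
                end_cycle=int(d["end_cycle"]),
                params={k: float(v) for k, v in (d.get("params") or {}).items()},
            )
        )
    return out
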