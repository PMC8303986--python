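"""YAML run configuration: machine, kernel and metric thresholds.

Keys mirror the dataclass fields, SI units as documented there
(seconds, Gy, Gy/s, mm; currents in ampere).  Missing blocks or keys
fall back to the package defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .dose_engine import SpotKernel
from .machine import MachineModel
from .metrics import MetricConfig

_BLOCKS = {"machine": MachineModel, "kernel": SpotKernel, "metrics": MetricConfig}


def load_config(path: str | Path) -> tuple[MachineModel, SpotKernel, MetricConfig]:
    """Read ``(machine, kernel, metrics)`` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = []
    for block, cls in _BLOCKS.items():
        kwargs = raw.get(block, {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown {block} config keys: {sorted(unknown)}")
        out.append(cls(**kwargs))
    return tuple(out)


def save_config(
    path: str | Path,
    machine: MachineModel = MachineModel(),
    kernel: SpotKernel = SpotKernel(),
    metrics: MetricConfig = MetricConfig(),
) -> None:
    """Write the three blocks to YAML."""
    doc = {
        "machine": dataclasses.asdict(machine),
        "kernel": dataclasses.asdict(kernel),
        "metrics": dataclasses.asdict(metrics),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
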