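"""Spot maps and the raster-scanning delivery timeline.

A transmission field is a list of lateral spot positions with MU weights,
delivered sequentially: the beam dwells on each spot for ``mu / MU_rate``
seconds, then the scanning magnets move it to the next spot at the scan
speed.  The timeline is the sequence of per-spot ``[t_start, t_end]``
intervals; no dose is deposited during inter-spot transit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .machine import MachineModel


@dataclass
class SpotMap:
    """Ordered spots of one field: lateral positions (mm) and MU weights.

    ``positions`` is an ``(n, 2)`` array of (x, y) in the field-local
    beam's-eye view; row order is delivery order.  ``gantry_angle`` is
    metadata for multi-field fixtures (degrees).
    """

    field_id: str
    positions: np.ndarray
    mu: np.ndarray
    gantry_angle: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of lateral mm")
        if len(self.positions) == 0:
            raise ValueError("a spot map needs at least one spot")
        if len(self.mu) != len(self.positions):
            raise ValueError("mu and positions length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("spot positions must be finite")
        if not np.all(np.isfinite(self.mu)) or np.any(self.mu <= 0):
            raise ValueError("spot MU weights must be finite and positive")

    @property
    def n_spots(self) -> int:
        return len(self.mu)

    def reordered(self, order: Sequence[int]) -> "SpotMap":
        order = np.asarray(order, dtype=int)
        return SpotMap(self.field_id, self.positions[order], self.mu[order], self.gantry_angle)

    def reversed(self) -> "SpotMap":
        return self.reordered(np.arange(self.n_spots)[::-1])

    def scaled(self, factor: float) -> "SpotMap":
        """Same spots with every MU weight multiplied by ``factor``."""
        return SpotMap(self.field_id, self.positions, self.mu * factor, self.gantry_angle)


@dataclass
class DeliveryTimeline:
    """Per-spot delivery intervals of one field, seconds from beam-on."""

    t_start: np.ndarray
    t_end: np.ndarray

    def __post_init__(self) -> None:
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        if self.t_start.shape != self.t_end.shape or self.t_start.ndim != 1:
            raise ValueError("t_start and t_end must be 1-d arrays of equal length")
        if np.any(self.t_end < self.t_start):
            raise ValueError("spot intervals must have t_end >= t_start")
        if np.any(self.t_start[1:] < self.t_end[:-1]):
            raise ValueError("spot intervals must be ordered and non-overlapping")

    @property
    def dwell(self) -> np.ndarray:
        return self.t_end - self.t_start

    @property
    def total_time(self) -> float:
        """Beam-on plus transit time of the field in seconds."""
        return float(self.t_end[-1] - self.t_start[0])

    @property
    def n_spots(self) -> int:
        return len(self.t_start)


def serpentine_order(positions: np.ndarray) -> np.ndarray:
    """Delivery order that scans rows of constant y, alternating x direction.

    Rows (groups of equal y) are visited bottom-to-top; even rows are
    traversed left-to-right, odd rows right-to-left.  Sorting is stable:
    ties are broken by x and then by input index, so the order is
    deterministic for any input, on or off a lattice.

    Returns the permutation of input indices.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    order = np.lexsort((np.arange(n), positions[:, 0], positions[:, 1]))
    ys = positions[order, 1]
    row_id = np.concatenate(([0], np.cumsum(ys[1:] != ys[:-1])))
    out = np.empty(n, dtype=int)
    pos = 0
    for r in range(row_id[-1] + 1):
        seg = order[row_id == r]
        if r % 2 == 1:
            seg = seg[::-1]
        out[pos : pos + len(seg)] = seg
        pos += len(seg)
    return out


def build_timeline(spot_map: SpotMap, model: MachineModel) -> DeliveryTimeline:
    """Delivery timeline of ``spot_map`` in its stored order.

    The first spot starts at t=0; between consecutive spots the beam is
    off for the Euclidean lateral distance divided by the scan speed.
    Raises :class:`~pbsflash.machine.UndeliverableSpotError` if any spot
    is below the machine minimum MU.
    """
    dwell = np.array([model.dwell_time(mu) for mu in spot_map.mu])
    hops = np.linalg.norm(np.diff(spot_map.positions, axis=0), axis=1)
    transit = hops / model.scan_speed_mm_per_s
    t_start = np.empty(spot_map.n_spots)
    t_start[0] = 0.0
    t_start[1:] = np.cumsum(dwell[:-1] + transit)
    return DeliveryTimeline(t_start=t_start, t_end=t_start + dwell)


# ----------------------------------------------------------------------
# spot-map file format: CSV with columns field_id, x_mm, y_mm, mu
# (optional gantry_angle_deg); row order is delivery order
# ----------------------------------------------------------------------

def write_spot_maps(maps: Iterable[SpotMap], path: str | Path) -> None:
    frames = []
    for m in maps:
        frames.append(
            pd.DataFrame(
                {
                    "field_id": m.field_id,
                    "x_mm": m.positions[:, 0],
                    "y_mm": m.positions[:, 1],
                    "mu": m.mu,
                    "gantry_angle_deg": m.gantry_angle,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spot_maps(path: str | Path) -> list[SpotMap]:
    df = pd.read_csv(path)
    required = {"field_id", "x_mm", "y_mm", "mu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spot-map file missing columns: {sorted(missing)}")
    maps = []
    for fid, g in df.groupby("field_id", sort=False):
        angle = float(g["gantry_angle_deg"].iloc[0]) if "gantry_angle_deg" in g else 0.0
        maps.append(
            SpotMap(
                field_id=str(fid),
                positions=g[["x_mm", "y_mm"]].to_numpy(),
                mu=g["mu"].to_numpy(),
                gantry_angle=angle,
            )
        )
    return maps
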