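"""Cumulative dose- and dose-rate-volume histograms (DVH / DRVH).

A DRVH is the dose-rate analogue of the familiar DVH: the curve gives,
for each rate R, the fraction of the evaluated volume receiving at least
R Gy/s.  Summary statistics (V_40Gy/s, D2%, Dmax, mean) are computed from
the raw voxel samples rather than from the binned curve, so bin width
never biases them.

Plan-level pooling follows the per-field convention: each field's dose
rate is computed independently and the plan DRVH is sampled from all
fields, so a voxel irradiated by k fields contributes k samples.  This
differs from (and is documented against) per-voxel combination rules such
as taking the min or max across fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dose_engine import DoseGrid


@dataclass
class VolumeHistogram:
    """Cumulative volume histogram over the defined voxels of a grid.

    ``cumulative[k]`` is the fraction (0..1) of the volume with value
    >= ``bin_edges[k]``; the curve starts at 1.0 at the 0 edge and is 0
    beyond the maximum.  ``values`` keeps the raw (sorted) voxel samples
    for bin-free statistics.
    """

    kind: str
    bin_edges: np.ndarray
    cumulative: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if self.kind not in ("dose", "dose-rate"):
            raise ValueError("kind must be 'dose' or 'dose-rate'")
        if len(self.values) == 0:
            raise ValueError("a volume histogram needs at least one voxel sample")

    @property
    def n_voxels(self) -> int:
        return len(self.values)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0]) if len(self.bin_edges) > 1 else 0.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"bin_edge": self.bin_edges, "cumulative_fraction": self.cumulative}
        ).to_csv(path, index=False)

    def summary(self, flash_rate: float = 40.0) -> dict[str, float]:
        """Headline statistics: mean, max, and V_40Gy/s or D2% by kind."""
        out = {
            "mean": float(self.values.mean()),
            "max": float(self.values.max()),
            "n_voxels": self.n_voxels,
        }
        if self.kind == "dose-rate":
            out[f"V_{flash_rate:g}Gy/s_percent"] = v_at_rate(self, flash_rate)
        else:
            out["D2%_Gy"] = d_at_volume(self, 2.0)
        return out


def build_histogram(
    grid: DoseGrid,
    mask: np.ndarray | None = None,
    bin_width: float | None = None,
    label: str = "",
) -> VolumeHistogram:
    """Cumulative histogram of a grid over ``mask`` (default: all voxels).

    Undefined voxels (NaN) inside the mask are excluded — volume fractions
    are over the metric's defined voxels only.  Default bin width: 0.1 Gy
    for dose, 1 Gy/s for dose rate.
    """
    if mask is None:
        mask = np.ones(grid.geometry.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.values.shape:
        raise ValueError("mask shape must match the grid")
    values = grid.values[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("mask selects no defined voxel")
    if np.any(values < 0):
        raise ValueError("histogram values must be non-negative")
    if bin_width is None:
        bin_width = 0.1 if grid.kind == "dose" else 1.0
    return _from_values(grid.kind, values, bin_width, label or grid.name)


def _from_values(
    kind: str, values: np.ndarray, bin_width: float, label: str
) -> VolumeHistogram:
    vmax = float(values.max())
    n_bins = int(np.ceil(vmax / bin_width)) + 2  # one edge strictly beyond max
    edges = bin_width * np.arange(n_bins)
    values = np.sort(values)
    # fraction of samples >= edge, via the sorted sample array
    below = np.searchsorted(values, edges, side="left")
    cumulative = 1.0 - below / len(values)
    return VolumeHistogram(kind, edges, cumulative, values, label)


def v_at_rate(h: VolumeHistogram, rate: float) -> float:
    """Percent of the evaluated volume with dose rate >= ``rate`` Gy/s."""
    if h.kind != "dose-rate":
        raise ValueError("v_at_rate needs a dose-rate histogram")
    return float(np.mean(h.values >= rate) * 100.0)


def d_at_volume(h: VolumeHistogram, volume_percent: float) -> float:
    """DVH dose statistic D_{p%}: the dose received by the hottest p% of
    the volume (linear interpolation between samples)."""
    if h.kind != "dose":
        raise ValueError("d_at_volume needs a dose histogram")
    if not 0.0 < volume_percent <= 100.0:
        raise ValueError("volume_percent must be in (0, 100]")
    return float(np.quantile(h.values, 1.0 - volume_percent / 100.0))


def pool_fields(histos: Sequence[VolumeHistogram], label: str = "plan") -> VolumeHistogram:
    """Plan-level histogram: sample union over per-field histograms.

    Each voxel sample of each field keeps its multiplicity, so a voxel
    irradiated by k fields contributes k samples.  Inputs must share kind
    and bin width.
    """
    histos = list(histos)
    if not histos:
        raise ValueError("nothing to pool")
    kind = histos[0].kind
    bw = histos[0].bin_width
    for h in histos[1:]:
        if h.kind != kind:
            raise ValueError("cannot pool histograms of different kinds")
        if h.bin_width != bw:
            raise ValueError("cannot pool histograms with different binning")
    values = np.concatenate([h.values for h in histos])
    return _from_values(kind, values, bw if bw > 0 else 1.0, label)
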