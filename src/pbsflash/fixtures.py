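"""Built-in study fixtures: no external data needed.

Everything the engine is exercised on is generated here:

* the water-phantom benchmark — a 5 x 5 cm^2 uniform field of minimum-MU
  spots at 5 mm spacing (121 spots), conventionally evaluated with the
  spot peak dose rate pinned to 1300 Gy/s;
* single-spot fields for closed-form checks;
* a synthetic multi-field "lung-like" cylinder phantom: n equally spaced
  gantry angles (five at 72 degrees by default) each covering the
  beam's-eye-view footprint of a cylinder target with minimum-MU spots.
  It stands in for patient anatomy at a realistic target scale and makes
  no claim of reproducing any patient result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .delivery import SpotMap, serpentine_order
from .dose_engine import GridGeometry, SpotKernel
from .machine import MachineModel


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the generated fixtures.

    ``field_size`` is the lateral extent covered by spots (mm x mm);
    ``spdr_override`` pins the spot peak dose rate instead of deriving it
    from the machine calibration (1300 Gy/s for the water-phantom
    benchmark).  ``cylinder_radius``/``cylinder_length`` (mm) size the
    multi-field target; ``mu_jitter`` > 0 randomizes spot weights upward
    of the minimum MU (deterministic in ``seed``).
    """

    field_size: tuple[float, float] = (50.0, 50.0)
    spot_spacing: float = 5.0
    spdr_override: float | None = 1300.0
    n_fields: int = 5
    cylinder_radius: float = 40.0
    cylinder_length: float = 60.0
    mu_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_spacing <= 0:
            raise ValueError("spot_spacing must be strictly positive")
        if min(self.field_size) < 0:
            raise ValueError("field_size must be non-negative")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        if self.mu_jitter < 0:
            raise ValueError("mu_jitter must be >= 0")


def _lattice(size_x: float, size_y: float, spacing: float) -> np.ndarray:
    """Centered regular lattice covering ``size_x`` x ``size_y`` mm."""
    nx = int(np.floor(size_x / spacing + 1e-9)) + 1
    ny = int(np.floor(size_y / spacing + 1e-9)) + 1
    xs = spacing * (np.arange(nx) - (nx - 1) / 2.0)
    ys = spacing * (np.arange(ny) - (ny - 1) / 2.0)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def make_uniform_field(
    spec: BenchmarkSpec = BenchmarkSpec(),
    model: MachineModel = MachineModel(),
    field_id: str = "benchmark",
) -> SpotMap:
    """Uniform minimum-MU field on a regular lattice, serpentine ordered.

    The default spec yields the 11 x 11 = 121-spot benchmark field.
    """
    positions = _lattice(*spec.field_size, spec.spot_spacing)
    order = serpentine_order(positions)
    positions = positions[order]
    mu = np.full(len(positions), model.min_mu_per_spot)
    return SpotMap(field_id, positions, mu)


def make_single_spot(mu: float, model: MachineModel = MachineModel()) -> SpotMap:
    """Single spot at the origin; ``mu`` must be deliverable."""
    model.dwell_time(mu)  # raises UndeliverableSpotError below the minimum
    return SpotMap("single-spot", np.array([[0.0, 0.0]]), np.array([mu]))


def make_multifield_cylinder(
    spec: BenchmarkSpec = BenchmarkSpec(),
    model: MachineModel = MachineModel(),
) -> list[SpotMap]:
    """Spot maps of ``n_fields`` equally spaced gantry angles around a
    cylinder target (axis along the gantry rotation axis).

    Every field sees the same rectangular beam's-eye-view footprint
    (2 x radius across, length along the axis) and covers it with
    minimum-MU spots on the lattice; with ``mu_jitter`` > 0 weights are
    drawn uniformly from [min_mu, (1 + jitter) * min_mu], reproducibly
    from ``seed``.
    """
    angles = 360.0 * np.arange(spec.n_fields) / spec.n_fields
    positions = _lattice(2.0 * spec.cylinder_radius, spec.cylinder_length, spec.spot_spacing)
    order = serpentine_order(positions)
    positions = positions[order]
    maps = []
    for k, angle in enumerate(angles):
        mu = np.full(len(positions), model.min_mu_per_spot)
        if spec.mu_jitter > 0:
            rng = np.random.default_rng(spec.seed * 1000 + k)
            mu = mu * (1.0 + spec.mu_jitter * rng.random(len(positions)))
        maps.append(SpotMap(f"field{k:02d}", positions.copy(), mu, gantry_angle=float(angle)))
    return maps


def benchmark_geometry(
    spot_map: SpotMap,
    lateral_margin: float = 15.0,
    depth_range: tuple[float, float] = (0.0, 60.0),
    spacing: float = 2.0,
) -> GridGeometry:
    """Beam-aligned voxel grid enclosing a field with lateral margin (mm)."""
    lo = spot_map.positions.min(axis=0) - lateral_margin
    hi = spot_map.positions.max(axis=0) + lateral_margin
    nx = int(np.floor((hi[0] - lo[0]) / spacing)) + 1
    ny = int(np.floor((hi[1] - lo[1]) / spacing)) + 1
    nz = int(np.floor((depth_range[1] - depth_range[0]) / spacing)) + 1
    return GridGeometry(
        origin=(lo[0], lo[1], depth_range[0]),
        spacing=(spacing, spacing, spacing),
        shape=(nx, ny, nz),
    )


def footprint_mask(
    geometry: GridGeometry,
    spot_map: SpotMap,
    depth: float | None = None,
    slab_halfwidth: float | None = None,
    kernel: SpotKernel = SpotKernel(),
) -> np.ndarray:
    """Field-footprint evaluation mask on a grid.

    True for voxels whose lateral center lies inside the convex hull of
    the spot centers and whose depth is within ``slab_halfwidth`` (default
    half a voxel) of ``depth`` (default: the kernel's reference depth,
    where the spot peak dose rate is defined).  The Gaussian tails extend
    indefinitely, so coverage fractions such as V_40Gy/s are only
    well-posed over a bounded region; the hull of the spot map is the
    field-region convention used here.
    """
    if depth is None:
        depth = kernel.peak_depth_reference
    if slab_halfwidth is None:
        slab_halfwidth = geometry.spacing[2] / 2.0
    xc = geometry.axis_centers(0)
    yc = geometry.axis_centers(1)
    zc = geometry.axis_centers(2)
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    try:
        hull = Delaunay(spot_map.positions)
        inside = hull.find_simplex(pts) >= 0
    except QhullError:  # degenerate hull (single spot / collinear row):
        # bounding box buffered by half a voxel so the region is non-empty
        buffer = max(geometry.spacing[0], geometry.spacing[1]) / 2.0
        lo = spot_map.positions.min(axis=0) - buffer
        hi = spot_map.positions.max(axis=0) + buffer
        inside = np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)
    lateral = inside.reshape(len(xc), len(yc))
    in_slab = np.abs(zc - depth) <= slab_halfwidth + 1e-9
    return lateral[:, :, None] & in_slab[None, None, :]
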