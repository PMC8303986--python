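"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from pbsflash import (
    MachineModel,
    SpotKernel,
    SpotMap,
    benchmark_geometry,
    build_influence,
    build_timeline,
    footprint_mask,
    make_uniform_field,
)


@pytest.fixture(scope="session")
def model():
    return MachineModel()


@pytest.fixture(scope="session")
def kernel():
    return SpotKernel()


@pytest.fixture(scope="session")
def benchmark_field(model):
    """The 121-spot, 5x5 cm^2, 5 mm, minimum-MU serpentine field."""
    return make_uniform_field(model=model)


@pytest.fixture(scope="session")
def benchmark_setup(benchmark_field, model, kernel):
    """Field + timeline + influence matrix at SPDR 1300 Gy/s on a 2 mm grid."""
    geom = benchmark_geometry(benchmark_field)
    timeline = build_timeline(benchmark_field, model)
    matrix = build_influence(benchmark_field, model, kernel, geom, spdr=1300.0)
    mask = footprint_mask(geom, benchmark_field, kernel=kernel)
    return benchmark_field, timeline, matrix, mask


def random_spot_map(rng: np.random.Generator, n_spots: int = 20, model=MachineModel()) -> SpotMap:
    """Random deliverable field: positions in a 40 mm box, MU in [min, 4*min]."""
    positions = rng.uniform(-20.0, 20.0, size=(n_spots, 2))
    mu = model.min_mu_per_spot * rng.uniform(1.0, 4.0, size=n_spots)
    return SpotMap("random", positions, mu)


def brute_force_cumulative(rates_dense, t_start, t_end, dt=1e-6):
    """Time-stepped cumulative dose, independent of the analytic path.

    ``rates_dense`` is (n_voxels, n_spots).  Each step of width ``dt`` is
    weighted by its overlap with each spot's dwell interval, so the
    cumulative dose at step edges is exact for the rectangular-pulse
    delivery model.  Returns (times at step edges, cumulative (n_steps+1,
    n_voxels)).
    """
    total = float(np.max(t_end))
    n_steps = int(np.ceil(total / dt - 1e-12))
    edges = dt * np.arange(n_steps + 1)
    lo = np.maximum(edges[:-1, None], t_start[None, :])
    hi = np.minimum(edges[1:, None], t_end[None, :])
    overlap = np.clip(hi - lo, 0.0, None)  # (n_steps, n_spots) seconds
    per_step = overlap @ rates_dense.T  # Gy per step, (n_steps, n_voxels)
    cum = np.vstack([np.zeros(rates_dense.shape[0]), np.cumsum(per_step, axis=0)])
    return edges, cum


def brute_force_adr(rates_dense, t_start, t_end, dstar, dt=1e-6):
    """ADR by brute-force time accumulation at ``dt`` resolution.

    Finds t0 and t1 by linear interpolation between step edges of the
    brute-force cumulative dose.  NaN where D <= 2 d*.
    """
    edges, cum = brute_force_cumulative(rates_dense, t_start, t_end, dt)
    D = cum[-1]
    out = np.full(rates_dense.shape[0], np.nan)
    for v in range(rates_dense.shape[0]):
        if D[v] <= 2.0 * dstar:
            continue
        t0 = _cross_time(edges, cum[:, v], dstar, first=True)
        t1 = _cross_time(edges, cum[:, v], D[v] - dstar, first=False)
        out[v] = (D[v] - 2.0 * dstar) / (t1 - t0)
    return out


def _cross_time(edges, cum, target, first):
    """Time at which ``cum`` crosses ``target``; for flat stretches at the
    target value take the latest (first=True) or earliest (first=False)
    edge, matching a threshold that trims beam-off time."""
    if first:
        k = int(np.searchsorted(cum, target, side="right"))
        k = min(k, len(cum) - 1)
        lo, hi = cum[k - 1], cum[k]
        if hi <= target:  # flat at target: push to the last edge at target
            return edges[k]
    else:
        k = int(np.searchsorted(cum, target, side="left"))
        k = max(k, 1)
        lo, hi = cum[k - 1], cum[k]
    if hi == lo:
        return edges[k]
    return edges[k - 1] + (target - lo) / (hi - lo) * (edges[k] - edges[k - 1])
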