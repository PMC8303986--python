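"""DADR, ADR and DTDR: worked examples, bounds and timing invariances."""

import numpy as np
import pytest
from scipy import sparse

from pbsflash import (
    DeliveryTimeline,
    GridGeometry,
    InfluenceMatrix,
    MetricConfig,
    SpotKernel,
    adr,
    build_influence,
    build_timeline,
    compute_field_metrics,
    dadr,
    dtdr,
)

from conftest import brute_force_adr, random_spot_map

ONE_VOXEL = GridGeometry(shape=(1, 1, 1))


def one_voxel_matrix(rates, dwell):
    """Hand-built single-voxel influence matrix."""
    rates = sparse.csr_matrix(np.atleast_2d(np.asarray(rates, dtype=float)))
    return InfluenceMatrix(rates, np.asarray(dwell, dtype=float), ONE_VOXEL, spdr=np.max(rates.data))


class TestDadr:
    def test_single_contribution_passes_through(self):
        m = one_voxel_matrix([1300.0], [2e-3])
        assert dadr(m).values[0, 0, 0] == pytest.approx(1300.0)

    def test_dose_weighted_mean(self):
        # doses 2 Gy @ 100 Gy/s and 1 Gy @ 50 Gy/s -> (200 + 50)/3
        m = one_voxel_matrix([100.0, 50.0], [0.02, 0.02])
        assert dadr(m).values[0, 0, 0] == pytest.approx(250.0 / 3.0)

    def test_equal_rates_are_returned_unchanged(self):
        m = one_voxel_matrix([80.0, 80.0, 80.0], [0.001, 0.05, 0.3])
        assert dadr(m).values[0, 0, 0] == pytest.approx(80.0)

    def test_zero_dose_voxel_is_undefined(self):
        m = InfluenceMatrix(sparse.csr_matrix((1, 1)), np.array([2e-3]), ONE_VOXEL, spdr=1.0)
        assert np.isnan(dadr(m).values[0, 0, 0])
        zero = dadr(m, MetricConfig(undefined_policy="zero"))
        assert zero.values[0, 0, 0] == 0.0


class TestAdr:
    def test_single_linear_ramp_equals_its_slope(self):
        m = one_voxel_matrix([1300.0], [2e-3])
        tl = DeliveryTimeline([0.0], [2e-3])
        assert adr(m, tl).values[0, 0, 0] == pytest.approx(1300.0)

    def test_two_pulses_with_beam_off_gap(self):
        """2 Gy at 1000 Gy/s, 1 ms off, 2 Gy at 1000 Gy/s; d* = 0.1 Gy
        -> t0 = 0.1 ms, t1 = 4.9 ms, ADR = 3.8 Gy / 4.8 ms."""
        m = one_voxel_matrix([1000.0, 1000.0], [2e-3, 2e-3])
        tl = DeliveryTimeline([0.0, 3e-3], [2e-3, 5e-3])
        assert adr(m, tl).values[0, 0, 0] == pytest.approx(3.8 / 4.8e-3)

    def test_exact_boundary_crossings_trim_flat_gaps_on_both_sides(self):
        # three 0.2 Gy pulses; d* = 0.2 crosses exactly at pulse edges, so
        # the window must collapse onto the middle ramp (ADR = its slope)
        m = one_voxel_matrix([100.0, 100.0, 100.0], [2e-3, 2e-3, 2e-3])
        tl = DeliveryTimeline([0.0, 10e-3, 20e-3], [2e-3, 12e-3, 22e-3])
        got = adr(m, tl, MetricConfig(adr_dose_threshold=0.2)).values[0, 0, 0]
        assert got == pytest.approx(100.0)

    def test_gap_trimming_with_margin(self):
        # D = 0.4 Gy, d* = 0.1: t0 = 1 ms into ramp 1, t1 = 1 ms into ramp 2
        m = one_voxel_matrix([100.0, 100.0], [2e-3, 2e-3])
        tl = DeliveryTimeline([0.0, 10e-3], [2e-3, 12e-3])
        got = adr(m, tl).values[0, 0, 0]
        assert got == pytest.approx(0.2 / 10e-3)

    def test_voxel_below_two_thresholds_is_undefined(self):
        m = one_voxel_matrix([75.0], [2e-3])  # D = 0.15 Gy
        tl = DeliveryTimeline([0.0], [2e-3])
        assert np.isnan(adr(m, tl).values[0, 0, 0])

    def test_zero_threshold_uses_the_full_active_window(self):
        m = one_voxel_matrix([100.0, 100.0], [2e-3, 2e-3])
        tl = DeliveryTimeline([0.0, 10e-3], [2e-3, 12e-3])
        got = adr(m, tl, MetricConfig(adr_dose_threshold=0.0)).values[0, 0, 0]
        assert got == pytest.approx(0.4 / 12e-3)

    def test_mismatched_timeline_rejected(self):
        m = one_voxel_matrix([100.0], [2e-3])
        with pytest.raises(ValueError):
            adr(m, DeliveryTimeline([0.0, 3e-3], [2e-3, 5e-3]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_time_integration(self, seed, model, kernel):
        rng = np.random.default_rng(seed)
        smap = random_spot_map(rng, n_spots=12, model=model)
        geom = GridGeometry(origin=(-15, -15, 36), spacing=(10, 10, 4), shape=(4, 4, 3))
        tl = build_timeline(smap, model)
        mat = build_influence(smap, model, kernel, geom)
        got = adr(mat, tl).values.ravel()
        oracle = brute_force_adr(mat.rates.toarray(), tl.t_start, tl.t_end, 0.1)
        defined = np.isfinite(oracle)
        assert np.isfinite(got[defined]).all()
        assert got[defined] == pytest.approx(oracle[defined], rel=1e-3)


class TestDtdr:
    def test_low_dose_tail_spot_is_disqualified(self):
        # (D=0.5, 100 Gy/s) and (D=0.05, 500 Gy/s), d*=0.1 -> 100 Gy/s
        m = one_voxel_matrix([100.0, 500.0], [0.005, 1e-4])
        assert dtdr(m).values[0, 0, 0] == pytest.approx(100.0)

    def test_single_qualifying_spot_passes_through(self):
        m = one_voxel_matrix([200.0], [2e-3])
        assert dtdr(m).values[0, 0, 0] == pytest.approx(200.0)

    def test_no_qualifying_spot_is_undefined(self):
        m = one_voxel_matrix([10.0], [2e-3])  # D = 0.02 < d*
        assert np.isnan(dtdr(m).values[0, 0, 0])

    def test_uniform_min_mu_field_exceeds_dstar_over_dwell(self, benchmark_setup):
        """Every qualifying spot has rate = D/tau with D > d*, so DTDR
        > d*/tau = 50 Gy/s on every defined voxel of the benchmark."""
        _, _, matrix, _ = benchmark_setup
        grid = dtdr(matrix)
        vals = grid.values[np.isfinite(grid.values)]
        assert vals.size > 0
        assert np.all(vals > 0.1 / 2e-3)


@pytest.fixture(scope="module")
def random_field(model, kernel):
    rng = np.random.default_rng(42)
    smap = random_spot_map(rng, n_spots=15, model=model)
    geom = GridGeometry(origin=(-20, -20, 32), spacing=(5, 5, 4), shape=(9, 9, 5))
    return smap, geom


class TestFieldLevelInvariances:

    def test_dadr_within_per_voxel_rate_bounds(self, random_field, model, kernel):
        smap, geom = random_field
        mat = build_influence(smap, model, kernel, geom)
        grid = dadr(mat).values.ravel()
        r = mat.rates
        for v in range(r.shape[0]):
            row = r.data[r.indptr[v] : r.indptr[v + 1]]
            if len(row):
                assert row.min() - 1e-9 <= grid[v] <= row.max() + 1e-9

    def test_adr_bounded_by_max_instantaneous_rate(self, random_field, model, kernel):
        smap, geom = random_field
        tl = build_timeline(smap, model)
        mat = build_influence(smap, model, kernel, geom)
        grid = adr(mat, tl).values.ravel()
        r = mat.rates
        for v in np.nonzero(np.isfinite(grid))[0]:
            row = r.data[r.indptr[v] : r.indptr[v + 1]]
            assert grid[v] <= row.max() * (1 + 1e-7)

    def test_reversing_delivery_order_leaves_all_metrics_unchanged(
        self, random_field, model, kernel
    ):
        smap, geom = random_field
        rev = smap.reversed()
        grids = compute_field_metrics(smap, model, kernel, geom)
        grids_rev = compute_field_metrics(rev, model, kernel, geom)
        for name in ("DADR", "ADR", "DTDR"):
            a, b = grids[name].values, grids_rev[name].values
            assert np.isnan(a).sum() == np.isnan(b).sum()
            m = np.isfinite(a)
            assert a[m] == pytest.approx(b[m], rel=1e-9)

    def test_timing_free_metrics_ignore_scan_speed(self, random_field, model, kernel):
        import dataclasses

        smap, geom = random_field
        slow = dataclasses.replace(model, scan_speed=1.0)
        fast = compute_field_metrics(smap, model, kernel, geom)
        crawl = compute_field_metrics(smap, slow, kernel, geom)
        for name in ("DADR", "DTDR"):
            m = np.isfinite(fast[name].values)
            assert fast[name].values[m] == pytest.approx(crawl[name].values[m])
        # ADR does depend on timing: the slow machine cannot be faster
        m = np.isfinite(fast["ADR"].values) & np.isfinite(crawl["ADR"].values)
        assert np.all(crawl["ADR"].values[m] <= fast["ADR"].values[m] * (1 + 1e-9))

    def test_mu_scaling_scales_all_metrics_linearly(self, random_field, model, kernel):
        """Scaling the layer minimum MU and all spot MUs by f multiplies
        every rate by f at unchanged timing; with the dose thresholds
        scaled alongside, all three fields scale by f."""
        smap, geom = random_field
        f = 3.0
        scaled_model = model.with_min_mu(model.min_mu_per_spot * f)
        cfg = MetricConfig()
        cfg_f = MetricConfig(adr_dose_threshold=0.1 * f, dtdr_dose_threshold=0.1 * f)
        base = compute_field_metrics(smap, model, kernel, geom, cfg)
        scaled = compute_field_metrics(smap.scaled(f), scaled_model, kernel, geom, cfg_f)
        for name in ("DADR", "ADR", "DTDR"):
            m = np.isfinite(base[name].values)
            assert scaled[name].values[m] == pytest.approx(f * base[name].values[m], rel=1e-9)

    def test_benchmark_ordering_dtdr_below_dadr(self, benchmark_setup):
        _, timeline, matrix, mask = benchmark_setup
        g_dadr = dadr(matrix).values[mask]
        g_dtdr = dtdr(matrix).values[mask]
        g_adr = adr(matrix, timeline).values[mask]
        assert np.nanmean(g_dtdr) <= np.nanmean(g_dadr)
        assert np.nanmean(g_adr) <= np.nanmean(g_dadr)
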