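"""Synthetic 5-field plan around a cylinder target: pooled plan DRVH.

Five fields at 72-degree gantry intervals each cover the beam's-eye-view
of a 40 mm-radius, 60 mm-long cylinder with minimum-MU spots.  Each
field's dose rate is computed on its own beam-aligned grid; the plan
DRVH pools the per-field samples (a voxel irradiated by several fields
contributes once per field).
"""

from pbsflash import (
    BenchmarkSpec,
    MachineModel,
    SpotKernel,
    benchmark_geometry,
    build_histogram,
    build_timeline,
    compute_field_metrics,
    footprint_mask,
    make_multifield_cylinder,
    pool_fields,
    v_at_rate,
)

model = MachineModel(min_mu_per_spot=400.0)  # high-dose-rate regime
kernel = SpotKernel()
spec = BenchmarkSpec(n_fields=5, cylinder_radius=40.0, cylinder_length=60.0)
fields = make_multifield_cylinder(spec, model)

histos = {name: [] for name in ("DADR", "ADR", "DTDR")}
for field in fields:
    geom = benchmark_geometry(field)
    grids = compute_field_metrics(field, model, kernel, geom)
    mask = footprint_mask(geom, field, kernel=kernel)
    tl = build_timeline(field, model)
    print(f"{field.field_id} (gantry {field.gantry_angle:5.1f} deg): "
          f"{field.n_spots} spots, beam-on {tl.total_time * 1e3:.0f} ms")
    for name in histos:
        histos[name].append(build_histogram(grids[name], mask))

print(f"\nplan DRVH over {5} fields (SPDR {model.spot_peak_dose_rate:.0f} Gy/s):")
for name, hs in histos.items():
    plan = pool_fields(hs)
    print(f"  {name:>4}: mean {plan.values.mean():7.1f} Gy/s, "
          f"V_40Gy/s {v_at_rate(plan, 40.0):5.1f}%  ({plan.n_voxels} samples)")

# With 400 MU/spot the peak rate is ~673 Gy/s and the timing-free metrics
# stay far above 40 Gy/s; ADR is lower because each ~1 s field spreads the
# dose over the scan.
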