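"""Water-phantom benchmark: 5x5 cm^2 uniform field, DRVHs and V_40Gy/s.

Builds the 121-spot minimum-MU field at 5 mm spacing with the spot peak
dose rate pinned to 1300 Gy/s, computes DADR, ADR and DTDR on a 2 mm
grid and summarizes their dose-rate-volume histograms over the field
footprint at the 40 mm reference depth.
"""

import numpy as np

from pbsflash import (
    MachineModel,
    SpotKernel,
    build_histogram,
    build_timeline,
    benchmark_geometry,
    compute_field_metrics,
    footprint_mask,
    make_uniform_field,
    v_at_rate,
)

model = MachineModel()
kernel = SpotKernel()
field = make_uniform_field(model=model)
geom = benchmark_geometry(field)

timeline = build_timeline(field, model)
print(f"{field.n_spots} spots, serpentine delivery in {timeline.total_time * 1e3:.0f} ms")

grids = compute_field_metrics(field, model, kernel, geom, spdr=1300.0)
mask = footprint_mask(geom, field, kernel=kernel)
print(f"footprint: {mask.sum()} voxels at the reference-depth slab")
print(f"field-center dose: "
      f"{grids['dose'].values[geom.shape[0] // 2, geom.shape[1] // 2, 20]:.1f} Gy")

print(f"{'metric':>6} {'mean':>8} {'min':>8} {'max':>8}  V_40Gy/s")
for name in ("DADR", "ADR", "DTDR"):
    h = build_histogram(grids[name], mask)
    print(f"{name:>6} {h.values.mean():8.1f} {h.values.min():8.1f} "
          f"{h.values.max():8.1f}  {v_at_rate(h, 40.0):6.1f}%")

# Every metric covers 100% of the footprint above the 40 Gy/s FLASH
# threshold.  DADR (timing-free, no threshold) is highest and most
# uniform; ADR is scan-pattern dependent with elevated strips on the
# outermost scan lines; DTDR peaks *between* the spots, because at a spot
# center the farthest still-qualifying neighbour spot sets a lower
# minimum rate.
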