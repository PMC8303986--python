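# Methods

## Delivery model

A field is an ordered list of spots (lateral position in mm, weight in
MU).  The accelerator sets the layer beam current so that the spot with
the minimum MU is delivered in a fixed dwell `dwell_time_min_mu` (default
2 ms); the MU rate of the layer is therefore `min_mu / dwell_min` and any
heavier spot dwells proportionally longer at the same current.  Between
spots the beam is off while the scanning magnets move at `scan_speed`
(default 10 mm/ms); inter-row repositioning uses the same speed.  Dose
accrues at a constant rate during a dwell (rectangular pulse) and not at
all during transit; the cyclotron's MHz pulse microstructure is far below
this model's resolution and is ignored.  The default scan pattern is a
row-serpentine (rows of equal y bottom-to-top, alternating x direction),
which minimizes travel on a lattice; any explicit order is accepted.
Fields are temporally disjoint: each starts its own clock, and dose-rate
metrics are computed per field.  Energy-layer switching does not occur —
transmission plans are single-energy.

## Machine calibration

One calibration anchor links current to dose rate: at nozzle current
`calibration_current` (640 nA) the spot peak dose rate (SPDR) is
`calibration_spdr` (2600 Gy/s).  With `protons_per_mu` (5.17e6) and the
elementary charge, the anchor current corresponds to ≈7.73e5 MU/s, giving
a fixed dose-per-MU constant k ≈ 3.365e-3 Gy/MU at the spot peak.  SPDR
of any layer is then k × MU rate: ≈168.3 Gy/s at 100 MU/spot and
≈673.0 Gy/s at 400 MU/spot.  The anchor is adopted as-is; no
energy-transmission correction is applied between the planning energy and
the calibration energy, as both share the plateau region relevant here.

## Spot dose model

The instantaneous rate of spot i at voxel j is

    rate = SPDR × depth_factor(z) × exp(−r² / (2 σ(z)²)),

with r the lateral distance to the spot axis.  Defaults: σ₀ = 4.0 mm at
the surface (clinical range for ~240–250 MeV spots; the validation suite
exercises σ₀ ∈ [3, 6] mm), σ growth 0.02 mm per mm depth (Coulomb
scattering), and a transmission-plateau depth factor — linear buildup
below the 40 mm reference depth and linear attenuation beyond it, both at
5e-4 per mm, normalized to 1 at 40 mm (the depth at which SPDR is defined
in water) and clipped at zero.  This keeps the properties the metrics
depend on — lateral Gaussian falloff (1.1% of peak at 3σ), a peak near
4 cm, monotone attenuation of the on-axis rate beyond it — while staying
analytic.  It is not a pencil-beam-convolution or Monte Carlo depth dose:
no heterogeneity, nuclear halo, or range straggling, and with σ growth
enabled the *field* dose can rise slowly with depth even though each
spot's on-axis rate falls (energy is not laterally renormalized).

The influence structure stores, per voxel, each contributing spot's rate
(sparse CSR, spots in delivery order); the per-entry dose is
rate × dwell.  Entries beyond `cutoff_sigma` (default 3.5σ, > 99.8% of
the lateral integral) are dropped; the ADR window is insensitive to this
cutoff because the d* trim dominates.  Voxels sample the field at their
centers on a 2 mm isotropic grid by default.  Multi-field plans are
computed field-by-field on beam-aligned grids; plan statistics pool
per-field voxel samples (below), so no shared-grid resampling is needed.

## Metrics

- **DADR** — dose-weighted mean of contributing rates, all influence
  entries within the cutoff, no dose threshold.  Undefined where no dose.
- **ADR** — (D − 2d*)/(t₁ − t₀) with d(t₀) = d*, d(t₁) = D − d*,
  d* = 0.1 Gy default.  The cumulative dose is piecewise linear; the
  crossings are found analytically on a prefix sum of the entry doses and
  interpolated within the crossing ramp.  A crossing that falls exactly on
  a ramp boundary is ambiguous (the cumulative dose is flat at the
  threshold across the adjacent beam-off gap); it is resolved toward
  trimming the gap — the latest admissible t₀ and earliest t₁ — with a
  negligible-dose nudge (1e-9 of the max voxel dose) used only to select
  the ramp, so no bias enters the interpolated time.  Undefined where
  D ≤ 2d*.
- **DTDR** — minimum rate over spots whose individual dose exceeds d*
  (strict inequality); undefined where no spot qualifies.  Ties in the
  minimum do not affect the value; the first spot in delivery order is
  reported as argmin.

ADR and DTDR thresholds are separate configuration keys (both default
0.1 Gy): one trims an accumulation window, the other qualifies spots, and
nothing forces them equal.

Undefined voxels are excluded from histograms rather than set to zero
(configurable `undefined_policy='zero'`): coverage statistics such as
V_40Gy/s are fractions of the *irradiated* volume, and zero-filling would
deflate them with voxels the field never touches.

Useful exact properties (all enforced by tests): for a single
uninterrupted ramp all three metrics equal the local rate; DADR lies
between the min and max contributing rate; ADR never exceeds the largest
instantaneous rate the voxel experiences; DTDR > d*/max dwell on defined
voxels (50 Gy/s for min-MU spots at d* = 0.1 Gy — why DTDR coverage at
40 Gy/s is always total for minimum-MU fields); DADR and DTDR ignore
timing entirely, ADR is invariant to reversing the delivery order; and
scaling the layer minimum MU and all spot MUs by f (with the dose
thresholds scaled alongside, since they are absolute doses) scales all
three fields by f.

## Histograms and statistics

DVH/DRVH curves are cumulative ("volume fraction ≥ value") with
configurable bin width (0.1 Gy / 1 Gy/s defaults); summary statistics
(V_40Gy/s, D2%, mean, max) are computed from the raw voxel samples, never
from the binned curve.  Plan-level DRVHs pool the per-field samples with
multiplicity: a voxel irradiated by k fields contributes k samples.  This
convention matters — per-voxel min/max combination across fields gives
different plan curves — and is therefore the single documented pooling
rule.  Coverage fractions need a bounded region because Gaussian tails
extend indefinitely: the benchmark evaluation mask is the convex hull of
the spot centers at the reference-depth slab (one voxel thick by
default), falling back to a half-voxel-buffered bounding box when the
hull is degenerate (single spot or collinear row).

## Synthetic fixtures

The built-in fixtures define the study conditions; none require external
data.

- *Water-phantom benchmark*: 5×5 cm² lattice at 5 mm spacing → 11×11 =
  121 spots, uniform at the minimum MU (the only self-consistent reading
  of a uniform benchmark map), serpentine order, SPDR pinned to
  1300 Gy/s by override rather than derived from the calibration.
  Delivery takes 302 ms (121 × 2 ms + 120 × 0.5 ms).
- *Single spot* at the origin for closed-form checks.
- *Multi-field cylinder*: n fields (default 5 at 72° spacing) covering
  the beam's-eye-view rectangle of a cylinder target, default 40 mm
  radius × 60 mm length — a realistic lung-target scale.  Spot weights
  default to the minimum MU; an optional jitter draws weights uniformly
  above it, reproducibly from the seed.

What the fixtures do *not* emulate: patient CT heterogeneity, optimized
(non-uniform) spot weights, target-conformal field shapes, inter-field
dead time, and organ geometry.  Passing tests therefore validate the
engine's arithmetic, timing model, and metric definitions — not clinical
dose-rate predictions for patients.

## Validation and problem sizes

The test suite checks worked examples against hand arithmetic, and the
ADR implementation against an independent brute-force time integrator
(1 µs steps, overlap-weighted so step-edge cumulative doses are exact)
to within 0.1% on 50 random 20-spot fields; benchmark-scale runs use the
full 121-spot field on the 41×41×31 2 mm grid (≈0.4 s to build the
influence matrix, ≈0.06 s for all three metrics).  One documented
expectation fails by design of the conditions rather than by
implementation error: on the small benchmark field the *mean* ADR
(~96–161 Gy/s across σ₀ ∈ [3, 6] mm) exceeds the mean DTDR (~57–85 Gy/s),
because 0.3 s of beam-on leaves ADR windows short while DTDR is pinned
near d*/dwell = 50 Gy/s by far-but-qualifying spots (qualifying radius
≈ 2.55σ at SPDR 1300 Gy/s exceeds the 5 mm spacing).  The conventional
ordering ADR < DTDR < DADR is a plan-scale phenomenon and is recovered by
the multi-field cylinder example (~1 s fields): 46 < 66 < 348 Gy/s mean.

## Known limitations

- The depth model is a stylized transmission plateau; absolute doses at
  depths far from 40 mm should not be over-interpreted.
- A single lateral Gaussian per spot (no nuclear-halo second Gaussian).
- DTDR is defined per field; no cross-field DTDR is computed.
- Inter-field and inter-fraction timing is not modeled.
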