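# Methods

`flashpbs` models the planning and delivery-time physics needed to ask one
question: *given a scanned transmission beam (proton or very-high-energy
electron), how much of the relevant high-dose volume is actually delivered
at ultra-high dose rate (UHDR), and how does that depend on the machine's
time structure?*  This note documents the models, their assumptions, the
defaults, and what the synthetic setting does and does not show.

## Synthetic phantoms

Patient CTs are not available for work like this, so all downstream stages
run on procedural phantoms.  The four presets span the geometry axes that
drive scanned-beam dose-rate coverage — target size and depth, density of
the surroundings, and OAR abutment:

| preset | target | surroundings | OARs | fields |
|---|---|---|---|---|
| `brain_like` | 1.5 cm-radius sphere, 4 cm deep | water | box behind target | 1 |
| `lung_like` | 2.0 cm sphere | 0.3-density ellipsoid | lateral box | 2 (0°, 90°) |
| `liver_like` | 4.0 cm sphere | water | posterior box | 2 (0°, 270°) |
| `prostate_like` | 4.0 cm sphere, centered | water | two abutting boxes | 2 lateral (90°, 270°) |

The grid is 100×100×100 voxels at 2 mm (matching the 2 mm spot-grid scale
used throughout); BODY is a box; density is relative to water with no CT
calibration.  Target volumes are strictly ordered
brain < lung < liver ≤ prostate: the small/large-target contrast is the
point of the preset family, so the radii were chosen to make the ordering
an invariant (a 1.5 cm brain target and a 4.0 cm liver target) rather
than mirroring any particular clinical volume.  The presets are declared
surrogates: no clinical PTV volumes, field arrangements or prescriptions
are reproduced.  Field counts per preset are a design choice on clinical
grounds (FLASH transmission treatments use few fields; small shallow
targets are treated with a single field).

Default prescription is 30 Gy in a single fraction — high enough that the
10 Gy threshold of the FLASH index is exercised across structures.

## Beam kernels

Transmission beams traverse the phantom at fixed energy, so the dose of a
spot factorizes as

```
dose(x) = C · PDD(z_rad(x)) · L(r_perp(x), z_rad(x))
```

with `z_rad` the radiological depth (line integral of relative density
along the beam axis), `PDD` a tabulated, piecewise-linear normalized
depth-dose, and `L` a normalized single- or double-Gaussian lateral
profile with linear depth broadening `σ_i(z) = σ_i0 + g·z`.

Defaults:

* **proton 250 MeV** — single Gaussian, σ0 = 4.25 mm (10 mm FWHM),
  g = 0.05 mm/mm, PDD rising 0.95 → 1.10 over 0–300 mm (transmission
  plateau of a high-energy beam);
* **VHEE 150 / 200 MeV** — double Gaussian, σ1 = 5 mm, σ2 = 3σ1 with 10%
  halo weight, g = 0.10 / 0.07 mm/mm, PDD with a 30 mm build-up then a
  linear decline of −0.7 %/cm (150 MeV) or −0.4 %/cm (200 MeV), so the
  lower energy falls off faster with depth.

The core sigmas are the published values for such beams; the halo
fraction, broadening rates and PDD tables are *configuration, not ground
truth* — every table is user-replaceable through the `BeamModel` fields.
These kernels intentionally replace full dose engines (Monte Carlo or
validated analytic transport): the quantities this package studies (dose
rates, FLASH indices, PRF thresholds) are governed by delivery timing and
geometry, not by sub-percent dosimetric fidelity.

Numerical choices: radiological depth uses midpoint-rule ray marching at
a quarter of the smallest voxel spacing (half-spacing sampling leaves up
to ~2.5% error on oblique rays through strongly heterogeneous grids;
quarter-spacing is converged to ≲0.2%).  Density is sampled trilinearly,
so material interfaces sit at midpoints between voxel centers, and the
entry point of a medium that extends to the grid edge is the first voxel
center on the ray.  Columns are truncated below 10⁻⁴ of their maximum and
stored sparse; the calibration constant `C` (Gy·mm²/MU, default 100) sets
the MU scale such that preset spots carry a few MU each.

## Spot placement

Spots are placed in the beam's-eye view of the projected target:
`round(area / spacing²)` interior generators relaxed by Lloyd iterations
to a centroidal Voronoi tessellation (uniform random initialization from
the run seed; at most 50 iterations, 0.1 mm movement tolerance;
generators snapped back inside non-convex regions), plus border spots at
equal arc-length steps along the projection contour.  The default 5 mm
spacing balances the number of scanned spots against in-target
homogeneity.  Border spots are fixed after placement — they do not
participate in the CVT relaxation — and substitute for a lateral margin
(margin defaults to zero).

## Influence matrices and optimization

Per field, dose-per-unit-weight columns are precomputed on a regular 2 mm
BEV node lattice covering the projected target plus a 2σ apron; the
column of a spot at an arbitrary position is the bilinear combination of
its four surrounding node columns (rebuilding at 1 mm pitch leaves node
columns bit-identical and changes the optimized PTV D95 by far less than
0.5%).  Rows of the node matrices cover the scorecard structures plus a
conformity ring (PTV dilated 15 mm, minus PTV) rather than the whole
BODY — the ring stands in for normal tissue at a fraction of the memory.

Weights are found by projected gradient descent with a backtracking
(Armijo) line search on a scorecard of quadratic penalties: one-sided for
`min_dose` / `max_dose` / `mean_dose_max`, two-sided for `uniform` (which
also accepts a per-voxel target).  The solver is deterministic, handles
the nonnegativity constraint exactly, and its objective trace is
non-increasing by construction; it stops at a relative change below
1e−5 (pipeline default) or 300 iterations.  Initialization scales uniform
weights so the mean target dose equals the prescription.  The shipped
scorecards (target uniformity + coverage, OAR max/mean caps, ring cap)
are surrogates standing in for clinical-protocol objective lists, which
are not public for any specific study.

Optional position refinement alternates per-spot finite-difference steps
on the interpolated columns (bounded by half the node pitch) with weight
re-fits, accepting only improving rounds; it is off by default in the
comparison pipeline.

The final dose of the optimized plan is evaluated by direct kernel
evaluation at the optimized spot positions over the whole BODY (not by
node interpolation): delivery and evaluation then share one consistent
per-spot dose matrix, and BODY-wide metrics (conformity indices) are
available without carrying BODY-sized node matrices.  Because the 2 mm
bilinear interpolation slightly widens the effective kernels, weights
tuned on the interpolated influence land ~1% off prescription when
re-evaluated with exact kernels; this systematic offset is common to all
plans of a comparison and cancels in the relative quantities reported.

## Delivery time structure and PBS dose rate

* **Proton (continuous scanned beam)**: dwell = weight / nozzle rate
  (default 2000 MU/s, giving ~2–4 ms dwells on the presets, the scale of
  cyclotron FLASH operation), travel = slower-axis distance / 10 000 mm/s,
  zero switching overhead.  Spots are scanned in serpentine row order.
* **VHEE (pulsed linac)**: spots fire on the global 1/PRF lattice, one
  spot per pulse (pulse capacity 25 MU so preset spots fit in a single
  pulse — the regime in which the PRF alone sets the irradiation time),
  pulse width 4 µs, beam deflection assumed faster than the inter-pulse
  gap.  A heavier spot takes `ceil(w / capacity)` consecutive pulses.

All machine numbers are configurable surrogates.

The per-voxel PBS dose rate is the threshold-trimmed construction: with
cumulative dose curve `D_j(t)` and total `D_j`, a small threshold
`d̂ = 0.1 Gy` is trimmed at each end and

```
DR_j = (D_j − 2d̂) / ( t(D_j − d̂) − t(d̂) )
```

with crossing times found by exact inversion of the piecewise-linear
curve (a linear ramp during each emission).  Voxels with `D_j ≤ 2d̂` get
DR = 0 — they can never count as UHDR, a conservative choice that is
irrelevant at the 10 Gy reporting threshold.  `d̂` is configurable and
every report is tied to the configured value.  Fractions repeat an
identical timeline with effectively infinite pauses: dose rate never
accumulates across fields or fractions.

The UHDR ("FLASH") dose map is `fractions × Σ_fields dose_f · [DR_f ≥ 40 Gy/s]`,
and is bounded by the total dose everywhere, hence DRDVH ≤ DVH pointwise.

Alternative dose-rate definitions (average, percentile, sliding-window)
are noted hooks, not implemented; instantaneous intra-pulse dose rate
plays no role under the trimmed-window definition.

## Metrics and the FLASH index

DVH values use strict `>` at dose levels; dose-rate thresholds use `≥`
(this asymmetry is kept deliberately consistent everywhere).  Quantiles
Dx% sort voxel doses descending and interpolate linearly at midpoint
plotting positions.  HI98 = D98/D2 on the target; CI_X divides the target
volume at the X% isodose by the BODY volume at that isodose and is
reported missing when no voxel reaches the level.

The FLASH index is the generic two-parameter family

```
FI(X Gy, Y Gy/s) = VolDRDVH(X, Y) / VolDVH(X),    FI := 0 when VolDVH = 0,
```

computed per structure from the total-dose and UHDR-dose maps.  It is a
pure coverage ratio — agnostic to the magnitude of any radiobiological
FLASH effect — and satisfies FI ∈ [0, 1] and monotone non-increase in the
dose-rate threshold by construction.  The robustness scan tabulates FI
over dose thresholds 0–20 Gy and dose-rate thresholds 30–100 Gy/s.

## What the synthetic setting shows — and what it does not

The pipeline reproduces, at desk scale, the *directional* structure of
the proton-vs-VHEE comparison: on a large deep target the OAR FLASH
indices of the pulsed VHEE delivery rise monotonically with PRF and only
approach the continuous proton machine's values near 1000 Hz, while a
small shallow single-field target is fully UHDR-covered already at
100 Hz.  Those statements are properties of the time structure and
geometry and are what the test suite asserts.

Absolute FI values, DVH metrics, and the exact PRF at which a given
structure's coverage saturates depend on surrogate choices (machine
constants, scorecards, preset geometry, d̂) and on the simplified kernels;
they are *not* predictions for any clinical case.  Known limitations:
scalar-density phantoms without anatomical texture; no Monte Carlo
transport, nuclear halo or range straggling; no robust or LET-aware
optimization; per-field dose-rate evaluation only (no cross-field
accumulation); and a single PBS dose-rate definition.

## Problem sizes used by the test suite

The end-to-end fixtures run the full compare pipeline on the 100³ presets
(prostate-like with a 100/500/1000 Hz sweep, brain-like at 100 Hz); the
oracle comparisons use 10³-voxel random instances, 1000-voxel random
timelines, and analytic water boxes — sizes chosen so the whole suite
runs in minutes on a single CPU while every assertion stays a property,
not a tuned number.
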