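# flashpbs

**Transmission pencil-beam-scanning planning and FLASH dose-rate
quantification for protons and very-high-energy electrons.**

FLASH radiotherapy exploits the healthy-tissue sparing observed when dose
is delivered at ultra-high dose rates (UHDR, ≳ 40 Gy/s).  Scanned
("pencil beam scanning", PBS) delivery only stays at UHDR with
*transmission* beams — the highest machine energy shot straight through
the patient — which makes the *time structure* of the machine the
deciding factor: a cyclotron-driven proton beam paints spots continuously,
while a very-high-energy-electron (VHEE) linac fires spots on a pulse
lattice set by its pulse repetition frequency (PRF).

`flashpbs` is a desk-scale pipeline for medical physicists who want to
study exactly that trade-off:

* synthetic phantoms spanning four geometry classes (small shallow
  target, target in low-density surroundings, large target, large deep
  target with abutting OARs);
* analytic transmission pencil-beam kernels (single/double Gaussian ×
  tabulated depth dose) for 250 MeV protons and 150/200 MeV VHEE;
* spot placement by centroidal Voronoi tessellation plus ~5 mm border
  spots, and nonnegative spot-weight optimization on precomputed 2 mm
  dose-influence grids with bilinear column interpolation;
* delivery-time models for a continuous scanned proton nozzle and a
  pulsed VHEE linac (PRF 100–1000 Hz);
* per-voxel PBS dose rate via the threshold-trimmed definition
  `DR = (D − 2d̂) / (t(D − d̂) − t(d̂))` with `d̂ = 0.1 Gy`;
* DVH/DRDVH curves, dose quantiles, HI/CI indices, and the **FLASH
  index**

  ```
  FI(X Gy, Y Gy/s) = VolDRDVH(X, Y) / VolDVH(X)
  ```

  — the fraction of a structure's voxels receiving dose > X Gy at a PBS
  dose rate ≥ Y Gy/s, divided by the fraction receiving dose > X Gy
  (FI := 0 when VolDVH = 0).  FI is a model-independent plan metric: it
  measures UHDR coverage of the relevant high-dose volume without
  assuming any magnitude for the radiobiological FLASH effect.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Compare a proton plan against VHEE 200 MeV at two PRFs on the small
shallow-target preset (30 Gy, single fraction, one field):

```python
from flashpbs.pipeline import compare_modalities

fi, metrics, deliveries = compare_modalities(
    "brain_like", prf_values_Hz=(100, 500), seed=1)
print(fi.to_string(index=False))
```

```
  modality      structure   VolDVH  VolDRDVH      FI
    proton           BODY 0.046418  0.046418 1.00000
    proton            PTV 1.000000  1.000000 1.00000
    proton brainstem_like 1.000000  1.000000 1.00000
vhee@100Hz           BODY 0.050960  0.022294 0.43747
vhee@100Hz            PTV 1.000000  1.000000 1.00000
vhee@100Hz brainstem_like 1.000000  1.000000 1.00000
vhee@500Hz           BODY 0.050960  0.050960 1.00000
vhee@500Hz            PTV 1.000000  1.000000 1.00000
vhee@500Hz brainstem_like 1.000000  1.000000 1.00000
```

Reading the table: `VolDVH` is the fraction of each structure above
10 Gy, `VolDRDVH` the fraction above 10 Gy *delivered at ≥ 40 Gy/s*, and
`FI` their ratio.  For this small target both the PTV and the adjacent
OAR are fully UHDR-covered (FI = 1) by the continuous proton beam and by
the pulsed beam even at 100 Hz; only the body-wide beam track needs
500 Hz to saturate.  On the large deep `prostate_like` preset the same
sweep shows the opposite regime — OAR FI climbs from ≈ 0 at 100 Hz to
≈ 0.73 at 1000 Hz and stays below the proton plan at 500 Hz.

The plan-quality side of the comparison comes out of the same call:

```
modality structure    D95_Gy     D2_Gy     HI98
  proton       PTV 27.080685 31.418996 0.844888
    vhee       PTV 27.011415 32.087891 0.823686
```

The same pipeline is scriptable from the shell:

```bash
flashpbs compare --preset prostate_like --prf 100,250,500,1000 \
    --seed 1 --out runs/prostate
flashpbs phantom --preset lung_like --out runs/lung_phantom
```

Each run directory contains the FI report and metric tables as CSV plus a
`manifest.json` (config hash, seed, versions) that makes the run exactly
reproducible.

## Layout

```
src/flashpbs/
  grids.py      voxel grids, structure sets, NIfTI I/O
  phantom.py    synthetic phantom presets
  beams.py      pencil-beam kernels, radiological depth, dose columns
  spots.py      BEV projection, CVT + border spot placement
  optimize.py   dose-influence matrices, scorecards, weight/position solver
  delivery.py   machine models, timelines, PBS dose-rate & UHDR maps
  metrics.py    DVH/DRDVH, quantiles, HI/CI, FLASH index
  pipeline.py   plan / deliver / compare orchestration
  cli.py, io.py command line and file formats
```
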