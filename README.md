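# foveapit

Automated foveal-pit morphometry from macular OCT volumes, plus the
sex-stratified multilevel association analysis that a population eye
study builds on top of such a phenotype — implemented end to end on
synthetic data so that every stage is testable against known ground
truth without any restricted imaging data.

## Who this is for

Researchers in ophthalmic image analysis and ophthalmic epidemiology who
want a transparent, fully seeded reference implementation of the classic
OCT phenotyping chain: graph-based retinal boundary segmentation →
quadratic pit morphometry → linear mixed models over eyes nested in
participants.

## What it computes

A volume is 128 B-scans × 512 A-scans over a 6 × 6 mm macular field.
For each eye the pipeline produces:

* **FC (foveal curvature)** — the retina band (ILM to RPE) is segmented
  per B-scan as a minimum-cost path (A\* with an admissible heuristic,
  cost = inverted vertical gradient + smoothness penalty λ·|Δrow|,
  λ = 0.05, max jump 15 rows); the fovea centre is the centroid of the
  thinnest-retina region of the smoothed thickness map; FC is the
  negated leading coefficient **a** of an OLS quadratic
  `row = a·x² + b·x + c` through the 25 ILM trace points within ±12
  columns of the centre, reported as FC × 100 (positive = steeper pit).
* **MC (macular curvature)** — the median over the 32 central B-scans of
  the analogous quadratic coefficient fitted to each RPE trace, × 100.
* **CPRT (centre-point retinal thickness)** — `rpe_row − ilm_row` at
  the centre, in pixels and µm.

On the cohort side, FC is z-standardised and modelled by REML with a
person-level random intercept,

    fc_z(person i, eye j) = x_ij'β + b_i + e_ij,  b_i ~ N(0, σ_b²),  e_ij ~ N(0, σ_e²),

stratified by sex, with nested covariate sets (model 1: age, ethnicity,
height, assessment centre; model 2: + VA, SE, corneal astigmatism, IOP,
MC, CPRT; model 3: + deprivation, education, fluid intelligence, income,
birth order), Satterthwaite degrees of freedom for per-term tests, an
ordered-income linear trend test, and sensitivity refits after excluding
high refractive error and low visual acuity.  The REML engine is
validated in the test suite against statsmodels and R's lmerTest.

The synthetic generators are first-class library code: volumes render a
three-zone scene with an exactly-quadratic pit core, curved RPE and
multiplicative gamma speckle, exporting the boundary truth as rendered;
cohorts have two eyes per person with configurable standardized effects
and variance components.

## Worked example

```python
from foveapit.synthetic import VolumeParams, generate_volume
from foveapit.morphometry import quantify_volume

params = VolumeParams()          # FC 0.0725, MC 0.0021, CPRT 87 px, speckle 0.35
volume, truth = generate_volume(params, seed=42)
rec = quantify_volume(volume)
print(f"fovea centre : slice {rec.center.slice}, column {rec.center.column}")
print(f"FC x 100     : {rec.fc_x100:.3f}   (truth {100*truth.a_fovea_true:.3f})")
print(f"MC x 100     : {rec.mc_x100:.3f}   (truth {100*truth.a_macula_true:.3f})")
print(f"CPRT         : {rec.cprt_um:.1f} um  (truth {truth.cprt_true_px*2.6:.1f} um)")
print(f"QC           : {rec.qc}")
```

prints

```
fovea centre : slice 64, column 256
FC x 100     : 6.934   (truth 7.250)
MC x 100     : 0.210   (truth 0.210)
CPRT         : 226.1 um  (truth 226.2 um)
QC           : ok
```

The fovea centre and thickness are recovered essentially exactly; the
FC estimate is ~4% off truth for this seed, typical of single-slice
quadratic fitting at the default speckle contrast (median relative
error is 2–3%).  With `noise_sigma=0.0` the same run returns
`FC x 100 = 7.25000`, `MC x 100 = 0.21000`, `CPRT = 226.20 um` — the
sub-pixel boundary refinement makes noiseless recovery exact.

A command-line driver wraps the same stages:

```bash
foveapit simulate --out runs/demo --seed 1          # volumes + cohort CSV
foveapit segment  --in runs/demo/volume_0000.tiff --out traces.csv
foveapit quantify --in runs/demo/volume_0000.tiff --traces traces.csv --out morph.csv
foveapit analyze  --cohort runs/demo/cohort.csv --models 1,2,3 --out tables/
foveapit run-all  --out runs/full --seed 1          # everything + run log
```

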