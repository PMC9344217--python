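# Methods

`foveapit` re-creates, end to end and on synthetic data, an automated
pipeline for quantifying the shape of the foveal pit from macular OCT
volume scans, together with the population-scale statistical analysis
such a phenotype feeds into.  This note records the model behind each
stage, the defaults and why they were chosen, and what the synthetic
data can and cannot tell you about behaviour on real scans.

## The imaging scene and its simulator

A volume is a raster of 128 B-scans, each 512 A-scans wide, covering a
6 x 6 mm macular field (lateral scale 6/512 mm per column).  Frame
height (650 rows) and axial scale (2.6 um/row) are configurable
assumptions: the emulated device family does not publish a single fixed
export geometry, and the axial scale only rescales the thickness in
micrometres, never the curvature coefficients, which live entirely in
pixel coordinates.

The simulated scene has three intensity zones: dark vitreous above the
internal limiting membrane (ILM), a bright retina band from the ILM to
the retinal pigment epithelium (RPE), and a dimmer choroid below.  The
RPE is a downward-opening quadratic bowl, row = R0 - a_mac * u^2 with
u the column offset from the macula centre; the reported macular
curvature (MC) convention is the negated leading coefficient, so a
normal bowl is positive (default a_mac = 0.0021, i.e. MC x 100 = 0.21).
The ILM runs parallel to the RPE at the rim thickness except for the
foveal pit: a downward bump whose profile is *exactly* quadratic within
+/-20 columns of the pit centre and then blends into the flat rim via a
C1 cubic Hermite segment ending with zero slope at +/-60 columns.  A
cosine blend cannot match both value and slope at the junction without a
kink, hence the Hermite choice; the curvature fit window (+/-12 columns)
lies strictly inside the quadratic core either way.  The bump
coefficient is a_fovea - a_mac, so the realized ILM leading coefficient
in the fit window equals `a_fovea` exactly -- the generator's ground
truth is the quantity the pipeline is supposed to recover (default
a_fovea = 0.0725, FC x 100 = 7.25).  Pit depth is 1.2x the quadratic
core span and the bump amplitude decays across slices as a Gaussian with
SD 6 slices, giving a pit of similar lateral extent in both directions
and a unique thickness minimum at the pit centre (default centre-point
thickness 87 px = 226.2 um at the default axial scale).

Frames are rendered by area sampling (each pixel's value is the
coverage-weighted mix of the zones crossing it), so boundary positions
are encoded with sub-pixel precision, and the band convention is that
the pixel row equal to the reported RPE row is the last retina row --
thickness in pixels is exactly `rpe_row - ilm_row`.  Speckle is
multiplicative gamma noise with unit mean; its SD (`noise_sigma`,
default 0.35) is the speckle contrast.  0.35 is a realistic value for
device-preprocessed OCT exports; it was fixed before any accuracy
measurements and is the condition under which all noisy-scan results
below are quoted.

What the simulator does **not** contain: vascular shadows, motion and
blink artifacts, pathology, intensity roll-off with depth, or a
multi-layered retina.  Segmentation scores on these scans therefore
bound what the same algorithm would do on clean real scans, not on hard
ones; the statistical machinery downstream is insensitive to this
because it is exercised on the cohort generator instead.

## Boundary segmentation

Each B-scan is segmented by minimum-cost path search, the classic
graph formulation of OCT layer tracing.  For each surface a cost image
is built from the vertical one-sided intensity gradient of the scan
after a vertical-only Gaussian blur (sigma 1 px): backward difference
for the ILM (dark above, bright here), forward difference for the RPE
(bright here, dark below), min-max normalised to [0, 1] with 0 at the
strongest edge.  One-sided differences map a sharp edge to a unique row;
the blur is purely vertical because lateral smoothing visibly smears the
edge where the surface is steep (the pit walls fall ~3 rows per column).
A scan whose gradient dynamic range is below 1 intensity unit is
rejected as featureless.

The surface is the globally minimal left-to-right path with unit column
steps, a hard cap of 15 rows per step, and an L1 smoothness penalty of
lambda = 0.05 per row of jump.  The penalty weight matters at the
extremes: cutting straight across a pit saves about 2 x depth x lambda,
so at lambda = 0.1 the *globally optimal* path shortcuts the deepest
population-tail pits (FC >= ~0.12, depth ~60 rows) and underestimates
their curvature by tens of percent; at 0.05 the optimum follows the
walls of even an FC = 0.15 pit while flat-region accuracy and IoU are
unchanged.  The production search is A* with the admissible and
consistent heuristic "suffix sum of per-column cost minima", so the
first goal expansion is provably optimal.  On tall scans the search is
bracketed to a +/-18-row corridor around a coarse path found on a 4x
min-pooled, laterally smoothed guide cost (min-pooling keeps the thin
low-cost edge visible at coarse scale; the coarse pass uses half the
smoothness and a 10-coarse-row jump cap so it can follow steep walls
without wandering with the speckle, and the corridor is widened at the
lateral edge columns where the coarse path only extrapolates).  The
search falls back to the unrestricted image whenever the banded optimum
presses against its corridor wall or the best cost outside the corridor
beats the inside for eight or more consecutive columns -- the signature
of a mis-bracketed pit rather than a speckle-weakened edge.  An
exhaustive column-by-column dynamic program over the identical cost
function is kept in the package as an independent oracle, and the test
suite asserts cost equality between the two routes across the full
population curvature range.

If the two paths cross, the ILM is clamped to one row above the RPE and
the scan flagged low-confidence.  The mask is the band between the paths
inclusive; traces extracted from masks take the top/bottom true row per
column, with empty columns linearly interpolated and flagged invalid.

A final sub-pixel refinement inverts the fractional coverage of the
partial edge pixel on the *raw* scan (plateau levels estimated by local
medians, midpoint crossing located, coverage inverted).  On noiseless
renders this recovers the continuous boundary exactly, which is what
makes end-to-end exact-quadratic recovery possible; integer-quantised
traces alone bias the 25-point quadratic coefficient by about 2%.

Measured under the default conditions (fresh seeds): mean mask IoU
~0.995 over scan sets, 95% of trace columns within 1 row of truth;
worst-case single columns at the pit walls reach ~6-8 rows, the
intrinsic lateral-ambiguity-times-slope limit at this speckle level.

## Morphometry

* **Fovea centre**: the 128 x 512 thickness map (RPE minus ILM trace) is
  smoothed with a 3-slice x 11-column moving average -- anisotropic
  because slice spacing (47 um) is ~4x the column spacing -- and the
  centroid of the minimal connected region is rounded to (slice,
  column).  Ties across disjoint minimal regions break to the lowest
  slice then column.  A centre on the volume border or within 12 columns
  of the lateral edge is a QC failure (pit not captured).
* **CPRT**: `rpe_row - ilm_row` at the centre column, times the axial
  scale for micrometres.  Non-positive thickness is a QC error.
* **FC**: ordinary least-squares quadratic through the 25 ILM trace
  points within 12 columns of the centre on the centre slice, in pixel
  coordinates; the negated leading coefficient is reported (positive =
  steeper pit) together with FC x 100.  The window semantics ("12 left
  and right") and the single-centre-slice reading of the fit are the
  natural interpretation of the method being emulated; a 2-D surface
  fit across slices is a documented non-goal.
* **MC**: per central slice (slices 48-79, the symmetric middle 32 of
  128), an OLS quadratic over the valid RPE trace columns; the median of
  the 32 negated leading coefficients.  The median tolerates up to 15 of
  32 slices being corrupted to one side, which the suite asserts.

FC at default noise has a per-volume relative error of ~2-3% (median),
driven almost entirely by residual trace noise inside the 25-point
window rather than by bias; 1,000-replicate simulations show the fit
itself is unbiased to <1%.

The tertile-ordering validation mirrors a reader study: a pool of
volumes with population-spread FC (normal, mean 0.0725, SD 0.02,
clipped to [0.02, 0.15]) is split into tertiles by true FC; each of 10
sets takes the rank-matched (evenly spaced) member of every tertile, and
a set counts as correct only if the pipeline FC values are strictly
ordered with tertile rank (ties count against).  Rank-matched assembly
is deterministic and avoids pairing two scans that straddle a tertile
boundary by less than any finite pipeline's resolution.

## Synthetic cohort and multilevel analysis

The cohort generator emulates a large population eye study: ~55%
female, age 56 (SD 8), 92.1% white with the remaining ethnic groups at
a few percent or less, sex-specific height, ocular covariates drawn per
eye around person-level means, ordered income bands, deprivation
quintiles, education, birth order, assessment centre, and rare
disease/surgery flags.  The FC outcome is built additively: a linear
predictor from configurable standardized effects (each applied per its
reporting increment), a person-level random intercept, and eye-level
noise.  Default variance components are SD 0.85 between persons and SD
0.5 residual -- a fellow-eye intraclass correlation of ~0.74, realistic
for a strongly person-determined ocular trait -- and with default
effects the total SD is close to 1, so configured effects read
approximately as SD units.  Thirty percent of persons contribute one eye.

Analysis proceeds as in the emulated study: eye-level exclusion of
disease/surgery flags (sensitivity mode additionally drops SE beyond
+/-6 D and VA below 80 letters), z-standardisation of FC on the pooled
included sample (both sexes, before stratification -- sex differences
are reported on a common scale), covariate encoding on the reporting
increments with missing categories kept as explicit levels, and
sex-stratified random-intercept models 1-3 of strictly nested covariate
sets.  The income trend test rescores the ordered bands 1..5 as a single
term while non-informative levels keep their adjustment dummies.  No
multiple-testing adjustment is applied, matching the per-term
presentation of the emulated analysis.

The REML fitter is package-authored: with at most two eyes per person
the covariance is block diagonal with 1x1/2x2 blocks, the criterion
profiles to one variance ratio, and a Brent search over the profiled
criterion plus the group-mean-shrinkage GLS transform gives a fit in
tens of milliseconds at 10,000 eyes -- two orders of magnitude faster
than generic mixed-model machinery, which is what makes 100-replicate
coverage and 400-replicate type-I studies affordable.  Satterthwaite
degrees of freedom are computed from the delta method on the diagonal of
the fixed-effect covariance, with the variance-parameter covariance
taken as twice the inverse Hessian of the -2 restricted log-likelihood
(finite differences).  The engine is cross-checked in the test suite
against statsmodels MixedLM (estimates, SEs, variance components) and
against R's lmerTest (Satterthwaite dfs and p-values agree to ~4
significant figures); boundary fits (zero between-person variance) are
flagged singular and fall back to residual degrees of freedom.

Calibration studies fit the **raw** FC outcome: the configured generator
effects are exact truths on that scale, whereas z-scoring divides by a
sample SD that includes effect-induced variance, so "the CI covers the
generating value" is only a well-posed check on the raw scale.  The
z-score path is verified separately by the identity z-coefficients =
raw-coefficients / SD(FC).  Coverage runs use 5,000 persons x 100
replicates; the null type-I study uses 400 persons x 400 replicates
(problem sizes chosen to keep a full calibration run in the
single-digit minutes on one core).

## Numerical and degenerate-input choices

* Coordinates are 0-based; rows grow toward the choroid.  All sign
  conventions (FC, MC positive for the normal anatomy) follow from
  negating raw leading coefficients.
* IoU of two empty masks is defined as 1.0.
* `a_fovea = 0` renders a locally flat ILM (the bump exactly cancels
  the RPE bowl inside the rim), and the FC fit returns 0.
* Constant-intensity scans raise a boundary-not-found error rather than
  returning an arbitrary path.
* QC failures inside the per-volume pipeline produce a record with null
  measures and the failure reason instead of an exception.
* The profiled REML search runs over log variance-ratio in [-20, 8] and
  compares against the exact boundary value, so singular fits are
  detected rather than approximated.

## Known limitations

* The synthetic retina is a two-surface, three-zone scene; there is no
  evidence here about multi-layer segmentation or pathology robustness.
* Worst-case trace error at the pit walls (~6-8 rows on isolated
  columns) is intrinsic to single-scan tracing at speckle contrast 0.35;
  methods that average neighbouring B-scans would do better but would
  blur the very curvature being measured.
* The cohort generator draws covariates independently apart from
  sex-height coupling and the configured effects; real confounding
  structure is richer.  Parameter-recovery results validate the
  estimator, not any epidemiological claim.
* CPRT in micrometres inherits the assumed axial scale; curvatures do
  not.
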