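# Methods

`protonqa` re-creates, at desk scale, the statistical pipeline a proton
pencil-beam-scanning (PBS) clinic uses to commission an *independent dose
calculation* as a patient-specific QA (PSQA) method: gamma-index comparison of
paired dose distributions, point-dose verification, and the derivation of
confidence, tolerance and action limits from per-plan gamma passing rates.
The clinic's actual dose engines (a treatment planning system and a Monte
Carlo recalculation) and its detector measurements are not reproducible on a
desk; an analytic PBS dose generator and a cohort generator stand in for them.
This note records the models, the defaults, and what the substitution does and
does not establish.

## Gamma index

For a reference point **r** with dose `D_ref(r)`, the gamma index is

    gamma(r) = min over r' of sqrt( |r' - r|^2 / dta^2
                                  + (D_eval(r') - D_ref(r))^2 / dD^2 )

with `dta` the distance-to-agreement criterion (mm) and `dD` the dose
criterion in Gy: `dose_tol% x max(D_ref)` under global normalization (the
default) or `dose_tol% x D_ref(r)` under local.  A point passes when
`gamma <= 1`; the passing rate is the percentage of passing points among
reference points at or above the low-dose threshold (default 10% of the
normalization dose).

Search configuration (all exposed on `GammaCriteria`): the evaluated dose is
sampled by trilinear interpolation on a fine offset lattice of step
`dta / fine_step_fraction` (default dta/10) out to a radius of
`search_radius_factor x dta` (default 3).  The optimized engine visits offsets
in shells of increasing distance and retires a point once the distance term
alone exceeds its current best gamma; this is exactly equivalent to the
exhaustive search over the same lattice, and the test suite verifies the
equivalence against an independent brute-force oracle built on
`scipy.interpolate.RegularGridInterpolator`.

Numerical choices:

* Ties at `gamma = 1` pass; the comparison uses `1 + 1e-9` so that the
  analytically borderline case (a uniform +3% pair under a 3% criterion,
  where gamma is exactly 1 everywhere) is not failed by float rounding.
* Offsets falling outside the evaluated grid are dropped (truncated search
  sphere): no dose is invented beyond the computed volume.  Reference points
  with no evaluated sample at all are excluded from the evaluation count.
* The comparison is asymmetric by construction (reference defines the query
  points); only the reference-vs-evaluated direction is specified or tested.
* Comparing rates *across* criteria with different DTA is subject to a
  sampling artifact: the default step `dta/10` gives each criterion a
  different offset lattice, and a finer lattice can find slightly smaller
  gammas.  Monotonicity checks (3%/2mm -> 3%/3mm -> 5%/3mm) therefore use a
  common absolute step (fine_step_fraction scaled with DTA).

A one-voxel-thick reference grid expresses a planar (detector-style)
comparison; the search still explores the evaluated volume in 3D along any
axis where it has extent.

## Analytic PBS beam and dose engine

* **Range-energy**: Bragg–Kleeman, `R(cm) = alpha E^p`, defaults
  `alpha = 0.0022 cm/MeV^1.77`, `p = 1.77` (standard water values).  The
  machine window is 70–220 MeV (ranges ~4.1–30.8 cm).
* **Depth dose** (relative, peak = 1, `s = peak_sigma_frac x R`): a constant
  entrance plateau (`entrance_ratio`, default 0.35) plus a Gaussian peak on
  the proximal side, and a slightly narrower Gaussian (0.9 s) on the distal
  side.  This satisfies the qualitative constraints that matter for QA
  emulation: entrance value = `entrance_ratio` exactly, monotone rise to a
  single peak at `R`, distal 80–20% falloff of ~1 s (2.4 mm at 160 MeV), and
  < 1% of peak within 3 s beyond it.  `peak_sigma_frac` defaults to 0.012,
  the order of range straggling in water.
* **Lateral spot**: normalized 2D Gaussian with
  `sigma(z) = sigma0 + sigma_growth x z` (defaults 4 mm + 0.3 mm/cm), plus
  0.5 mm per cm of range-shifter thickness.
* **Range shifter**: pure range pullback by its water-equivalent thickness
  (depth-dose evaluated at `z + shifter`) plus the lateral inflation above.
  Allowed thicknesses: 0/2/3/5 cm.
* **Dose** is the weight-linear superposition over layers and spots,
  optionally rescaled so a stated point receives a stated dose (2 Gy at 2 cm
  depth for the single-energy reference fields).  Uniform-weight rectangular
  spot grids take a separable fast path (outer product of 1D Gaussian sums);
  arbitrary layouts take a per-spot path; the two agree to float precision
  and both are covered by tests.

**Plan builders.**  The single-energy field is a 10 x 10 cm^2 grid at 2.5 mm
pitch (41 x 41 = 1681 spots, 100 MU each).  Cubic SOBP plans space layer
ranges by ~1.2 local peak sigma across the target span and solve per-layer
weights by non-negative least squares against the depth-dose curves on a
1 mm central-axis lattice; the resulting SOBPs are flat within ±3% for every
cube (3–15 cm) and depth (10–20 cm) in the validation matrix.  A 15 cm cube
at 10 cm depth needs a proximal range below the 70 MeV minimum;
`range_shifter_cm="auto"` then selects the smallest feasible shifter (2 cm),
mirroring clinical practice for shallow targets.

**Perturbation model.**  The "evaluated" member of each synthetic QA pair is
the reference grid after, in order: rigid translation (trilinear, zero fill),
a distal range shift (depth-proportional stretch: zero displacement at the
entrance plane, the full shift at the deepest plane), a multiplicative dose
offset, and voxelwise Gaussian noise (clipped at zero — dose is
non-negative).  A zero spec returns the input unchanged, bit for bit.
Pipeline defaults — +1% dose, (0.5, 0, 0.5) mm shift, 0.8% noise, 1 mm range
error — were chosen once as a plausible TPS-vs-Monte-Carlo discrepancy scale
and produce passing rates in the high-90s, the regime the clinical tables
report.  Shifted plans additionally receive 0.3 mm of range error per cm of
shifter (WET uncertainty), which reproduces the published qualitative
passing-rate decrease with shifters; without it the shifter cancels out of
the reference/evaluated pair.

**Simple-plan scoring** is planar: gamma is evaluated on the central
beam-axis (x–z) plane of the reference volume against the full evaluated
volume.  Whether the original clinical comparisons were 2D or 3D is not
recorded; planar scoring matches detector-array QA practice and keeps the
full matrix tractable on one CPU.

## Passing-rate cohorts

Site-labelled per-plan passing rates are drawn from a normal distribution
truncated above at 100%.  Because truncation shifts moments, the generator
*moment-matches*: it solves (Brent's method on the standardized bound, with
`scipy.stats.truncnorm` moments) for the pre-truncation parameters whose
truncated distribution has exactly the requested mean and SD, so sample
statistics converge to the targets and SPC limits computed on generated
cohorts recover the closed-form values of the generating parameters.

An upper-truncated normal always has `SD < (100 - mean)`; published cells
with `SD >= 100 - mean` (e.g. 99.0 ± 1.7, and most measurement-column cells)
are infeasible for this family — real QA-rate distributions are skewed with
a point mass at 100, which a two-parameter summary cannot pin down.  For
such cells the mean is matched exactly and the SD is capped at the family's
maximum (standardized bound floored at −8).  The pooled statistics used in
the stochastic acceptance checks (95.9 ± 2.7 and 97.9 ± 1.8) are feasible
and recovered to within sampling error.

The cohort size defaults to 10 plans per site (50 plans over five sites, the
published cohort's size; the per-site split is not recorded and 10/site is
assumed).

## SPC limits

On a series of per-plan passing rates `x_i` (acquisition order) with mean
`x̄` and sample SD `s` (n−1 denominator):

* **Confidence limit** (TG-119 style): deviations are measured from the
  100% ideal and the limit is reported as a lower bound on the rate,
  `CL = 100 − (|100 − x̄| + 1.96 s)`.  This deviation reading is the one
  consistent with the published limit table.
* **Tolerance limits** (individuals chart): center line `x̄`, control lines
  `x̄ ± 2.660 m̄R` with `m̄R` the mean moving range
  `(1/(n−1)) Σ |x_i − x_{i−1}|`.  The lower line is the reported tolerance
  limit (rates fail downward).  The source's lower-control-line formula
  prints a "+" — an evident typo (it would equal the upper line) — corrected
  to "−" here.  Because `m̄R` depends on the (unpublished) acquisition order,
  printed tolerance-limit cells are not exactly reproducible from summary
  statistics; the I-chart is instead validated by its statistical property
  `2.660 x E[m̄R] = 3 sigma` on i.i.d. normal series.
* **Action limits** (TG-218): `dA = beta sqrt(s^2 + (x̄ − T)^2)` with
  `beta = 6`, target `T = 100`; limits `T ± dA/2`, lower one reported.

Raw limits are exact closed forms; rounding (one decimal) and capping to
[0, 100] happen only in reports.  Comparison statistics are two-sided paired
t-tests (measurement vs recalculation per site) and one-way ANOVA across
sites at alpha = 0.05, with no multiple-testing correction — deliberately
mirroring the emulated workflow; both are known limitations.

## What a green suite establishes — and what it does not

The synthetic generator reproduces the *statistical structure* the pipeline
consumes: plan geometry, dose pairs whose disagreement is of the stated
scale, and cohorts with the published summary statistics.  Green tests
establish that the gamma engine, the limit formulas and the pipeline are
correct and deterministic, and that the closed-form limit cells follow from
the published summary statistics.  They do not establish anything about real
TPS/Monte Carlo agreement: the published per-plan clinical rates depend on
the clinic's beam model, CT data and detector, none of which are modelled.
Heterogeneity effects (e.g. lung), nuclear halo dose, and detector response
are explicitly outside the dose model.

## I/O conventions

Grids are (nx, ny, nz) arrays in Gy with `origin` at the center of voxel
(0,0,0) and spacing in mm (DICOM RT Dose semantics; beam along +z for
synthetic grids).  DICOM RT Dose is read and written by a built-in minimal
explicit-VR little-endian codec (32-bit pixels; quantization < 1e-4 of max
dose; identity image orientation only).  A plain JSON grid format serves as
the text fixture format.  All randomness flows from explicit integer seeds;
no global state.
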