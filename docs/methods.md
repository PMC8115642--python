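# Methods

## Kinetic model

The package works on three-phase DCE-MRI: one acquisition before
contrast injection and two after, at roughly 1–2 min (early) and
5–6 min (delayed). For an ROI with mean signals SI_pre, SI_early,
SI_delay, two semi-quantitative descriptors summarise the
time–signal-intensity curve:

- washout index WI = (SI_early − SI_delay) / SI_pre × 100 %, the
  strength of signal loss between the early and delayed phases;
- initial enhancement ratio SI_early / SI_pre × 100 %.

A curve is *fast-washout* iff the ratio is strictly above 200 % and
WI is at least 10 %; the complement (ratio ≤ 200 % **or** WI < 10 %)
is *other*. The strict/inclusive pattern at the two thresholds is
deliberate and pinned by boundary tests. Both thresholds are module
constants, overridable per call and via the run configuration, so
sensitivity analyses do not require code changes. Negative WI is a
legal value (persistent enhancement), not an error; a non-positive
SI_pre is an error, since it is the denominator of both indices.

No pharmacokinetic modelling (Tofts, Ktrans) is attempted: the package
deliberately stays at the semi-quantitative level that standard
clinical DCE protocols support.

## ROI search geometry

The lesion-level WI is defined by an exhaustive max-WI search:

- the ROI is a flat disc of 3 mm diameter within a single slice;
  membership is by in-plane voxel-center distance ≤ radius (inclusive);
- placements are enumerated at every voxel center, in every slice of
  all three orthogonal plane families (axial-only available via
  config), and the disc must be fully contained in the lesion mask —
  and hence in the grid (erosion with zero border); containment
  prevents partial-volume dilution from outside the lesion;
- per placement, the per-phase ROI mean signals feed the WI formula;
  placements with non-positive pre-contrast mean are skipped with a
  warning; ties on the maximum break to the first placement in
  (plane, slice, row, column) order, for bit-stable results;
- lesions too small to host any disc raise a no-placement signal by
  default (mirroring the exclusion of unmeasurably small lesions from
  signal analysis); an optional single-voxel fallback exists.

Anisotropic voxels are supported; in-plane distances use the two
in-plane spacing components. Indexing is 0-based with world
coordinates = index × spacing; oblique orientations are assumed to be
resampled upstream. Exhaustive enumeration is a superset of a
radiologist placing "multiple ROIs" by hand, so the search can only
find an equal or higher maximum than a manual reading.

Implementation note: per plane family the disc means of *all*
placements are computed at once by correlating each phase volume with
the normalised disc footprint; the test suite checks this against an
independent brute-force oracle (explicit shift-and-AND containment,
shift-and-add sums) on ~100 random phantoms up to 32³ voxels.

Lesion size is the longest in-plane Feret diameter: the maximum
center-to-center distance between mask voxels within any single slice,
over the three plane families. Center-to-center is the simplest
defensible convention (a single voxel has diameter 0) and is stated so
fixtures are exact. A convex-hull shortcut is used for slices with
many voxels; degenerate (collinear) slices fall back to direct
pairwise distances.

Shrinkage-pattern classification (concentric vs dendritic) is a
computational proxy for a visual call: a partial-response lesion is
*dendritic* if it fragments into more 26-connected components than the
baseline, or if it is not contained in the baseline's morphological
interior (baseline eroded by 2 mm, configurable) — residual tissue
hugging the original boundary is uneven shrinkage. An empty follow-up
mask is CR, for which the category is undefined.

## Response logic

RECIST on longest diameters with baseline at the pre-treatment scan:
CR when no enhancing lesion remains (size 0); PD at ≥ +20 %; PR at
≥ −30 %; SD otherwise; both thresholds inclusive and PD given
precedence for determinism. The imaging predictor of pathological
response is *WI < 0 (strict) or size = 0*; the size-only predictor is
*size = 0*. The size rule logically implies the kinetic rule, which
the suite asserts as a property. Survival stratification at a
timepoint is three-way: CR on MRI, residual lesion with fast washout,
residual lesion with other curve type; "residual disease" here is the
radiological residual (an enhancing lesion), since curve type is only
defined where enhancement persists. The 20 mm size stratification is
strict (< 20 vs ≥ 20).

pCR and RCB class are carried as independent cohort columns with no
cross-constraint: clinically, pCR definitions admitting residual
in-situ disease are a superset of RCB-0, and the package does not
force one convention on input data. (The synthetic generator, by
contrast, derives pCR = RCB-0 — a simplification of the generator,
not of the analysis.)

## Statistics

- Fisher's exact test (two-sided) uses the sum-of-small-p definition:
  the sum of hypergeometric probabilities, over tables with the
  observed margins, not exceeding the observed probability (relative
  tolerance 1e-7 for float ties). This is the definition used by the
  common biostatistics packages of the study's era and reproduces all
  six published p-values at printed rounding; it is cross-checked
  against a full-enumeration oracle for tables with n ≤ 40.
  Degenerate margins give p = 1 with a warning.
- Diagnostic performance: sensitivity, specificity, PPV, NPV, accuracy
  in percent; a zero denominator makes that metric (only) NaN with a
  warning.
- Spearman correlation uses mid-ranks for ties and the large-sample t
  approximation for p; constant input is signalled as undefined rather
  than returned as NaN.
- Reader agreement is ICC(2,1): two-way random effects, absolute
  agreement, single rater, computed from the two-way ANOVA mean
  squares. This form is chosen because both readers rate every lesion
  and both are samples from a population of readers, and absolute
  agreement (not consistency) is what justifies averaging their
  measurements. Categories: < 0.50 poor, 0.50–0.75 moderate,
  0.75–0.90 good, > 0.90 excellent, with boundary values assigned to
  the lower-named category. Cross-checked against pingouin's ICC(A,1).
- The two-sample t-test is the pooled-variance (Student) form by
  default, Welch via flag.
- Display rounding is 1 dp for percentages and 4 dp for p-values;
  machine-readable outputs keep full precision. No multiple-testing
  correction is applied anywhere.

## Survival

DDFS: time from start of preoperative chemotherapy to distant
metastasis; anyone without the event is right-censored at last
follow-up ("discounted" is read as censoring, the standard treatment).
Non-positive follow-up times are rejected with a warning.

Kaplan–Meier, the K-group log-rank test and univariate Cox regression
are implemented in-package: the product-limit estimator processes
censoring at an event time after the events; the log-rank statistic
accumulates hypergeometric observed−expected terms over distinct event
times; Cox maximises the partial likelihood by Newton iteration with
step-halving, converging when the log-likelihood change drops below
1e-9 (≤ 50 iterations), with Efron tie handling by default and Breslow
via option. Efron is the default because event times with yearly-scale
granularity tie often and Efron is the more accurate approximation.
Wald 95 % CIs are exp(β ± 1.96 SE). A binary covariate whose events
all fall on one level has a monotone likelihood (the hazard ratio
diverges — e.g. a group with 0 events out of 21); this is detected and
signalled as non-convergence with a diagnostic rather than returning a
runaway estimate. Five-year DDFS is read off the KM step function at
t = 5.

All three estimators are verified against independent references in
the test suite (lifelines for KM/log-rank/Efron-Cox, statsmodels PHReg
for Breslow-Cox, plus a hand-worked product-limit table), and by
simulation: type-I error of the log-rank test calibrated to
0.05 ± 0.01 over 10⁴ null replicates, and Wald CI coverage ≥ 90 %
over 200 cohorts at n = 2000 with true HR 0.10.

The published per-patient survival times are not available, so the
published hazard ratios (≈ 0.09) cannot be reproduced exactly;
survival correctness is established by the parameter-recovery and
calibration properties above instead.

## Synthetic data

**Phantoms.** A phantom is a union of ellipsoidal lesion regions on a
regular grid, with per-subregion kinetic templates (SI_pre,
enhancement ratio, WI) that determine all three phase values exactly,
plus independent Gaussian noise per phase. Ground truth records the
maximal planted WI and whether a disc ROI fits entirely inside the
arg-max region. Because a disc averaging several templates yields a
WI strictly between the constituent WIs (a mediant bound, valid since
all SI_pre > 0), the planted maximum is an upper bound for the search,
attained exactly (to float precision) iff a pure disc fits — this is
what makes the `recoverable` flag and the 1e-6 noise-free recovery
test sound. With noise, the reported maximum over thousands of
placements carries the usual max-statistic upward bias, visible as a
~2–3 % overshoot at noise SD 2 % of SI_pre; tests budget for it
explicitly.

**Cohorts.** Patients are drawn as: RCB class from the study's
distribution (32.4 / 23.0 / 36.5 / 8.1 %); pCR = RCB-0; RCB index
uniform within the class's interval (cut-points 1.36 / 3.28); lesion
type mass/NME/mixed at 55:8:11. A latent "severity" flag marks 30 %
of residual-disease patients as high-risk. WI and enhancement-ratio
distributions are truncated normals conditional on (timepoint ×
group): the pCR group's WI collapses to ≈ 0 by the midpoint and goes
negative after treatment, plain RD stays intermediate, and severe RD
keeps high, strictly positive WI — reproducing the qualitative
separation the analysis is meant to detect. Curve labels are derived
from the sampled (ratio, WI) through the same thresholds as the
kinetics module, never sampled directly. Sizes shrink by group-
conditional factors, with a probability of complete radiological
disappearance for pCR patients. DDFS is exponential with one hazard
per imaging group at the midpoint — 0.0674/yr for RD-with-fast-washout
(five-year survival 71.4 %), 0.00674/yr for RD-other (≈ 96.7 %),
0.004/yr for CR on MRI — so the RD-other vs RD-fast hazard ratio is
0.10 by construction; censoring is uniform on 2–12 years,
approximating the study's observation window. The numerical WI/size
parameters are illustrative (the source figures print no numbers);
the class distribution, the five-year survival anchors and the hazard
ratio target are the quantities the generator is committed to.

Everything is reproducible bit-for-bit given (spec, seed); one global
seed fans out to per-component child streams via `SeedSequence` spawn
keys, so adding a generator never perturbs existing streams.

**What passing tests do not show.** The generator has no MRI physics
(no Rician noise, coil profiles, motion), no registration error
between phases or timepoints, no reader variability, and its
group-conditional distributions are stylised. Passing recovery tests
demonstrates the estimators and the pipeline are correct, not that
the clinical effect sizes would replicate in new patients.

## Problem sizes

The default verification runs use: 100 random phantoms ≤ 32³ voxels
for oracle equivalence; cohorts of n = 2000 (200 seeds) for Cox
recovery/coverage; 10⁴ two-group replicates (n = 100 per arm) for
log-rank calibration; n = 10⁵ for generator marginals. These sizes
give Monte-Carlo error comfortably below the tolerances asserted while
keeping a full run in tens of seconds.

## Known limitations

- Masks are inputs; no segmentation, registration or motion handling.
- Size and kinetics use the same mask per timepoint, whereas a
  clinical reading may measure size on a separate high-resolution
  contrast sequence.
- Only the binary fast-washout/other split is implemented, not the
  full BI-RADS curve taxonomy.
- Univariate Cox only (the motivating analysis had too few events for
  multivariate modelling); no competing risks.
- The RCB index itself is consumed as an input column, never computed
  from pathology measurements.
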