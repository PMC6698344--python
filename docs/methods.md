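# Methods

## Problem and model

`tbmscreen` implements a longitudinal tensor-based-morphometry analysis of
brain volume change.  For each subject pair of scans (reference,
follow-up) separated by an interval `dt` (years), the registration
displacement field `u(x)` yields a Jacobian-determinant map
`J(x) = det(I + ∂u/∂x)`: the local volume ratio of the deformation
(`J > 1` expansion, `J < 1` contraction).  Two analyses run on these
maps:

1. **Screening classifier.** Annualized change maps of cognitively
   unimpaired subjects are used to predict amyloid positivity (CSF
   amyloid-beta at or below 192 pg/mL — the cutoff separating the
   amyloid-negative controls, Ctrl, from preclinical AD, PreAD).  The
   estimator is ridge (L2) logistic regression on the top fraction of
   voxels ranked by a univariate F test, evaluated by a repeated,
   prevalence-fixed nested cross-validation.  The classifier's precision
   P and recall R feed a triage cost model.
2. **Signature maps.** Voxel-wise two-sample t contrasts between
   diagnostic groups (Ctrl, PreAD, and amyloid-positive MCI/AD) on
   age-residualized annualized maps, thresholded at uncorrected
   p < 0.005 with a cluster-extent filter k > 100 voxels, produce signed
   maps of regional atrophy/expansion.

## Annualization

Pairs with different `dt` enter one pooled analysis, which only makes
sense on a rate scale.  The default annualization is `log J / dt` — the
annual log-volume-change rate, for which "no change" is 0 regardless of
`dt`.  A `literal_divide` mode (`J / dt`) is kept for strict
reproduction of pipelines that divide the raw determinant; note it maps
"no change" to `1/dt` and should not be pooled across intervals.

## Age confound

Healthy aging changes brain volume too.  A per-voxel ordinary least
squares of the annualized rate on age (the mean of the pair's two visit
ages) is fitted on control maps only and can be subtracted from any map.
By default only the age-slope term is removed (`keep_mean = True`), so
maps stay on their natural scale; the intercept (the expected control
map at the mean control age) can be removed as well.  The statistical
maps always residualize; the classifier takes a boolean switch (default
off, i.e. raw annualized features), since either choice is defensible
and the pipeline supports both.  When the switch is on, the age model is
refitted inside every cross-validation repeat on training controls only,
so no information flows from held-out maps into training.

## Nested cross-validation with fixed test prevalence

Per repeat (default 100; the shipped study configurations use 20–30):

1. Subjects are split 80/20 into development and test sets; the test set
   is forced to a 20% positive-class prevalence (a realistic
   amyloid-positivity rate in middle-aged adults) by stratified sampling
   with down-sampling of the over-represented class.  Splitting is by
   subject: all maps of a subject stay on one side.  The training set
   keeps its natural post-split prevalence.
2. Voxels are ranked by the two-class F statistic computed on training
   maps only; a fixed fraction (default 0.5%) is kept (an l1-penalized
   embedded selector is available as an alternative mode).
3. The ridge strength C is tuned by a 3-fold, subject-level,
   class-stratified grid search (13 points, log-uniform on 1e-3..1e3)
   maximizing validation F1; ties go to the smallest C.
4. The model is refitted on the full training set (features z-scored
   with training statistics) and evaluated on the held-out maps: AUC by
   the rank statistic, and accuracy/precision/sensitivity/specificity/F1
   at the 0.5 probability threshold.

Metrics are summarized across repeats by mean, s.d. and either the
2.5/97.5 percentile interval (default) or the min–max range.  Evaluation
can be restricted to test maps with `dt` inside a window (for example
`dt > 2.5` years); repeats whose restricted test set has fewer than two
maps in either class are flagged invalid and excluded, and the count of
valid repeats is reported.

## Savings model

With prevalence `rho`, screening-MRI cost `C_MRI`, confirmatory-test
cost `C_PET` (CSF and PET treated as one parameter) and average standard
screening cost `C_avg`:

    savings_cost  = 1 − (rho·C_PET/P + C_MRI/R) / (2·C_avg)
    savings_tests = 1 − rho / P

Defaults: `C_MRI = 700`, `C_PET = 3000`, `C_avg = (700+3000)/2 = 1850`
cost units.  Both quantities can be negative (a bad classifier costs
more than no triage).  The precision–recall savings surface is evaluated
on an open grid `P, R ∈ (0, 1]` with marching-squares iso-contours.

## Statistical maps

Pooled-variance two-sample t per voxel (Welch optional), one-sided in
both directions so volume decreases and increases are reported
separately.  Voxels with zero pooled variance get t = 0 and a degeneracy
flag.  Supra-threshold voxels (p < 0.005, default) are grouped into
connected components (18-connectivity default; 6 and 26 available) and
components with at most k = 100 voxels are discarded — "k > 100" is a
strict inequality.  There is deliberately no family-wise or FDR
correction; the extent filter is the only multiplicity guard.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
on a 32×38×32 grid of 2 mm isotropic voxels holding a toy brain with
seven regions (ventricles, caudate heads adjacent to the ventricular
walls, parahippocampal/fusiform, middle temporal, posterior
cingulate/precuneus, basal ganglia, remaining gray matter).  Per visit
pair the raw log-Jacobian is

    dt · (rate[group, region] + aging_slope[region] · (mean_age − 74))
    + N(0, scan_noise_sd)  per voxel,   then Gaussian smoothing.

Default study conditions (all configurable):

- **Cohort**: 30 Ctrl, 18 PreAD, 12 MCI/AD subjects (the cognitively
  unimpaired subset is ~37% amyloid positive, matching the imbalance of
  the cohort the analysis is designed for, at desk scale); baseline ages
  truncated-normal N(74, 6²) on [55, 90]; 2–4 visits per subject
  (probabilities 0.35/0.40/0.25); consecutive-visit pairs.
- **Intervals**: `dt` lognormal with median 2.0 y, log-s.d. 0.55,
  truncated at 0.5 y (visits at least six months apart).  This gives
  mean ≈ 2.3 y and s.d. ≈ 1.4 y, a realistic longitudinal follow-up
  spread, with about a third of pairs beyond 2.5 y.
- **CSF amyloid-beta**: Ctrl truncated-normal N(230, 25²) above the
  192 pg/mL cutoff; PreAD and MCI/AD N(150, 25²) at or below it.  These
  are plumbing choices that place values plausibly around the cutoff.
- **Effects** (annual log-volume rates; calibration choices of this
  package, not measured values): PreAD −1.0%/y parahippocampal/fusiform,
  −0.4%/y middle temporal, +2.0%/y ventricles; MCI/AD −2.5%/y
  parahippocampal/fusiform, −1.5%/y middle temporal and posterior
  cingulate/precuneus, −1.0%/y basal ganglia, +4.5%/y ventricles.
  Aging slopes: +4e-4 (ventricles) and −1.5e-4 (gray matter) per year of
  age.
- **Noise**: `scan_noise_sd = 0.30` on the raw (pre-annualization)
  log-Jacobian, independent of `dt`.  This is the load-bearing choice:
  after annualization the noise scales as `1/dt`, so pairs with longer
  intervals carry more signal per unit noise, and restricting evaluation
  to `dt > 2.5` y raises the AUC.  A control mode
  (`noise_stage="annualized"`) scales the noise with `dt` instead,
  making the per-map SNR flat in `dt`; the AUC curve then flattens.
- **Smoothing**: 8 mm FWHM Gaussian.  Smoothing both suppresses voxel
  noise and spreads the implanted effects beyond their nominal region
  boundaries.  One consequence is reproduced deliberately: the strong
  ventricular expansion bleeds into the adjacent caudate head, which
  then appears as spurious "expansion" in the statistical maps when
  smoothing is on and disappears when it is off.

Two output modes: `map` (emit log-Jacobian volumes directly; fast,
default) and `field` (solve the potential-flow problem ∇²φ = dt·target
spectrally on the periodic grid and emit `u = ∇φ`, so the morphometry
module's Jacobian operator is exercised end to end; for small amplitudes
`log det(I + ∇u) ≈ div u = target` to second order).  A constant nonzero
target divergence is incompatible with periodic boundaries and its mean
is removed with a warning.

Determinism: per-map random streams are derived from the master seed by
a counter-based spawn scheme, so the same seed reproduces the dataset
byte for byte and any single map can be regenerated independently.

### Calibration choices and what they show

The defaults were calibrated once so the end-to-end classifier sits in a
realistic regime (unrestricted mean AUC ≈ 0.6–0.75, long-interval AUC
≈ 0.8–0.9 across dataset seeds) rather than at ceiling.  In this regime
the per-voxel group difference (Cohen's d ≈ 0.2–0.5 per voxel) is far
below what single-voxel t tests need for reliable detection — the
classifier succeeds by aggregating thousands of voxels, exactly the
situation the method is designed for.  Voxel-level *recovery* checks of
the statistical maps therefore use a dedicated recovery calibration:
the same effect rates with `scan_noise_sd = 0.02`, under which ≥ 95% of
implanted atrophy voxels survive p < 0.005, k > 100.  The null
calibration (no implanted effects, default noise) and the
selection-frequency concentration check run at the defaults.

Selection-frequency concentration is measured against the *smoothed*
effect support — voxels where the smoothed implanted rate field exceeds
5% of its peak magnitude — because smoothing genuinely relocates part of
the effect into a halo around the nominal regions, and the F-filter
rightly selects halo voxels (the same mechanism that produces the
caudate spillover).

### What the simulator does not model

i.i.d. Gaussian voxel noise has no spatial correlation before smoothing
and no between-subject biological variability (in real cohorts, rate
heterogeneity across subjects is spatially structured and does not
average away over voxels, which is what keeps real AUCs below ceiling at
moderate scan noise).  There are no registration errors, no scanner or
site effects, no T1 intensities, and the "anatomy" is a box-and-ellipsoid
cartoon.  Passing tests therefore demonstrate the correctness and the
qualitative mechanisms of the pipeline (interval dependence, spillover,
leakage hygiene, prevalence forcing), not clinical performance on real
data.

## Numerical choices

- Displacement gradients: central differences in mm, one-sided at the
  lattice edges (`replicate`) or wrapped (`periodic`); non-positive
  determinants are counted and reported, never clipped silently.
- Gaussian smoothing uses `sigma = fwhm / sqrt(8 ln 2)` per axis with
  edge replication; a zero FWHM is the identity.
- F-test ranking breaks ties (including zero-variance columns, whose F
  is defined as 0) by ascending column index, so rankings are
  deterministic.
- Fraction-to-count conversion rounds half away from zero with a floor
  of one feature.
- Ridge logistic: features z-scored with training statistics
  (zero-variance columns get unit scale), scikit-learn L-BFGS solver at
  tolerance 1e-6; the objective is the sum of logistic losses plus
  `||w||²/(2C)` with an unpenalized intercept.
- Precision with zero predicted positives is defined as 0 with a
  warning; AUC uses midranks on ties.
- Degenerate (zero-variance) voxels in t maps get t = 0, one-sided
  p = 0.5, and a flag.
- `dt` windows are open intervals on both sides, matching the
  strictly-between convention used for the evaluation subset.

## Problem sizes

The shipped study configurations use a ~60-subject cohort (~100 maps) on
the 32×38×32 grid, 20–30 cross-validation repeats, and 50–100 null
simulations; these sizes were chosen as the package's desk-scale study
conditions.  Larger cohorts, more repeats and finer grids are plain
configuration changes.

## Known limitations

- With 18 positive subjects and a 20%-prevalence test set of ~10
  subjects, each repeat's test set holds only two positive subjects;
  per-repeat metrics are coarse and cross-repeat intervals are wide (as
  they are in comparably sized real studies).  Interval-restricted
  evaluations can drop repeats entirely.
- The `literal_divide` annualization is provided for fidelity but is
  statistically inappropriate for pooling across intervals.
- The savings model assumes the classifier screens everyone with MRI and
  sends predicted positives to the confirmatory test; it does not model
  recruitment dynamics or capacity constraints.
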