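# Methods

## Sample entropy

SampEn(m, r, tau) of a series x_1..x_N: the series is first coarse-grained
into nonoverlapping block means of length tau (tau = 1 leaves it unchanged,
and is the default — multiscale curves are out of scope). With
r = r_frac x SD (sample SD, n-1 denominator, of the coarse-grained series
itself), B counts pairs i < j of m-length templates whose Chebyshev
distance is <= r, A the same for (m+1)-length templates, both over the
same N - m starting positions; SampEn = -ln(A/B).

Conventions chosen where the estimator leaves room:

* **Per-series tolerance.** r is computed from each voxel's own series, the
  standard convention in the entropy literature; it makes the estimate
  exactly invariant to affine rescaling of the signal (tested to 1e-9).
* **Constant series -> 0.** In the r -> 0+ limit all template distances are
  zero, so A = B and SampEn = 0.
* **Undefined values.** If no template pair matches at either length the
  estimate is undefined (NaN); such voxels are excluded from regional means
  and counted per region (`n_voxels_dropped`).
* **m from the shortest epoch.** `select_m` returns the largest m with
  10^m strictly below the shortest series length; 77 samples admit m = 1.
  Defaults m = 1, r_frac = 0.15, tau = 1.
* **Aggregation.** Region value = arithmetic mean of defined voxel values;
  whole brain = unweighted mean of the regional means (a voxel-weighted
  variant is available by flag). The unweighted choice keeps small
  subcortical regions from being swamped by large cortical ones.

The counting kernel is O(N^2) per voxel, numba-compiled with an equivalent
numpy fallback; both are verified count-exactly against a pure-Python loop
oracle on random short series. Two analytic anchors are tested: for long
i.i.d. Gaussian series with m = 1, SampEn converges to
-ln(2 Phi(0.15/sqrt(2)) - 1) ~= 2.4714 (the increment pair-match
probability), and mean SampEn of AR(1) series decreases monotonically in
the lag-one coefficient phi (measured slope ~= -0.44 per unit phi over
phi in [0.2, 0.5] at N = 300).

## Age windows, outliers, group tests

Windows start at lo = 6, 7, ..., 26 with width 5 (21 windows); membership
uses the half-open rule lo <= age < lo + 5 on continuous age, so the
"26 to 30" label admits ages up to (but excluding) 31 — this reconciles
integer window labels with fractional ages at the cohort boundary. A
subject in the interior belongs to exactly width/step = 5 windows.

Rosner's generalized ESD test screens each (window x group x target) cell:
max_k defaults to max(1, ceil(0.1 n)) with alpha = 0.05 (both
configurable and logged); cells smaller than max_k + 3 are tabulated
unscreened. Cells with n = 1 report SD 0 and missing SEM and never enter a
test. The group test is the pooled-variance Student t-test (Welch by
configuration); the KS normality statistic is recorded for reporting only,
since the parametric test is applied throughout. Bonferroni levels are
exact quotients: 0.05/5 = 0.01 for the whole-brain trajectory (five
overlapping windows re-use each year of age), 0.05/450 = 1.111e-4 at the
region level, 0.05/n_predictors for the regression.

## Differential curves and clustering

The differential curve of a target is (case mean - control mean) per
window, missing (never zero-imputed) wherever either group mean is
missing. Clustering uses Euclidean distances between complete region
curves — rows with any missing window are excluded with a logged list, and
the pipeline first drops windows with no data in either group — followed
by complete-linkage agglomeration (scipy), whose merge heights are
guaranteed monotone. The cluster count is the Calinski-Harabasz maximum
over k = 2..6 (smallest k on ties; singleton-only or zero-dispersion
clusterings are reported as infinite and flagged). Dendrogram leaf order
is the deterministic display permutation for heatmap export; a rank-2
ellipse seriation of the association matrix is deliberately not
reimplemented, as the partition itself depends only on the
distance/linkage choices, which are implemented exactly. The t-test
between two clusters' mean trendlines is offered both paired-by-window
(primary: the two curves share their windows) and unpaired; the pipeline
logs both.

## Behavioral association

VIF_j = 1/(1 - R^2_j) from regressing predictor j on the remaining
candidates (with intercept); predictors exceeding the threshold
(default 10) are dropped worst-first, exactly collinear ones first with
infinite VIF, and the full trace is exported for audit. The regression of
each behavioral score on the surviving regional entropies plus age and sex
(coded male = 0, female = 1) is complete-case per response.

Point estimates, R^2, F, and the model p come from the full-sample OLS
fit. Uncertainty comes from 1000 bootstrap refits, each drawing
floor(0.85 n) subjects **with replacement**; per-predictor bootstrap p =
2 min(P(beta* <= 0), P(beta* >= 0)), floored at 1/n_boot, with percentile
95% CIs; the full-sample OLS p-values are reported alongside. Drawing the
85%-sized resample with replacement was a deliberate design choice: a
without-replacement 85% subsample concentrates the resampled coefficients
at ~0.42 x SE around the full-sample estimate, so sign-fraction p-values
would be badly anti-conservative (type-I ~ 0.28 at a nominal 0.01); with
replacement the spread is ~1.08 x SE and the test is calibrated, measured
at ~0.005 rejections at the corrected 0.01 level over 500 null
simulations. Without-replacement subsampling remains available
(`RegressionSpec(replace=False)`) for sensitivity analyses. Singular
resamples are skipped and counted, with a warning above 10%.

## Synthetic cohorts

The generator produces the minimal data with the statistical structure the
analysis assumes — it emulates *irregularity structure*, not fMRI physics
(no drift, motion, physiological noise, or hemodynamic model):

* **Parcellation:** contiguous flat-order blocks on a small grid
  (default 9 x 9 x 10 = 810 voxels, 9 per region), with the packaged AAL-90
  names when n_regions = 90.
* **Voxel signal:** standardized AR(1), x_t = phi x_{t-1} + eps_t, the
  minimal stationary process with one irregularity knob; higher phi =
  smoother signal = lower SampEn (the planted monotone link, verified over
  replicates).
* **Templates:** controls follow phi falling linearly 0.45 -> 0.25 from age
  6 to 30 (entropy rising through development). Cases add
  amplitude x (0.4 - exp(-(age - 14)^2 / (2 x 3^2))): an entropy deficit in
  childhood and adulthood and an excess peaking at age 14. Two region
  families plant a two-cluster structure: a gentle "subcortical-like"
  family (cingulate, hippocampal/parahippocampal, parietal, paracentral,
  basal ganglia, thalamus ids) and a steeper "cortical-like" family
  covering the rest. Default amplitudes (0.02 / 0.05 in phi) put the
  case-control gap on the order of 0.01 nats.
* **Cohort:** balanced groups, ages uniform on [6, 30], sex 85% male
  (mirroring typical case cohorts), series length >= 77 (default 120).
* **Behavioral scores:** a known linear model on regional entropy, age,
  and sex plus Gaussian noise, so regression recovery is checkable against
  ground truth.
* **Determinism:** every quantity is a pure function of the root seed;
  subject volumes use `default_rng([seed, subject_index])` substreams so
  any single subject can be regenerated.

What passing tests on these cohorts shows: the pipeline's statistics do
what they claim on data satisfying their assumptions (stationary voxel
noise, within-cell normality, linear score model). What they cannot show:
robustness to scanner/site effects, motion artifacts, non-stationarity, or
violations of the linear behavioral model in real cohorts.

## The planted end-to-end study

`planted_study_config` fixes the study conditions for the full-pipeline
recovery checks: 240 subjects/group, series length 300, template
amplitudes 0.01 (gentle) / 0.18 (steep). These were set by a power
analysis before the recovery assertions were written: per-voxel SampEn
sampling noise was measured at SD ~= 0.062 (N = 300), giving ~0.021 per
subject-region over 9 voxels and ~0.006 per differential cell at ~25
subjects/group/window; because overlapping windows share subjects, a
curve's 21 cells carry ~8 effective degrees of freedom, so within-cluster
curve distances are heavy-tailed and the between-family separation must
clear them severalfold. The chosen amplitudes put the planted peak gap at
~0.05 nats — deliberately above the ~0.01-0.02 nats scale of the default
generator, because a desk-scale region (9 voxels) carries roughly an
order of magnitude more sampling noise than a full-resolution atlas
region; the *recovery margin*, not the raw effect, is what is matched.
Under these conditions the pipeline recovers the planted sign pattern, the
two region families exactly (ARI = 1), k = 2 from the CH scan, and every
behavioral beta within 3 bootstrap SEs, verified across several seeds
(~90 s per run on one CPU).

## Numerical and degenerate-input conventions

* SDs use the n-1 denominator throughout, fixed for bit-reproducibility.
* GESD stops early on a zero-variance remainder and returns the outliers
  confirmed so far; constant cells yield no outliers.
* t-tests are skipped (with a debug log) when a group has n < 2 or both
  variances vanish with unequal means; identical degenerate samples return
  t = 0, p = 1.
* Correlation rows with zero variance yield missing entries, flagged.
* Bootstrap p-values are floored at 1/n_boot; singular resamples are
  skipped and counted.
* All TSV exports use a stable column order and `%.10g` floats; re-running
  a configuration with the same seed reproduces every table byte-for-byte.

## Known limitations

* Preprocessing (motion correction, registration, nuisance regression,
  gray-matter masking) is upstream; the default mask is merely
  "finite, nonzero temporal variance".
* The design is cross-sectional; no within-subject or mixed-effects
  modeling, and no site/protocol covariates.
* The synthetic AR(1) model cannot probe sensitivity to hemodynamic
  autocorrelation structure beyond lag one.
* Entropy bias correction beyond the parameter choice (m = 1 for short
  epochs) is not applied.
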