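# braintraj

Developmental trajectories of resting-state fMRI brain complexity, measured
by sample entropy, in a cross-sectional case/control cohort.

The package is built for the question: *how does the irregularity of
spontaneous BOLD activity change from childhood (age 6) to young adulthood
(age 30), and where do cases deviate from controls?* It implements the full
analysis chain on top of standard neuroimaging inputs (4D NIfTI BOLD volumes,
an integer-label parcellation, a phenotype table), and ships a seeded
synthetic-cohort generator so the entire chain is testable end to end
without any imaging data.

## The measures and models

**Sample entropy.** For a voxel time series of length N, embedding dimension
m, and tolerance r,

    SampEn = -ln(A / B)

where B counts pairs of distinct m-length templates with Chebyshev distance
<= r, A counts the same for (m+1)-length templates, and self-matches are
excluded. r = 0.15 x SD of the (coarse-grained) series; with the
coarse-graining scale 1 and m = 1 the defaults suit series as short as 77
samples, since m must satisfy 10^m < N. Lower SampEn = more repetitive
signal. Voxel values are averaged within each of the 90 AAL regions (odd
ids left, even right; the region table is packaged), and the whole-brain
summary is the unweighted mean of the regional means.

**Trajectories.** Subjects are assigned to overlapping 5-year age windows
advancing by 1 year ("6 to 10" ... "26 to 30", 21 windows; membership is
lo <= age < lo+5). Within each (window x group x region) cell, Rosner's
generalized ESD test removes up to ceil(0.1 n) outliers at alpha = 0.05,
then mean/SD/SEM/n are tabulated. Group differences use pooled-variance
t-tests at a Bonferroni-corrected level (0.05 / 5 = 0.01 for the
whole-brain trajectory, 0.05 / 450 for 90 regions). A one-sample KS check
against a fitted normal is recorded per cell but never gates the t-test.

**Differential-curve clustering.** Each region's curve of (case mean -
control mean) across windows is clustered with Euclidean distance and
complete linkage; the cluster count comes from a Calinski-Harabasz scan
over k = 2..6, and dendrogram leaf order provides the heatmap permutation.

**Behavioral association.** Candidate regional entropies are screened by
variance inflation factor (threshold 10, iterative worst-first dropping);
survivors plus age and sex enter

    score = b0 + sum_r b_r * SampEn_r + b_age * age + b_sex * sex + eps

fitted by OLS with 1000 bootstrap refits, each drawing floor(0.85 n)
subjects with replacement; per-predictor significance is Bonferroni-corrected
by the predictor count (5 predictors -> 0.01).

## Worked example

The numbered scripts under `analysis/` run the planted synthetic study
(240 subjects/group, 300-sample series, adolescent-peak case offset, two
region families):

```
python analysis/01_simulate_profiles.py --seed 1
python analysis/02_trajectories.py
python analysis/03_cluster_regions.py
python analysis/04_behavior_regression.py --seed 1
```

Output from seed 1 (abridged):

```
whole-brain differential: first window -0.0100, peak +0.0254 at window 6, adult mean -0.0174 nats
CH scan: {2: 418.4, 3: 242.4, 4: 178.7, 5: 138.0, 6: 114.8} -> k = 2
adjusted Rand index vs. planted region families: 1.000
cluster 1 (64 regions): peak +0.0350 at window 6.0, trough -0.0254 at window 17.0
cluster 2 (26 regions): peak +0.0021 at window 6.0, trough -0.0034 at window 15.0
paired t-test between cluster trendlines: t = -0.49, p = 0.63
VIF screen: 3/3 regional predictors survive (max VIF 1.83, threshold 10)
model: n = 480, R^2 = 0.913, F = 996.0, p = 8.7e-249, per-predictor alpha = 0.01
        age: beta   -0.484  boot SE 0.009  ...  (planted -0.5)
```

Reading: the case group's whole-brain complexity runs below controls in the
earliest window (-0.010 nats), above controls around the planted adolescent
peak (+0.025 nats at window 6, ages 11-15), and below again in adulthood
(-0.017 nats); the Calinski-Harabasz scan picks exactly two region
clusters, which match the planted steep/gentle region families perfectly
(ARI 1.0); and the bootstrap regression recovers every planted behavioral
coefficient within its confidence band. The same steps accept real NIfTI +
phenotype inputs through `braintraj run-all --config <yaml>` (see
`braintraj --help`).

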