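# Methods

## Normative tangent-space model

Connectivity is estimated per subject as the Pearson correlation of the
region time series, shrunk toward the identity, C' = (1−λ)C + λI. The
shrinkage λ (default 0.05) exists to keep C' symmetric positive definite
when T is modest relative to R (clinical resting-state scans of ~128 volumes
against 45 regions); it biases every correlation toward zero by the same
factor, which the normative ranges absorb because patients and reference
subjects are shrunk identically.

The reference point of the tangent space is the affine-invariant Fréchet
(Karcher) mean of the reference cohort, computed by the standard fixed-point
iteration M ← M^{1/2} exp(mean_i log(M^{−1/2} C_i M^{−1/2})) M^{1/2},
initialized at the log-Euclidean mean and stopped when the Frobenius norm of
the mean tangent drops below 1e−6 (at most 100 iterations; non-convergence
is an error, not a silent fallback). All matrix logs, exponentials and square
roots use symmetric eigendecompositions. The affine-invariant metric is the
conventional choice for "tangent-space connectivity"; the construction is
congruence-equivariant, so a common linear mixing of regions does not change
the geometry of the cohort.

Normative per-pair ranges are the sample mean μ_ij and SD σ_ij (denominator
n−1) of the tangent values across the reference cohort. Ranges are computed
on tangent values rather than raw correlations: the tangent space is where
deviations from the reference are additive and approximately Gaussian, so a
per-pair z-score is meaningful there. A patient's pair is labeled
hyperconnected when z_ij > +3 strictly, hypoconnected when z_ij < −3
strictly, and normal otherwise — the ±3 boundary itself counts as within
range. The threshold (default 3) is configurable; raising it can only
shrink the anomaly set.

**Variance mask.** The ⌈P/3⌉ pairs with the largest normative σ_ij
(P = R(R−1)/2; ties broken by row-major pair order so the mask is
deterministic) are excluded from scoring. These pairs vary most across
healthy subjects, so a fixed-σ threshold on them is the most prone to false
discovery. At R = 45 this masks exactly 330 of 990 pairs. A cohort with zero
tangent variance on an unmasked pair is degenerate and rejected.

**Anomaly counts.** Each unmasked anomalous pair increments the incident
count of both endpoint regions, per direction (hypo/hyper). Regions are
stratified by laterality relative to the lesioned hemisphere (ipsilesional /
contralesional; midline regions form their own stratum) and by class
(cortical / subcortical). Because "number of anomalous parcels" is ambiguous
between incident-pair counts and touched-region counts, both are produced:
`total()` sums incident pairs, `parcel_flag_count()` counts regions touched
by at least one anomaly. Reports default to incident counts.

## Trajectory clustering

Features are the raw 4-timepoint score vectors of one scale, unstandardized
— all four entries share that scale's units, so standardization would only
distort the trajectory shape. Distances are Euclidean; linkage is Ward by
default (the natural companion of Euclidean distances), with `average` and
`complete` selectable since the original analytic choice is not documented.
K is selected by the mean silhouette coefficient over tree cuts at
K = 2..min(10, n−1) (small cohorts of ~22 patients make larger K degenerate
fits of 1–2 patients per cluster); ties go to the smallest K. Singleton
clusters contribute silhouette 0 by the usual convention. Scales are
clustered separately — pooling heterogeneous scales into one feature space
produces exactly the degenerate many-singleton solutions the K cap guards
against. The procedure contains no randomness.

## Statistical battery

* **Friedman test** with average ranks within rows and the tie-corrected
  statistic χ²_F = (k−1)·Σ_j (R_j − n(k+1)/2)² / (A − C). The p-value is
  asymptotic (χ², k−1 df) or exact by full enumeration of the (k!)^n
  within-row rank permutations; `method="auto"` switches to exact when the
  enumeration has at most 50 000 configurations. Exact mode exists because
  the χ² approximation is visibly off at the tiny repeated-measures sizes
  this battery targets (at n = 4, k = 3 the two can disagree by ~0.1).
  Kendall's W = χ²_F/(n(k−1)) is the effect size in both modes.
* **Dunn post hocs** after Friedman use z = (R̄_a − R̄_b)/√(k(k+1)/(6n));
  after Kruskal–Wallis, pooled-rank z-tests with the tie-corrected variance.
  All post hoc p-values are Bonferroni-multiplied by the pair count and
  capped at 1.
* **Two-group continuous comparisons** gate on Shapiro–Wilk normality of
  both groups and a two-sided variance-ratio F-test, all at α (default
  0.05): all gates passed → unpaired equal-variance t-test, otherwise
  Wilcoxon rank-sum (normal approximation with tie correction). Groups
  smaller than 3 skip the gate and use the rank-sum test. Constant samples
  are treated as failing normality. Every result carries its gating trace.
* **Categorical associations** use Fisher's exact test when any expected
  cell is below 5 (2×2 tables), Yates-corrected chi-square otherwise; r×c
  tables use the uncorrected chi-square, with a recorded warning when
  expected counts are low (no exact r×c network algorithm is implemented).
* Per-region cluster comparisons of anomaly counts use Kruskal–Wallis +
  Dunn, consistent with the nonparametric treatment of small samples
  elsewhere in the battery; both raw and Bonferroni-adjusted p-values are
  reported rather than guessing a single correction policy.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
raw imaging:

* **Normative BOLD**: subject covariance Σ_s ~ Wishart(κ, Σ₀/κ) around a
  base correlation Σ₀ (random low-rank-factor correlation, optional
  motor-community block), then T iid zero-mean Gaussian samples renormalized
  to unit variance per region. κ (default 100) is mean-preserving dispersion:
  smaller κ means more inter-subject variability, which is what makes the
  highest-variance-third mask non-degenerate. Draws require κ ≥ R.
* **Patients**: a jittered subject covariance is perturbed *in tangent space
  at Σ₀* by ±magnitude × normative σ_ij at each planted pair and mapped back
  through the exponential, which preserves positive-definiteness by
  construction. Magnitudes are therefore in the same units as the detection
  threshold. Planted ground truth is returned as a symmetric anomaly matrix.
  When a fitted model's σ is available it should be supplied (`spec.pair_sd`);
  otherwise the generator calibrates one internally from a 60-subject
  simulated reference.
* **Trajectories**: subject vectors are cluster mean + iid Gaussian noise,
  clipped to scale bounds and rounded to integers, mimicking integer clinical
  scores. The default specs are study-sized: 22 subjects per scale with the
  per-scale cluster counts and sizes of the motivating cohort (NIHSS
  6 clusters of 4/3/8/4/2/1, FMA 2 of 18/4, BI 5 of 2/5/6/3/6, WMFT 2 of
  16/6), cluster-mean baselines placed so cohort baseline means approximate
  the reported averages (NIHSS ≈ 11, FMA ≈ 16.5, BI ≈ 9, WMFT ≈ 12), and
  noise SDs of 1–2 points.
* **Structural ratings**: integrity and proximity are drawn from
  cluster-conditional categorical distributions; association strength 0
  gives identical distributions in every cluster, strength 1 with the
  deterministic map gives ratings constant within cluster.

What the generator does **not** emulate: temporal autocorrelation of BOLD
(the analysis consumes only covariance and no temporal model is specified),
physiological noise, head motion, scanner effects, lesion-induced signal
dropout, or correlations between a patient's connectivity anomalies and
their trajectory cluster (the pipeline's cluster-comparison stage is
exercised on ratings with a planted association instead). Passing tests
therefore demonstrate the correctness and calibration of the estimators on
data satisfying their assumptions, not robustness to real-data artifacts.

## Calibration and recovery experiments (problem sizes)

* Null anomaly rate: R = 10, T = 400, 200 reference subjects, 50
  pseudo-patients drawn from the same generator; the flagged fraction of
  unmasked pairs is compared with the analytic Gaussian rate
  2Φ(−3) ≈ 0.27%. Observed rates sit between ~0.1% and 0.5%: finite-T
  estimation noise and the t-like tails of estimated z-scores move the rate
  around the analytic value without leaving that band.
* Planted recovery: R = 20, T = 400, 200 reference subjects, 8 planted
  pairs per patient (4 hyper, 4 hypo) at ±6 normative SDs, planted on
  unmasked pairs (masked pairs are excluded from scoring by construction, so
  planting there would measure the mask, not the detector), aggregated over
  20 seeds.
* Trajectory recovery: K = 5 planted clusters, 30 subjects, consecutive
  means separated by 8× the noise SD, 100 seeds; success = correct K and
  ARI = 1.
* Type-I calibration: 2000 null replicates at the study's shapes (Friedman
  n = 22, k = 4; Kruskal–Wallis 3 groups of 8).
* Pipeline determinism: a 10-region, 20-reference, 6-patient synthetic study
  run twice with the same config and seed, compared byte-for-byte.

## Design choices and limitations

* **FMA bounds.** Published FMA totals differ between the full battery and
  motor subscales; the scale maximum defaults to 226 and is configurable
  (`default_scales(fma_max=...)`). Cohorts scored on a motor subscale should
  set it accordingly.
* **Session duration convention.** Per-train active time is
  pulses/frequency (bursts/burst-rate for theta burst); the inter-train
  interval is counted after every train including the last, and the total is
  floored to whole minutes. This is the one convention consistent with all
  three standard protocols' printed durations (3, 18, 20 min).
* **Quantiles** in cohort summaries are linear-interpolation (type-7)
  quartiles; percentages are of nonmissing values, rounded to the nearest
  integer.
* **Missing scores.** Subjects lacking any of the four timepoints are
  flagged and excluded from clustering for that scale; no imputation.
* **Region set.** The 45-label default (13 motor-network cortical parcels ×
  2 hemispheres, 9 subcortical structures × 2, midline brainstem) is a
  documented synthetic stand-in; real analyses should supply their own
  parcel list, which is plain configuration.
* Whether normative ranges should be computed on tangent values or raw
  correlations is not externally fixed; tangent values are used because the
  3-sigma rule presupposes an additive, symmetric deviation scale. The
  same applies to the unstated linkage criterion (Ward chosen, others
  selectable) and feature standardization (off).
* The Karcher mean is fitted on the reference cohort only; patients do not
  influence the reference, so the model is a true normative standard.
* The exact Friedman mode is exponential in n and capped; it is meant for
  the tiny repeated-measures designs where the asymptotic test is least
  trustworthy.
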