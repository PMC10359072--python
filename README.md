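# conntraj

Connectomic analysis of stroke recovery after repetitive TMS: normative
tangent-space functional-connectivity anomaly detection, recovery-trajectory
phenotyping by hierarchical clustering, and the nonparametric statistics to
compare connectivity features across recovery phenotypes.

The package is aimed at researchers who have (a) region-averaged BOLD time
series for a motor-network / subcortical parcel set, for patients and for a
healthy reference cohort, and (b) standardized stroke-scale scores (NIHSS,
FMA, BI, WMFT) at four timepoints: admission baseline and 1, 30 and 90 days
after treatment. Because such clinical datasets are rarely shareable, a
first-class synthetic-data module generates study-sized cohorts with planted
ground truth so the entire pipeline can be exercised and validated offline.

## Method

**Anomaly matrices.** Each subject's connectivity is the shrunk Pearson
correlation C of its region time series, C' = (1−λ)C + λI (λ = 0.05 by
default, guaranteeing a symmetric positive-definite matrix when the scan is
short). A normative cohort defines a reference point M — the affine-invariant
Fréchet (Karcher) mean on the SPD manifold — and each matrix is mapped to the
tangent space at M:

    t(C) = logm(M^{-1/2} C M^{-1/2}).

Per-pair normative means μ_ij and SDs σ_ij are estimated across the
reference cohort in tangent space. A patient pair with tangent z-score
z_ij = (t_ij − μ_ij)/σ_ij above +3 is *hyperconnected*, below −3
*hypoconnected*, otherwise normal; the highest-variance third of pairs
(⌈P/3⌉ of P = R(R−1)/2) is excluded up front to limit false discoveries.
Region-level counts of incident anomalous pairs are stratified by lesion
laterality (ipsilesional / contralesional) and region class
(cortical / subcortical).

**Trajectory phenotypes.** Per scale, each patient's raw 4-timepoint score
vector is clustered by agglomerative hierarchical clustering (Ward linkage on
Euclidean distances by default); the number of clusters K is selected by the
mean silhouette coefficient over tree cuts at K = 2..min(10, n−1), ties going
to the smallest K.

**Statistics.** Longitudinal change: Friedman's test (tie-corrected, with an
exact permutation mode for tiny samples), Kendall's W = χ²_F/(n(k−1)), and
Dunn's pairwise post hocs with Bonferroni correction. Between clusters:
Kruskal–Wallis plus Dunn for anomaly counts and structural ratings; gated
t-test / Wilcoxon rank-sum (Shapiro–Wilk + variance F-test gate) for
continuous demographics; Yates-corrected chi-square or Fisher's exact for
categorical tables, gated on expected counts.

## Worked example

```python
import numpy as np
from conntraj import (GroundTruthSpec, simulate_normative_cohort, estimate_connectivity,
                      fit_normative, score_anomalies, count_anomalies, simulate_patient,
                      cluster_trajectories, simulate_trajectories, SCALES)
from conntraj.stats import friedman_test
from conntraj.connectivity import pair_index

# normative model from a synthetic healthy cohort (R=20 regions)
spec = GroundTruthSpec(n_regions=20, seed=42)
rng = np.random.default_rng(42)
cohort = simulate_normative_cohort(spec, n_subjects=100, T=200, rng=rng)
model = fit_normative([estimate_connectivity(ts) for ts in cohort],
                      region_labels=spec.region_labels)

# one patient with two planted 6-SD anomalies
spec.pair_sd = model.pair_sd
rows, cols = pair_index(20)
free = np.flatnonzero(~model.variance_mask[rows, cols])
spec.planted_anomalies = [(int(rows[free[0]]), int(cols[free[0]]), "hyper", 6.0),
                          (int(rows[free[5]]), int(cols[free[5]]), "hypo", 6.0)]
ts, truth = simulate_patient(spec, "right", T=200, rng=rng, subject_id="pat001")
am = score_anomalies(estimate_connectivity(ts), model)
for i, j, d in am.anomalous_pairs():
    print(f"  {d:5s}  {model.region_labels[i]} -- {model.region_labels[j]}  "
          f"z={am.z_values[i, j]:+.1f}")
counts = count_anomalies(am, lesion_side="right")
print("ipsilesional hypo incident count:", counts.total("hypo", laterality="ipsilesional"))

# recovery-trajectory phenotypes on the Barthel Index
table, labels = simulate_trajectories(spec, SCALES["BI"], rng=rng)
wide = table.wide("BI")
sol = cluster_trajectories(wide, scale="BI")
print(f"BI: K={sol.k_selected}, "
      f"silhouette={sol.silhouette_by_k[sol.k_selected]:.2f}, n={len(wide)}")
fr = friedman_test(wide, method="asymptotic")
print(f"Friedman chi2={fr.statistic:.2f}, p={fr.p_value:.3g}, W={fr.kendalls_w:.2f}")
```

Output:

```
  hyper  L:cortical:M1 -- R:cortical:M1  z=+4.1
  hypo   L:cortical:M1 -- R:cortical:preSMA  z=-5.4
  hypo   L:cortical:preSMA -- R:cortical:PMv  z=-3.1
  hypo   R:cortical:CingulateMotor -- R:cortical:Area55b  z=-3.2
ipsilesional hypo incident count: 4
BI: K=3, silhouette=0.79, n=22
Friedman chi2=13.65, p=0.00342, W=0.21
```

Both planted anomalies are recovered (z = +4.1 and −5.4); the two extra
hypo flags at z ≈ −3.1 are borderline false positives, consistent with the
~0.3% per-pair false-positive rate a 3-SD threshold implies. The 22 synthetic
Barthel trajectories split into K = 3 phenotypes with a mean silhouette of
0.79, and the cohort-level improvement across the four timepoints is
significant (Friedman p = 0.003) with a small-to-moderate effect
(Kendall's W = 0.21).

## Command line

```bash
conntraj simulate --out study --seed 1            # synthetic cohort + truth.json
conntraj run --normative-dir study/normative --patient-dir study/patients \
    --scores-file study/scores.csv --patients-file study/patients.tsv \
    --ratings-file study/ratings.tsv --out study/run --seed 1
conntraj report --run-dir study/run
```

`run` writes the fitted normative model, per-patient anomaly matrices and
counts, per-scale cluster solutions, heatmap tables of per-cluster mean
anomaly counts, the full statistics report and a manifest carrying the
config hash and seed; reruns with the same config and seed are
byte-identical. `fit-normative`, `score`, `cluster` and `compare` expose the
individual stages.

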