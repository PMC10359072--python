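"""Synthetic cohorts: normative BOLD, lesioned patients, recovery trajectories.

Normative subjects get a covariance drawn around a shared base correlation
Sigma0 with Wishart dispersion (mean-preserving; smaller degrees of freedom
mean more inter-subject variability), then T iid zero-mean Gaussian samples
renormalized to unit variance per region. Patients additionally receive
tangent-space perturbations at planted pairs, expressed in units of the
normative per-pair tangent SD so the planted effect size is directly
comparable to the 3-sigma detection threshold. Trajectory cohorts are drawn
around planted per-cluster mean 4-vectors with Gaussian noise, clipped to
scale bounds and rounded to integer clinical scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cohort as ch
from . import connectivity as cn
from .regions import RegionLabel, default_motor_labels


@dataclass
class TrajectorySpec:
    """Planted recovery-trajectory clusters for one stroke scale."""

    cluster_means: np.ndarray  # K x 4
    cluster_sizes: list[int]
    noise_sd: float

    def __post_init__(self) -> None:
        self.cluster_means = np.asarray(self.cluster_means, dtype=float)
        if self.cluster_means.ndim != 2 or self.cluster_means.shape[1] != 4:
            raise ValueError("cluster_means must be K x 4")
        if len(self.cluster_sizes) != self.cluster_means.shape[0]:
            raise ValueError("one size per cluster required")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_clusters(self) -> int:
        return self.cluster_means.shape[0]

    @property
    def n_subjects(self) -> int:
        return int(sum(self.cluster_sizes))


def default_trajectory_specs() -> dict[str, TrajectorySpec]:
    """Study-sized default cohort: 22 subjects per scale.

    Cluster counts and sizes mirror the reported per-scale phenotypes
    (NIHSS 6 clusters of 4/3/8/4/2/1; FMA 2 of 18/4; BI 5 of 2/5/6/3/6;
    WMFT 2 of 16/6), with cluster-mean baselines placed so the cohort
    baseline means sit near the reported averages (NIHSS ~11, FMA ~16.5,
    BI ~9, WMFT ~12). Noise SDs of 1-2 points emulate test-retest noise on
    integer clinical scores.
    """
    return {
        "NIHSS": TrajectorySpec(
            cluster_means=[
                [14, 12, 6, 3],
                [20, 18, 16, 14],
                [8, 7, 5, 3],
                [14, 13, 13, 13],
                [4, 4, 3, 2],
                [28, 26, 20, 15],
            ],
            cluster_sizes=[4, 3, 8, 4, 2, 1],
            noise_sd=1.0,
        ),
        "FMA": TrajectorySpec(
            cluster_means=[[14, 16, 22, 30], [26, 32, 44, 56]],
            cluster_sizes=[18, 4],
            noise_sd=2.0,
        ),
        "BI": TrajectorySpec(
            cluster_means=[
                [10, 12, 18, 8],
                [5, 6, 8, 10],
                [8, 15, 45, 70],
                [5, 6, 12, 50],
                [12, 14, 15, 10],
            ],
            cluster_sizes=[2, 5, 6, 3, 6],
            noise_sd=2.0,
        ),
        "WMFT": TrajectorySpec(
            cluster_means=[[10, 11, 13, 16], [18, 22, 30, 40]],
            cluster_sizes=[16, 6],
            noise_sd=1.5,
        ),
    }


@dataclass
class GroundTruthSpec:
    """Everything the generator needs, with the planted ground truth.

    ``subject_jitter`` is the Wishart degrees of freedom kappa: subject
    covariances are drawn as Wishart(kappa, Sigma0/kappa), so the mean is
    Sigma0 and smaller kappa gives more inter-subject dispersion (kappa must
    be >= n_regions for the draw to be full rank).
    ``planted_anomalies`` is a list of (i, j, direction, magnitude) with
    direction in {"hypo", "hyper"} and magnitude in normative-SD units.
    """

    n_regions: int = 45
    region_labels: list[RegionLabel] | None = None
    base_covariance: np.ndarray | None = None
    subject_jitter: float = 100.0
    planted_anomalies: list[tuple[int, int, str, float]] = field(default_factory=list)
    trajectory_specs: dict[str, TrajectorySpec] = field(default_factory=default_trajectory_specs)
    pair_sd: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_labels is None:
            self.region_labels = default_motor_labels(self.n_regions)
        if len(self.region_labels) != self.n_regions:
            raise ValueError("region_labels length must equal n_regions")
        if self.base_covariance is None:
            self.base_covariance = make_base_covariance(self.n_regions, seed=self.seed)
        self.base_covariance = np.asarray(self.base_covariance, dtype=float)
        if self.base_covariance.shape != (self.n_regions, self.n_regions):
            raise ValueError("base covariance has wrong shape")
        if not np.allclose(np.diag(self.base_covariance), 1.0):
            raise ValueError("base covariance must have unit diagonal")
        if np.linalg.eigvalsh(self.base_covariance).min() <= 0:
            raise ValueError("base covariance must be SPD")
        if self.subject_jitter < self.n_regions:
            raise ValueError("subject_jitter (Wishart df) must be >= n_regions")
        for (i, j, direction, magnitude) in self.planted_anomalies:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions and i != j):
                raise ValueError(f"invalid planted pair ({i}, {j})")
            if direction not in ("hypo", "hyper"):
                raise ValueError(f"bad direction {direction!r}")
            if magnitude <= 0:
                raise ValueError("planted magnitude must be > 0")


def make_base_covariance(
    R: int, block_structure: list[list[int]] | None = None, seed: int = 0
) -> np.ndarray:
    """Random unit-diagonal SPD correlation matrix.

    A low-rank factor model plus diagonal noise, normalized to a correlation
    matrix. ``block_structure`` (lists of region indices) adds a shared
    within-block factor, mimicking e.g. a motor community with elevated
    within-community correlation.
    """
    if R < 2:
        raise ValueError("need at least 2 regions")
    rng = np.random.default_rng(seed)
    q = max(2, R // 3)
    A = rng.normal(scale=0.5, size=(R, q))
    cov = A @ A.T + np.eye(R)
    if block_structure:
        for block in block_structure:
            u = np.zeros(R)
            u[list(block)] = 1.0
            cov += 0.8 * np.outer(u, u)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return 0.5 * (corr + corr.T)


def _draw_subject_covariance(spec: GroundTruthSpec, rng: np.random.Generator) -> np.ndarray:
    """Wishart draw with mean Sigma0; retries (logged) on numerically
    non-SPD draws, which are possible only through round-off."""
    kappa = spec.subject_jitter
    scale = spec.base_covariance / kappa
    for attempt in range(5):
        cov = sps.wishart.rvs(df=kappa, scale=scale, random_state=rng)
        cov = 0.5 * (cov + cov.T)
        if np.linalg.eigvalsh(cov).min() > 0:
            return cov
        warnings.warn(f"non-SPD covariance draw (attempt {attempt + 1}); resampling")
    raise RuntimeError("could not draw an SPD subject covariance")


def _sample_timeseries(cov: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((T, cov.shape[0])) @ L.T
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X / sd


def simulate_normative_cohort(
    spec: GroundTruthSpec, n_subjects: int, T: int,
    rng: np.random.Generator | None = None,
) -> list[cn.RegionTimeSeries]:
    """Healthy reference cohort: per-subject jittered covariance, T iid draws."""
    if n_subjects < 2:
        raise ValueError("need at least 2 normative subjects")
    if T <= spec.n_regions:
        warnings.warn(f"T={T} <= R={spec.n_regions}: correlation estimates will be unstable")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    out = []
    for s in range(n_subjects):
        cov = _draw_subject_covariance(spec, rng)
        data = _sample_timeseries(cov, T, rng)
        out.append(cn.RegionTimeSeries(f"norm{s:04d}", data, spec.region_labels))
    return out


def _calibrated_pair_sd(spec: GroundTruthSpec, T: int) -> np.ndarray:
    """Normative per-pair tangent SD, estimated once from a simulated
    reference cohort when the spec does not carry one."""
    if spec.pair_sd is not None:
        return np.asarray(spec.pair_sd, dtype=float)
    calib_rng = np.random.default_rng((spec.seed, 0xC0FFEE))
    cohort = simulate_normative_cohort(spec, n_subjects=60, T=T, rng=calib_rng)
    mats = [cn.estimate_connectivity(ts) for ts in cohort]
    model = cn.fit_normative(mats)
    spec.pair_sd = model.pair_sd
    return spec.pair_sd


def simulate_patient(
    spec: GroundTruthSpec, lesion_side: str, T: int,
    rng: np.random.Generator | None = None,
    subject_id: str = "patient",
) -> tuple[cn.RegionTimeSeries, cn.AnomalyMatrix]:
    """One lesioned patient plus the planted ground truth.

    The subject covariance (jittered like a normative subject) is mapped to
    the tangent space at Sigma0, shifted by +/- magnitude x normative SD at
    each planted pair, and mapped back — the exponential map guarantees the
    perturbed matrix stays SPD. Returns the time series and a ground-truth
    anomaly matrix (planted labels; only the diagonal excluded).
    """
    if lesion_side not in ("left", "right"):
        raise ValueError("lesion_side must be 'left' or 'right'")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    R = spec.n_regions
    cov = _draw_subject_covariance(spec, rng)

    truth_codes = np.zeros((R, R), dtype=np.int8)
    if spec.planted_anomalies:
        pair_sd = _calibrated_pair_sd(spec, T)
        t = cn.tangent_project(cov, spec.base_covariance).values
        for (i, j, direction, magnitude) in spec.planted_anomalies:
            sign = 1.0 if direction == "hyper" else -1.0
            delta = sign * magnitude * pair_sd[i, j]
            t[i, j] += delta
            t[j, i] = t[i, j]
            truth_codes[i, j] = cn.HYPER if direction == "hyper" else cn.HYPO
            truth_codes[j, i] = truth_codes[i, j]
        cov = cn.tangent_inverse(t, spec.base_covariance)
        if np.linalg.eigvalsh(cov).min() <= 0:  # pragma: no cover - expm is SPD
            warnings.warn("perturbed covariance not SPD; reducing magnitude")
            cov = cn.tangent_inverse(0.5 * t, spec.base_covariance)

    data = _sample_timeseries(cov, T, rng)
    ts = cn.RegionTimeSeries(subject_id, data, spec.region_labels)
    excluded = np.zeros((R, R), dtype=bool)
    np.fill_diagonal(excluded, True)
    truth = cn.AnomalyMatrix(
        codes=truth_codes, excluded=excluded,
        z_values=np.full((R, R), np.nan), subject_id=subject_id,
        region_labels=spec.region_labels,
    )
    return ts, truth


def simulate_trajectories(
    spec: GroundTruthSpec, scale: ch.StrokeScaleDefinition,
    rng: np.random.Generator | None = None,
    traj: TrajectorySpec | None = None,
    subject_prefix: str = "sub",
) -> tuple[ch.ScoreTable, pd.Series]:
    """Four-timepoint score vectors with planted clusters for one scale.

    Each subject's vector is its cluster mean plus iid Gaussian noise,
    clipped to the scale bounds and rounded to integers. Returns a validated
    :class:`~conntraj.cohort.ScoreTable` and the true labels (1..K).
    """
    traj = traj if traj is not None else spec.trajectory_specs[scale.name]
    for mean in traj.cluster_means:
        if mean.min() < scale.min_score or mean.max() > scale.max_score:
            raise ValueError(f"cluster mean outside {scale.name} bounds")
    if traj.n_clusters > traj.n_subjects:
        raise ValueError("more clusters than subjects")
    rng = np.random.default_rng(spec.seed) if rng is None else rng

    records = []
    labels = {}
    idx = 0
    for k, (mean, size) in enumerate(zip(traj.cluster_means, traj.cluster_sizes), start=1):
        for _ in range(size):
            sid = f"{subject_prefix}{idx:03d}"
            idx += 1
            vals = mean + rng.normal(scale=traj.noise_sd, size=4)
            vals = np.clip(np.rint(vals), scale.min_score, scale.max_score)
            labels[sid] = k
            for tp, v in zip(ch.TIMEPOINTS, vals):
                records.append(ch.ScoreRecord(sid, scale.name, tp, float(v)))
    table = ch.validate_scores(records, scales={scale.name: scale})
    return table, pd.Series(labels, name="true_cluster")


def simulate_structural_ratings(
    true_labels: pd.Series, association_strength: float, seed: int = 0,
    deterministic_map: bool = False,
) -> pd.DataFrame:
    """Cluster-conditional 3-point integrity/proximity ratings.

    At strength 0 every cluster shares one categorical distribution (no
    association); at strength 1 with ``deterministic_map`` each cluster maps
    to a fixed rating (cluster k -> k mod 3), giving ratings constant within
    cluster. Intermediate strengths mix the two.
    """
    if not 0 <= association_strength <= 1:
        raise ValueError("association_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = np.array([0.5, 0.3, 0.2])
    rows = []
    for sid, k in true_labels.items():
        for tract in ch.TRACT_CLASSES:
            target = np.zeros(3)
            target[int(k) % 3] = 1.0
            if deterministic_map and association_strength == 1.0:
                integ = prox = int(k) % 3
            else:
                p = (1 - association_strength) * base + association_strength * target
                p = p / p.sum()
                integ = int(rng.choice(3, p=p))
                prox = int(rng.choice(3, p=p))
            rows.append(
                {"subject_id": sid, "tract_class": tract,
                 "integrity": integ, "proximity": prox}
            )
    return pd.DataFrame(rows)


def null_calibration_experiment(
    R: int = 10, T: int = 400, n_reference: int = 200,
    n_patients: int = 50, seed: int = 0, shrinkage: float = 0.05,
) -> dict:
    """False-positive calibration on pseudo-patients drawn from the
    normative generator itself.

    Fits the normative model on one reference cohort, scores ``n_patients``
    fresh draws from the same distribution, and returns the fraction of
    unmasked pairs flagged as anomalous. For Gaussian tangent values the
    analytic rate at a 3-SD threshold is 2 Phi(-3) ~ 0.27%.
    """
    rng = np.random.default_rng(seed)
    spec = GroundTruthSpec(n_regions=R, region_labels=default_motor_labels(R),
                           seed=seed)
    cohort = simulate_normative_cohort(spec, n_reference, T, rng=rng)
    mats = [cn.estimate_connectivity(ts, shrinkage) for ts in cohort]
    model = cn.fit_normative(mats)
    rows, cols = cn.pair_index(R)
    n_unmasked = int((~model.variance_mask[rows, cols]).sum())

    pseudo = simulate_normative_cohort(spec, n_patients, T, rng=rng)
    flagged = 0
    for ts in pseudo:
        am = cn.score_anomalies(cn.estimate_connectivity(ts, shrinkage), model)
        flagged += len(am.anomalous_pairs())
    total = n_unmasked * n_patients
    return {"flagged": flagged, "total_unmasked": total,
            "rate": flagged / total}


def trajectory_recovery_experiment(
    n_seeds: int = 100, n_subjects: int = 30, k_true: int = 5,
    separation: float = 8.0, noise_sd: float = 1.0, seed: int = 0,
) -> dict:
    """Planted-cluster recovery rate for the trajectory pipeline.

    Plants ``k_true`` well-separated mean trajectories (consecutive means
    ``separation`` x ``noise_sd`` apart on every timepoint) on a 0-100 scale,
    simulates ``n_subjects`` integer score vectors, clusters them, and counts
    the runs where the selected K is correct and the adjusted Rand index
    against the truth is exactly 1.
    """
    from sklearn.metrics import adjusted_rand_score

    from . import clustering as cl

    scale = ch.StrokeScaleDefinition("BI", 0, 100, ch.LOWER_WORSE)
    step = separation * noise_sd
    offsets = np.array([0.0, 1.0, 2.0, 3.0])
    means = [5 + k * step + offsets for k in range(k_true)]
    base_sizes = [n_subjects // k_true] * k_true
    for i in range(n_subjects - sum(base_sizes)):
        base_sizes[i] += 1
    successes = 0
    aris = []
    for s in range(n_seeds):
        spec = GroundTruthSpec(n_regions=2, subject_jitter=10, seed=seed + s)
        traj = TrajectorySpec(means, base_sizes, noise_sd)
        table, labels = simulate_trajectories(spec, scale, traj=traj)
        solution = cl.cluster_trajectories(table.wide("BI"), scale="BI")
        ari = adjusted_rand_score(labels[solution.labels.index],
                                  solution.labels.to_numpy())
        aris.append(ari)
        if solution.k_selected == k_true and ari == 1.0:
            successes += 1
    return {"successes": successes, "n_seeds": n_seeds,
            "success_rate": successes / n_seeds,
            "mean_ari": float(np.mean(aris))}


def recovery_experiment(
    R: int = 20, T: int = 400, n_reference: int = 200,
    magnitude: float = 6.0, n_planted: int = 8, seed: int = 0,
    shrinkage: float = 0.05,
) -> dict:
    """Planted-anomaly detection experiment for one seed.

    Fits the normative model on a fresh reference cohort, plants
    ``n_planted`` anomalies (alternating hyper/hypo at ``magnitude``
    normative SDs) on pairs sampled from the model's unmasked set — pairs in
    the excluded third are undetectable by construction — then scores one
    patient and tallies direction-matched detections.

    Returns sensitivity, the count of false detections, and the number of
    unmasked null pairs.
    """
    rng = np.random.default_rng(seed)
    labels = default_motor_labels(R)
    spec = GroundTruthSpec(n_regions=R, region_labels=labels, seed=seed)
    cohort = simulate_normative_cohort(spec, n_reference, T, rng=rng)
    mats = [cn.estimate_connectivity(ts, shrinkage) for ts in cohort]
    model = cn.fit_normative(mats)
    spec.pair_sd = model.pair_sd

    rows, cols = cn.pair_index(R)
    unmasked = ~model.variance_mask[rows, cols]
    candidates = np.flatnonzero(unmasked)
    chosen = rng.choice(candidates, size=n_planted, replace=False)
    spec.planted_anomalies = [
        (int(rows[c]), int(cols[c]), "hyper" if k % 2 == 0 else "hypo", magnitude)
        for k, c in enumerate(chosen)
    ]

    ts, truth = simulate_patient(spec, "right", T, rng=rng)
    am = cn.score_anomalies(cn.estimate_connectivity(ts, shrinkage), model)

    tp = fp = 0
    planted = {(i, j): d for (i, j, d, _) in spec.planted_anomalies}
    for (i, j, direction) in am.anomalous_pairs():
        if planted.get((i, j)) == direction:
            tp += 1
        else:
            fp += 1
    sensitivity = tp / n_planted
    n_null_unmasked = int(unmasked.sum()) - n_planted
    return {
        "true_positives": tp, "false_positives": fp,
        "n_planted": n_planted, "sensitivity": sensitivity,
        "n_null_unmasked": n_null_unmasked,
    }
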