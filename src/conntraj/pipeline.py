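"""End-to-end orchestration: simulate, fit, score, cluster, compare, report.

``run_pipeline`` is a pure function of (inputs, config): it fits the
normative model on the reference cohort, scores every patient's anomaly
matrix and region counts, clusters the recovery trajectories per scale,
runs the longitudinal and between-cluster statistics, and writes every
artifact (with the config hash and seed) into one run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as cl
from . import cohort as ch
from . import connectivity as cn
from . import io as cio
from . import stats as st
from . import synthetic as syn


@dataclass
class RunConfig:
    normative_dir: str
    patient_dir: str
    scores_file: str
    patients_file: str
    ratings_file: str | None = None
    out_dir: str = "run"
    shrinkage: float = 0.05
    sigma_threshold: float = 3.0
    mask_fraction: float = 1.0 / 3.0
    linkage: str = "ward"
    k_min: int = 2
    k_max: int = 10
    alpha: float = 0.05
    fma_max: int = 226
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.shrinkage < 1:
            raise ValueError("shrinkage must be in (0, 1)")
        if not 0 < self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("invalid k range")

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def render_heatmap_table(
    counts_by_subject: dict[str, cn.AnomalyCounts],
    labels: pd.Series,
) -> pd.DataFrame:
    """Per-cluster mean anomaly counts by region and laterality.

    Rows are (laterality, region) — ipsilesional regions first, then
    contralesional, then midline, alphabetical within each block; columns
    are (cluster, direction) mean counts.
    """
    missing = [s for s in counts_by_subject if s not in labels.index]
    if missing:
        raise ValueError(f"unlabeled subjects: {sorted(missing)}")
    frames = []
    for sid, counts in counts_by_subject.items():
        df = counts.per_region[["region", "laterality", "hypo_count", "hyper_count"]].copy()
        df["subject_id"] = sid
        df["cluster"] = int(labels.loc[sid])
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    means = (
        long.groupby(["laterality", "region", "cluster"], observed=True)[
            ["hypo_count", "hyper_count"]
        ]
        .mean()
        .unstack("cluster")
    )
    means.columns = [f"cluster{c}_{d.replace('_count', '')}" for d, c in means.columns]
    means = means[sorted(means.columns)]
    order = {"ipsilesional": 0, "contralesional": 1, "midline": 2}
    means = means.sort_index(
        key=lambda idx: idx.map(order) if idx.name == "laterality" else idx
    )
    return means


def _score_patients(
    patient_ts: list[cn.RegionTimeSeries],
    patients: dict[str, ch.PatientRecord],
    model: cn.NormativeModel,
    shrinkage: float,
) -> tuple[dict[str, cn.AnomalyMatrix], dict[str, cn.AnomalyCounts]]:
    anomalies: dict[str, cn.AnomalyMatrix] = {}
    counts: dict[str, cn.AnomalyCounts] = {}
    for ts in patient_ts:
        corr = cn.estimate_connectivity(ts, shrinkage)
        am = cn.score_anomalies(corr, model)
        anomalies[ts.subject_id] = am
        lesion = patients[ts.subject_id].lesion_side if ts.subject_id in patients else "right"
        counts[ts.subject_id] = cn.count_anomalies(am, lesion_side=lesion)
    return anomalies, counts


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Any stage failure removes partial outputs and raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_pipeline_inner(config, out)
    except Exception as exc:
        stage = getattr(exc, "stage", None)
        shutil.rmtree(out, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage or "unknown", exc) from exc


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def _run_pipeline_inner(config: RunConfig, out: Path) -> Path:
    scales = ch.default_scales(fma_max=config.fma_max)

    @_stage("read_inputs")
    def read_inputs():
        normative = [cio.read_timeseries(p) for p in sorted(Path(config.normative_dir).glob("*.tsv"))]
        patient_ts = [cio.read_timeseries(p) for p in sorted(Path(config.patient_dir).glob("*.tsv"))]
        scores = cio.read_scores(config.scores_file, scales=scales)
        patients = {p.subject_id: p for p in cio.read_patients(config.patients_file)}
        ratings = (pd.read_csv(config.ratings_file, sep="\t")
                   if config.ratings_file else None)
        if not normative:
            raise ValueError(f"no normative time series in {config.normative_dir}")
        if not patient_ts:
            raise ValueError(f"no patient time series in {config.patient_dir}")
        ref_labels = [str(l) for l in normative[0].region_labels]
        for ts in normative + patient_ts:
            if [str(l) for l in ts.region_labels] != ref_labels:
                raise ValueError(f"{ts.subject_id}: region labels differ from cohort")
        return normative, patient_ts, scores, patients, ratings

    normative, patient_ts, scores, patients, ratings = read_inputs()

    @_stage("fit_normative")
    def fit():
        mats = [cn.estimate_connectivity(ts, config.shrinkage) for ts in normative]
        return cn.fit_normative(
            mats, sigma_threshold=config.sigma_threshold,
            mask_fraction=config.mask_fraction,
            region_labels=normative[0].region_labels,
        )

    model = fit()
    cio.write_normative_model(model, out / "normative_model")

    @_stage("score_anomalies")
    def score():
        return _score_patients(patient_ts, patients, model, config.shrinkage)

    anomalies, counts = score()
    (out / "anomalies").mkdir(exist_ok=True)
    for sid in sorted(anomalies):
        cio.write_anomaly_matrix(anomalies[sid], out / "anomalies" / f"{sid}.tsv")
    totals = pd.DataFrame(
        [
            {
                "subject_id": sid,
                **{
                    f"{lat}_{dr}": counts[sid].total(dr, laterality=lat)
                    for lat in ("ipsilesional", "contralesional")
                    for dr in ("hypo", "hyper")
                },
            }
            for sid in sorted(counts)
        ]
    )
    totals.to_csv(out / "anomaly_totals.tsv", sep="\t", index=False)

    stats_report: dict = {}
    present_scales = sorted(set(scores.records["scale"]))
    for scale_name in present_scales:

        @_stage(f"cluster_{scale_name}")
        def cluster(scale_name=scale_name):
            wide = scores.wide(scale_name)
            solution = cl.cluster_trajectories(
                wide, scale=scale_name,
                k_range=range(config.k_min, min(config.k_max, len(wide) - 1) + 1),
                linkage=config.linkage,
            )
            return wide, solution

        wide, solution = cluster()
        cio.write_cluster_solution(solution, out / f"clusters_{scale_name}.json")
        solution.labels.to_csv(out / f"labels_{scale_name}.tsv", sep="\t")
        wide.to_csv(out / f"trajectories_{scale_name}.tsv", sep="\t")

        @_stage(f"stats_{scale_name}")
        def scale_stats(scale_name=scale_name, wide=wide, solution=solution):
            fr = st.friedman_test(wide, method="asymptotic")
            dunn = st.dunn_posthoc_friedman(wide, level_names=list(ch.TIMEPOINTS))
            entry = {
                "friedman": {
                    "statistic": fr.statistic, "df": fr.df, "p_value": fr.p_value,
                    "kendalls_w": fr.kendalls_w, "n": fr.n_subjects,
                },
                "dunn_timepoints": dunn.to_dict("records"),
                "incomplete_subjects": scores.incomplete_subjects(scale_name),
                "cluster_comparisons": [],
            }
            labeled = solution.labels
            for direction in ("hypo", "hyper"):
                for lat in ("ipsilesional", "contralesional"):
                    vals = {}
                    for sid, c in labeled.items():
                        if sid in counts:
                            vals.setdefault(str(c), []).append(
                                counts[sid].total(direction, laterality=lat)
                            )
                    if len(vals) >= 2 and all(len(v) for v in vals.values()):
                        res, post = st.compare_clusters_numeric(
                            {k: np.array(v) for k, v in vals.items()},
                            variable=f"{lat}_{direction}_count",
                            grouping=f"{scale_name}_cluster", alpha=config.alpha,
                        )
                        entry["cluster_comparisons"].append(_comparison_payload(res, post))
            if ratings is not None:
                for tract in ch.TRACT_CLASSES:
                    for measure in ("integrity", "proximity"):
                        sub = ratings[ratings["tract_class"] == tract]
                        vals = {}
                        for sid, c in labeled.items():
                            v = sub.loc[sub["subject_id"].astype(str) == sid, measure]
                            if len(v):
                                vals.setdefault(str(c), []).append(float(v.iloc[0]))
                        if len(vals) >= 2 and all(len(v) for v in vals.values()):
                            res, post = st.compare_clusters_numeric(
                                {k: np.array(v) for k, v in vals.items()},
                                variable=f"{tract}_{measure}",
                                grouping=f"{scale_name}_cluster", alpha=config.alpha,
                            )
                            entry["cluster_comparisons"].append(_comparison_payload(res, post))
            return entry

        stats_report[scale_name] = scale_stats()

        heat_subjects = {s: counts[s] for s in solution.labels.index if s in counts}
        if heat_subjects:
            heat = render_heatmap_table(heat_subjects, solution.labels)
            heat.to_csv(out / f"heatmap_{scale_name}.tsv", sep="\t",
                        float_format="%.6g")

    @_stage("demographics")
    def demographics():
        pdf = pd.DataFrame([vars(p) for p in patients.values()])
        return ch.summarize_cohort(pdf) if len(pdf) else None

    summary = demographics()
    if summary is not None:
        summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)

    (out / "stats_report.json").write_text(
        json.dumps(stats_report, indent=1, sort_keys=True, default=float)
    )
    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_normative": len(normative),
        "n_patients": len(patient_ts),
        "scales": present_scales,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _comparison_payload(res: st.GroupComparisonResult, post) -> dict:
    payload = {
        "variable": res.variable, "grouping": res.grouping,
        "test_used": res.test_used, "statistic": res.statistic,
        "p_value": res.p_value, "gating_trace": res.gating_trace,
    }
    if post is not None:
        payload["posthoc"] = post.to_dict("records")
    return payload


def simulate_study(
    out_dir: str | Path,
    seed: int = 0,
    n_regions: int = 45,
    n_normative: int = 200,
    T: int = 128,
    n_patients: int = 22,
    n_planted: int = 6,
    planted_magnitude: float = 6.0,
    association_strength: float = 0.8,
) -> Path:
    """Emit a complete synthetic study in the pipeline's input formats.

    Writes normative/ and patients/ time-series directories, scores.csv,
    patients.tsv, ratings.tsv and a truth.json with planted pairs, true
    cluster labels and the seed.
    """
    out = Path(out_dir)
    (out / "normative").mkdir(parents=True, exist_ok=True)
    (out / "patients").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spec = syn.GroundTruthSpec(n_regions=n_regions, seed=seed)

    cohort = syn.simulate_normative_cohort(spec, n_normative, T, rng=rng)
    for ts in cohort:
        cio.write_timeseries(ts, out / "normative" / f"{ts.subject_id}.tsv")

    # fit once on the simulated reference so planted magnitudes are in
    # normative-SD units, and plant on unmasked pairs
    mats = [cn.estimate_connectivity(ts) for ts in cohort]
    model = cn.fit_normative(mats)
    spec.pair_sd = model.pair_sd
    rows, cols = cn.pair_index(n_regions)
    candidates = np.flatnonzero(~model.variance_mask[rows, cols])

    protocols = list(ch.default_protocols())
    patients: list[ch.PatientRecord] = []
    truth_planted: dict[str, list] = {}
    for i in range(n_patients):
        sid = f"pat{i:03d}"
        lesion = "right" if rng.random() < 15 / 22 else "left"
        chosen = rng.choice(candidates, size=n_planted, replace=False)
        spec.planted_anomalies = [
            (int(rows[c]), int(cols[c]), "hyper" if k % 2 == 0 else "hypo",
             planted_magnitude)
            for k, c in enumerate(chosen)
        ]
        ts, truth = syn.simulate_patient(spec, lesion, T, rng=rng, subject_id=sid)
        cio.write_timeseries(ts, out / "patients" / f"{sid}.tsv")
        truth_planted[sid] = [list(p) for p in spec.planted_anomalies]
        proto = protocols[int(rng.integers(len(protocols)))]
        patients.append(ch.PatientRecord(
            subject_id=sid, age=float(rng.integers(45, 85)),
            sex="female" if rng.random() < 0.5 else "male",
            lesion_side=lesion,
            hospitalization_days=float(rng.integers(7, 14)),
            protocol=proto,
            tms_side_relative="contralateral" if proto == "low_frequency" else "ipsilateral",
            hypertension=bool(rng.random() < 0.55),
            diabetes=bool(rng.random() < 0.4),
            chd=bool(rng.random() < 0.2),
            hyperlipidemia=bool(rng.random() < 0.4),
        ))
    cio.write_patients(patients, out / "patients.tsv")

    scales = ch.default_scales()
    all_records = []
    true_labels: dict[str, dict[str, int]] = {}
    for name, scale in scales.items():
        traj = spec.trajectory_specs[name]
        means, sizes = traj.cluster_means, list(traj.cluster_sizes)
        if n_patients < len(sizes):  # drop the smallest planted clusters
            keep = sorted(np.argsort(sizes)[::-1][:n_patients])
            means = means[keep]
            sizes = [sizes[i] for i in keep]
        sizes = _resize_clusters(sizes, n_patients)
        traj = syn.TrajectorySpec(means, sizes, traj.noise_sd)
        table, labels = syn.simulate_trajectories(spec, scale, rng=rng, traj=traj,
                                                  subject_prefix="pat")
        all_records.append(table.records)
        true_labels[name] = {s: int(c) for s, c in labels.items()}
    scores = ch.validate_scores(pd.concat(all_records, ignore_index=True), scales=scales)
    cio.write_scores(scores, out / "scores.csv")

    bi_labels = pd.Series(true_labels["BI"])
    ratings = syn.simulate_structural_ratings(bi_labels, association_strength,
                                              seed=seed + 1)
    cio.write_ratings(ratings, out / "ratings.tsv")

    truth = {"seed": seed, "planted_pairs": truth_planted,
             "true_cluster_labels": true_labels}
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return out


def _resize_clusters(sizes: list[int], n: int) -> list[int]:
    """Scale planted cluster sizes to a total of n >= len(sizes), keeping
    every cluster nonempty."""
    if n < len(sizes):
        raise ValueError("fewer subjects than clusters")
    total = sum(sizes)
    scaled = [max(1, round(s * n / total)) for s in sizes]
    while sum(scaled) > n:
        candidates = [i for i, s in enumerate(scaled) if s > 1]
        scaled[max(candidates, key=lambda i: scaled[i])] -= 1
    while sum(scaled) < n:
        scaled[int(np.argmin(scaled))] += 1
    return scaled
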