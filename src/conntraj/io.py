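"""Readers and writers for all pipeline artifacts (plain-text formats).

Time series are tab-separated T x R tables whose header row carries
``hemi:class:name`` region labels; clinical scores are long-format CSV;
the normative model is a JSON header plus tab-separated matrices; anomaly
matrices are tab-separated with codes {-1, 0, 1, NA}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as ch
from . import connectivity as cn
from .regions import RegionLabel

_FLOAT_FMT = "%.10g"


def write_timeseries(ts: cn.RegionTimeSeries, path: str | Path) -> None:
    header = "\t".join(str(l) for l in ts.region_labels)
    np.savetxt(path, ts.data, fmt=_FLOAT_FMT, delimiter="\t",
               header=header, comments="")


def read_timeseries(path: str | Path, subject_id: str | None = None) -> cn.RegionTimeSeries:
    path = Path(path)
    with open(path) as fh:
        labels = [RegionLabel.parse(tok) for tok in fh.readline().rstrip("\n").split("\t")]
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    if data.ndim == 1:
        data = data[None, :]
    return cn.RegionTimeSeries(subject_id or path.stem, data, labels)


def write_scores(table: ch.ScoreTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False)


def read_scores(path: str | Path, scales=None) -> ch.ScoreTable:
    df = pd.read_csv(path)
    return ch.validate_scores(df, scales=scales)


def write_patients(patients: list[ch.PatientRecord], path: str | Path) -> None:
    pd.DataFrame([vars(p) for p in patients]).to_csv(path, sep="\t", index=False)


def read_patients(path: str | Path) -> list[ch.PatientRecord]:
    df = pd.read_csv(path, sep="\t")
    bool_cols = ["hypertension", "diabetes", "chd", "hyperlipidemia"]
    out = []
    for row in df.to_dict("records"):
        for c in bool_cols:
            if c in row:
                row[c] = bool(row[c])
        row["subject_id"] = str(row["subject_id"])
        out.append(ch.PatientRecord(**row))
    return out


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.to_csv(path, sep="\t", index=False)


def read_ratings(path: str | Path) -> list[ch.StructuralRating]:
    df = pd.read_csv(path, sep="\t")
    return [
        ch.StructuralRating(str(r["subject_id"]), r["tract_class"],
                            int(r["integrity"]), int(r["proximity"]))
        for r in df.to_dict("records")
    ]


def write_normative_model(model: cn.NormativeModel, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, cols = cn.pair_index(model.n_regions)
    masked_pairs = [
        [int(i), int(j)] for i, j in zip(rows, cols) if model.variance_mask[i, j]
    ]
    header = {
        "n_regions": model.n_regions,
        "n_reference": model.n_reference,
        "sigma_threshold": model.sigma_threshold,
        "mask_fraction": model.mask_fraction,
        "masked_pairs": masked_pairs,
        "region_labels": [str(l) for l in model.region_labels]
        if model.region_labels else None,
    }
    (out_dir / "model.json").write_text(json.dumps(header, indent=1, sort_keys=True))
    for name, mat in (("reference", model.reference),
                      ("pair_mean", model.pair_mean),
                      ("pair_sd", model.pair_sd)):
        np.savetxt(out_dir / f"{name}.tsv", mat, fmt=_FLOAT_FMT, delimiter="\t")


def read_normative_model(in_dir: str | Path) -> cn.NormativeModel:
    in_dir = Path(in_dir)
    header = json.loads((in_dir / "model.json").read_text())
    r = header["n_regions"]
    mask = np.zeros((r, r), dtype=bool)
    for i, j in header["masked_pairs"]:
        mask[i, j] = mask[j, i] = True
    labels = None
    if header.get("region_labels"):
        labels = [RegionLabel.parse(t) for t in header["region_labels"]]
    load = lambda name: np.loadtxt(in_dir / f"{name}.tsv", delimiter="\t").reshape(r, r)
    return cn.NormativeModel(
        reference=load("reference"), pair_mean=load("pair_mean"),
        pair_sd=load("pair_sd"), variance_mask=mask,
        n_reference=header["n_reference"],
        sigma_threshold=header["sigma_threshold"],
        mask_fraction=header["mask_fraction"], region_labels=labels,
    )


def write_anomaly_matrix(am: cn.AnomalyMatrix, path: str | Path) -> None:
    """Codes -1/0/1 with NA on excluded cells; header row of region labels
    when available."""
    r = am.n_regions
    cells = np.where(am.excluded, "NA", am.codes.astype(str))
    lines = []
    if am.region_labels:
        lines.append("\t".join(str(l) for l in am.region_labels))
    for i in range(r):
        lines.append("\t".join(cells[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_anomaly_matrix(path: str | Path, subject_id: str | None = None) -> cn.AnomalyMatrix:
    lines = Path(path).read_text().strip().split("\n")
    labels = None
    if ":" in lines[0]:
        labels = [RegionLabel.parse(t) for t in lines[0].split("\t")]
        lines = lines[1:]
    r = len(lines)
    codes = np.zeros((r, r), dtype=np.int8)
    excluded = np.zeros((r, r), dtype=bool)
    for i, line in enumerate(lines):
        for j, tok in enumerate(line.split("\t")):
            if tok == "NA":
                excluded[i, j] = True
            else:
                codes[i, j] = int(tok)
    return cn.AnomalyMatrix(
        codes=codes, excluded=excluded, z_values=np.full((r, r), np.nan),
        subject_id=subject_id or Path(path).stem, region_labels=labels,
    )


def write_cluster_solution(solution, path: str | Path) -> None:
    payload = {
        "scale": solution.scale,
        "linkage": solution.linkage,
        "k_selected": solution.k_selected,
        "silhouette_by_k": {str(k): v for k, v in sorted(solution.silhouette_by_k.items())},
        "labels": {s: int(c) for s, c in solution.labels.items()},
        "linkage_matrix": [[float(x) for x in row] for row in solution.linkage_matrix],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_cluster_labels(path: str | Path) -> pd.Series:
    payload = json.loads(Path(path).read_text())
    labels = pd.Series(payload["labels"], name="cluster")
    labels.index.name = "subject_id"
    return labels.astype(int)
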