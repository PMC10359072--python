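"""Normative tangent-space functional connectivity and anomaly matrices.

Per-subject connectivity is the shrunk Pearson correlation of region BOLD
time series. A normative cohort defines a reference point on the SPD
manifold (the affine-invariant Frechet/Karcher mean); each matrix is mapped
to the tangent space at that reference by

    t(C) = logm(M^{-1/2} C M^{-1/2}),

which linearizes the manifold so that per-pair normative ranges are
well-defined. A patient's pair is "hyperconnected" when its tangent value
lies more than ``sigma_threshold`` normative SDs above the normative mean,
"hypoconnected" below, and "normal" within (the +/-3 SD boundary itself is
normal). The third of pairs with the highest normative tangent variance is
excluded up front: those pairs vary most across healthy subjects and are the
most false-discovery-prone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import RegionLabel

HYPO, NORMAL, HYPER = -1, 0, 1

LATERALITY = ("ipsilesional", "contralesional", "midline")


class DegenerateCohortError(ValueError):
    """Normative cohort with zero variance on an unmasked pair."""


class ConvergenceError(RuntimeError):
    """Karcher-mean fixed-point iteration failed to converge."""


@dataclass
class RegionTimeSeries:
    """One subject's T x R BOLD sample matrix with ordered region labels."""

    subject_id: str
    data: np.ndarray
    region_labels: list[RegionLabel]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"{self.subject_id}: data must be 2-D (T x R)")
        if self.data.shape[1] != len(self.region_labels):
            raise ValueError(
                f"{self.subject_id}: {self.data.shape[1]} columns but "
                f"{len(self.region_labels)} region labels"
            )
        if self.data.shape[1] < 2:
            raise ValueError(f"{self.subject_id}: need at least 2 regions")
        if np.isnan(self.data).any():
            raise ValueError(f"{self.subject_id}: missing values in time series")
        names = [str(l) for l in self.region_labels]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.subject_id}: duplicate region labels")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R connectivity, either a correlation or a tangent image."""

    values: np.ndarray
    kind: str  # "correlation" | "tangent"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("correlation", "tangent"):
            raise ValueError(f"bad connectivity kind {self.kind!r}")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")


def estimate_connectivity(
    ts: RegionTimeSeries, shrinkage: float = 0.05
) -> ConnectivityMatrix:
    """Shrunk Pearson correlation (1 - lambda) C + lambda I.

    Shrinkage toward the identity guarantees positive-definiteness when the
    scan is short relative to the region count (clinical resting-state scans
    commonly have ~128 volumes against 45 regions).
    """
    if not 0 < shrinkage < 1:
        raise ValueError("shrinkage must be in (0, 1)")
    if ts.n_timepoints < 3:
        raise ValueError(f"{ts.subject_id}: need at least 3 samples")
    sd = ts.data.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = ", ".join(str(ts.region_labels[i]) for i in zero)
        raise ValueError(f"{ts.subject_id}: zero-variance region(s): {names}")
    corr = np.corrcoef(ts.data, rowvar=False)
    shrunk = (1.0 - shrinkage) * corr + shrinkage * np.eye(ts.n_regions)
    return ConnectivityMatrix(shrunk, "correlation", subject_id=ts.subject_id)


# --- SPD matrix functions (symmetric eigendecomposition) -------------------

def _eigh_fun(mat: np.ndarray, fun) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    return (v * fun(w)) @ v.T


def spd_logm(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    if w.min() <= 0:
        raise ValueError("matrix is not positive definite")
    return (v * np.log(w)) @ v.T


def sym_expm(mat: np.ndarray) -> np.ndarray:
    return _eigh_fun(mat, np.exp)


def spd_sqrtm(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    if w.min() <= 0:
        raise ValueError("matrix is not positive definite")
    return (v * np.sqrt(w)) @ v.T


def spd_invsqrtm(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    if w.min() <= 0:
        raise ValueError("matrix is not positive definite")
    return (v / np.sqrt(w)) @ v.T


def _as_values(mat) -> np.ndarray:
    if isinstance(mat, ConnectivityMatrix):
        return mat.values
    return np.asarray(mat, dtype=float)


def tangent_project(mat, reference) -> ConnectivityMatrix:
    """Map an SPD matrix to the tangent space at ``reference``:
    logm(reference^{-1/2} C reference^{-1/2})."""
    C = _as_values(mat)
    ref = _as_values(reference)
    inv_sqrt = spd_invsqrtm(ref)
    whitened = inv_sqrt @ C @ inv_sqrt
    whitened = 0.5 * (whitened + whitened.T)
    t = spd_logm(whitened)
    sid = mat.subject_id if isinstance(mat, ConnectivityMatrix) else None
    return ConnectivityMatrix(0.5 * (t + t.T), "tangent", subject_id=sid)


def tangent_inverse(tangent, reference) -> np.ndarray:
    """Inverse of :func:`tangent_project`: reference^{1/2} expm(T) reference^{1/2}."""
    t = _as_values(tangent)
    ref = _as_values(reference)
    sqrt = spd_sqrtm(ref)
    out = sqrt @ sym_expm(t) @ sqrt
    return 0.5 * (out + out.T)


def frechet_mean(
    mats, tol: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Affine-invariant (Karcher) mean of SPD matrices.

    Fixed-point iteration initialized at the log-Euclidean mean:
    M <- M^{1/2} exp(mean_i log(M^{-1/2} C_i M^{-1/2})) M^{1/2},
    stopping when the Frobenius norm of the mean tangent falls below ``tol``.
    """
    values = [_as_values(m) for m in mats]
    if not values:
        raise ValueError("empty input")
    shape = values[0].shape
    for v in values:
        if v.shape != shape:
            raise ValueError("inputs differ in size")
    mean = sym_expm(np.mean([spd_logm(v) for v in values], axis=0))
    for _ in range(max_iter):
        inv_sqrt = spd_invsqrtm(mean)
        sqrt = spd_sqrtm(mean)
        logs = []
        for v in values:
            w = inv_sqrt @ v @ inv_sqrt
            logs.append(spd_logm(0.5 * (w + w.T)))
        step = np.mean(logs, axis=0)
        resid = np.linalg.norm(step, "fro")
        if resid < tol:
            return 0.5 * (mean + mean.T)
        mean = sqrt @ sym_expm(step) @ sqrt
        mean = 0.5 * (mean + mean.T)
    raise ConvergenceError(f"Karcher mean did not converge (last residual {resid:.3e})")


# --- Normative model --------------------------------------------------------

def pair_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle pair indices (i < j)."""
    return np.triu_indices(n_regions, k=1)


@dataclass
class NormativeModel:
    """Normative tangent-space ranges fitted on a healthy cohort.

    ``pair_mean``/``pair_sd`` are full symmetric R x R matrices populated on
    off-diagonal pairs; ``variance_mask`` is True on the excluded
    highest-variance pairs (symmetric, False on the diagonal).
    """

    reference: np.ndarray
    pair_mean: np.ndarray
    pair_sd: np.ndarray
    variance_mask: np.ndarray
    n_reference: int
    sigma_threshold: float = 3.0
    mask_fraction: float = 1.0 / 3.0
    region_labels: list[RegionLabel] | None = None

    @property
    def n_regions(self) -> int:
        return self.reference.shape[0]

    @property
    def n_pairs(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2

    @property
    def n_masked_pairs(self) -> int:
        rows, cols = pair_index(self.n_regions)
        return int(self.variance_mask[rows, cols].sum())


def mask_size(n_pairs: int, mask_fraction: float = 1.0 / 3.0) -> int:
    """Number of excluded pairs: ceil(P * fraction)."""
    return int(math.ceil(n_pairs * mask_fraction))


def fit_normative(
    cohort,
    sigma_threshold: float = 3.0,
    mask_fraction: float = 1.0 / 3.0,
    region_labels: list[RegionLabel] | None = None,
) -> NormativeModel:
    """Fit the normative model on a cohort of correlation matrices.

    The reference is the Karcher mean of the cohort; every subject is
    projected to the tangent space at that reference, and per-pair means and
    SDs (denominator n-1) define the normative ranges. The
    ``ceil(P * mask_fraction)`` pairs with the largest normative SD are
    excluded (ties broken by row-major pair order).
    """
    values = [_as_values(m) for m in cohort]
    n = len(values)
    if n < 2:
        raise ValueError("normative cohort needs at least 2 subjects")
    reference = frechet_mean(values)
    inv_sqrt = spd_invsqrtm(reference)
    tangents = []
    for v in values:
        w = inv_sqrt @ v @ inv_sqrt
        tangents.append(spd_logm(0.5 * (w + w.T)))
    stack = np.stack(tangents)
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    mu = 0.5 * (mu + mu.T)
    sd = 0.5 * (sd + sd.T)

    r = reference.shape[0]
    rows, cols = pair_index(r)
    pair_sds = sd[rows, cols]
    n_mask = mask_size(pair_sds.size, mask_fraction)
    # stable argsort on -sd keeps row-major order among ties
    order = np.argsort(-pair_sds, kind="stable")
    masked = order[:n_mask]
    mask = np.zeros((r, r), dtype=bool)
    mask[rows[masked], cols[masked]] = True
    mask |= mask.T

    unmasked = np.ones(pair_sds.size, dtype=bool)
    unmasked[masked] = False
    if np.any(pair_sds[unmasked] == 0):
        raise DegenerateCohortError("zero tangent SD on an unmasked pair")

    return NormativeModel(
        reference=reference, pair_mean=mu, pair_sd=sd, variance_mask=mask,
        n_reference=n, sigma_threshold=sigma_threshold,
        mask_fraction=mask_fraction, region_labels=region_labels,
    )


@dataclass
class AnomalyMatrix:
    """Per-pair anomaly labels and tangent z-scores for one patient.

    ``codes`` holds -1 (hypo), 0 (normal), +1 (hyper); ``excluded`` marks
    masked pairs and the diagonal, whose codes are meaningless.
    """

    codes: np.ndarray
    excluded: np.ndarray
    z_values: np.ndarray
    subject_id: str | None = None
    region_labels: list[RegionLabel] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not (self.codes == self.codes.T).all():
            raise ValueError("anomaly codes must be symmetric")
        if not (self.excluded == self.excluded.T).all():
            raise ValueError("exclusion mask must be symmetric")
        if not self.excluded.diagonal().all():
            raise ValueError("diagonal must be excluded")

    @property
    def n_regions(self) -> int:
        return self.codes.shape[0]

    def label(self, i: int, j: int) -> str:
        if self.excluded[i, j]:
            return "excluded"
        return {HYPO: "hypo", NORMAL: "normal", HYPER: "hyper"}[int(self.codes[i, j])]

    def anomalous_pairs(self) -> list[tuple[int, int, str]]:
        rows, cols = pair_index(self.n_regions)
        out = []
        for i, j in zip(rows, cols):
            if not self.excluded[i, j] and self.codes[i, j] != NORMAL:
                out.append((int(i), int(j), "hyper" if self.codes[i, j] > 0 else "hypo"))
        return out


def score_anomalies(patient, model: NormativeModel) -> AnomalyMatrix:
    """Label one patient's pairs against the normative tangent ranges.

    z = (t - mu) / sigma per pair; strictly above +threshold is hyper,
    strictly below -threshold is hypo, otherwise normal ("within 3 SD" is
    inclusive of the boundary). Masked pairs and the diagonal are excluded.
    """
    C = _as_values(patient)
    if C.shape != model.reference.shape:
        raise ValueError(
            f"patient matrix {C.shape} does not match model {model.reference.shape}"
        )
    t = tangent_project(C, model.reference).values
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (t - model.pair_mean) / model.pair_sd
    excluded = model.variance_mask.copy()
    np.fill_diagonal(excluded, True)
    codes = np.zeros_like(z, dtype=np.int8)
    thr = model.sigma_threshold
    with np.errstate(invalid="ignore"):
        codes[z > thr] = HYPER
        codes[z < -thr] = HYPO
    codes[excluded] = NORMAL
    z = np.where(excluded, np.nan, z)
    sid = patient.subject_id if isinstance(patient, ConnectivityMatrix) else None
    return AnomalyMatrix(
        codes=codes, excluded=excluded, z_values=z, subject_id=sid,
        region_labels=model.region_labels,
    )


@dataclass
class AnomalyCounts:
    """Incident anomalous-pair counts per region, with laterality and class.

    ``per_region`` has one row per region: hypo_count / hyper_count of
    incident unmasked anomalous pairs (each anomalous pair contributes to
    both endpoints) and boolean parcel flags (region touched by >= 1 anomaly
    of the given direction).
    """

    per_region: pd.DataFrame
    subject_id: str | None = None
    lesion_side: str | None = None

    def totals(self) -> pd.DataFrame:
        """Sums of incident counts by (region class, laterality, direction)."""
        g = self.per_region.groupby(["region_class", "laterality"], observed=True)[
            ["hypo_count", "hyper_count"]
        ].sum()
        return g.reset_index()

    def total(self, direction: str, laterality: str | None = None,
              region_class: str | None = None) -> int:
        df = self.per_region
        if laterality is not None:
            df = df[df["laterality"] == laterality]
        if region_class is not None:
            df = df[df["region_class"] == region_class]
        return int(df[f"{direction}_count"].sum())

    def parcel_flag_count(self, direction: str, laterality: str | None = None,
                          region_class: str | None = None) -> int:
        """Number of regions with at least one incident anomaly."""
        df = self.per_region
        if laterality is not None:
            df = df[df["laterality"] == laterality]
        if region_class is not None:
            df = df[df["region_class"] == region_class]
        return int((df[f"{direction}_count"] > 0).sum())


def count_anomalies(
    am: AnomalyMatrix,
    region_labels: list[RegionLabel] | None = None,
    lesion_side: str = "right",
) -> AnomalyCounts:
    """Region-level anomaly counts split by lesion laterality.

    A region is ipsilesional when its hemisphere tag matches the lesion side
    ('left' -> 'L'), contralesional when opposite; midline regions ('M') form
    their own laterality stratum.
    """
    labels = region_labels or am.region_labels
    if labels is None:
        raise ValueError("region labels required")
    if lesion_side not in ("left", "right"):
        raise ValueError("lesion_side must be 'left' or 'right'")
    if len(labels) != am.n_regions:
        raise ValueError("label count does not match anomaly matrix")
    lesion_tag = "L" if lesion_side == "left" else "R"

    def laterality(hemi: str) -> str:
        if hemi == "M":
            return "midline"
        if hemi not in ("L", "R"):
            raise ValueError(f"unknown hemisphere tag {hemi!r}")
        return "ipsilesional" if hemi == lesion_tag else "contralesional"

    active = (~am.excluded) & (am.codes != NORMAL)
    hypo = ((am.codes == HYPO) & active).sum(axis=1)
    hyper = ((am.codes == HYPER) & active).sum(axis=1)
    per_region = pd.DataFrame(
        {
            "region": [l.name for l in labels],
            "hemi": [l.hemi for l in labels],
            "region_class": [l.region_class for l in labels],
            "laterality": [laterality(l.hemi) for l in labels],
            "hypo_count": hypo.astype(int),
            "hyper_count": hyper.astype(int),
        }
    )
    return AnomalyCounts(per_region=per_region, subject_id=am.subject_id,
                         lesion_side=lesion_side)
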