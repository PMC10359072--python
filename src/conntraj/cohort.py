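"""Clinical cohort model: stroke scales, timepoints, TMS protocols, patients.

Four standardized stroke scales are tracked at four timepoints (admission
baseline, then 1, 30 and 90 days after treatment). Treatment protocols are
repetitive TMS pulse trains characterized by frequency, train count, pulses
per train and inter-train interval; `total_pulses` and
`session_duration_minutes` implement the protocol arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIMEPOINTS = ("baseline", "day1", "day30", "day90")
TIMEPOINT_ORDINALS = {label: i + 1 for i, label in enumerate(TIMEPOINTS)}

HIGHER_WORSE = "higher_worse"
LOWER_WORSE = "lower_worse"


@dataclass(frozen=True)
class StrokeScaleDefinition:
    """Score range and severity direction of one standardized stroke scale."""

    name: str
    min_score: int
    max_score: int
    severity_direction: str

    def __post_init__(self) -> None:
        if self.min_score >= self.max_score:
            raise ValueError(f"{self.name}: min_score must be < max_score")
        if self.severity_direction not in (HIGHER_WORSE, LOWER_WORSE):
            raise ValueError(f"{self.name}: bad severity_direction {self.severity_direction!r}")

    def check_value(self, value: float) -> None:
        if not (self.min_score <= value <= self.max_score):
            raise ScoreRangeError(
                f"{self.name} value {value} outside [{self.min_score}, {self.max_score}]"
            )


class ScoreRangeError(ValueError):
    """A clinical score lies outside its scale's defined range."""


class ValidationError(ValueError):
    """Structurally invalid clinical input."""


def default_scales(fma_max: int = 226) -> dict[str, StrokeScaleDefinition]:
    """The four scales with their published ranges.

    NIHSS runs 0-42 with higher scores more severe; BI runs 0-100 and WMFT
    0-75 with lower scores more severe. FMA totals differ between the full
    battery and motor subscales across the literature, so its maximum is
    configurable (default 226, the conventional full-battery total).
    """
    return {
        "NIHSS": StrokeScaleDefinition("NIHSS", 0, 42, HIGHER_WORSE),
        "FMA": StrokeScaleDefinition("FMA", 0, fma_max, LOWER_WORSE),
        "BI": StrokeScaleDefinition("BI", 0, 100, LOWER_WORSE),
        "WMFT": StrokeScaleDefinition("WMFT", 0, 75, LOWER_WORSE),
    }


SCALES = default_scales()
SCALE_NAMES = tuple(SCALES)


@dataclass(frozen=True)
class ScoreRecord:
    subject_id: str
    scale: str
    timepoint: str
    value: float

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"{self.subject_id}/{self.scale}: unknown timepoint {self.timepoint!r}"
            )


@dataclass(frozen=True)
class TMSProtocol:
    """One rTMS stimulation protocol.

    For conventional protocols ``stimulation_frequency_hz`` is the pulse
    rate within a train. iTBS delivers bursts of ``pulses_per_burst`` pulses
    (at ``intra_burst_hz``) at ``burst_rate_hz`` bursts per second, so its
    active time per train is counted in bursts, not pulses.
    """

    name: str
    motor_threshold_fraction: float
    stimulation_frequency_hz: float
    trains: int
    pulses_per_train: int
    inter_train_interval_s: float
    side: str
    target: str = "M1"
    burst_rate_hz: float | None = None
    pulses_per_burst: int | None = None
    intra_burst_hz: float | None = None

    def __post_init__(self) -> None:
        if self.trains <= 0 or self.pulses_per_train <= 0:
            raise ValidationError(f"{self.name}: trains and pulses_per_train must be positive")
        if self.stimulation_frequency_hz <= 0:
            raise ValidationError(f"{self.name}: stimulation frequency must be positive")
        if not 0 < self.motor_threshold_fraction <= 1.5:
            raise ValidationError(f"{self.name}: implausible motor threshold fraction")
        if self.inter_train_interval_s < 0:
            raise ValidationError(f"{self.name}: negative inter-train interval")
        if self.is_theta_burst:
            if self.pulses_per_burst is None or self.burst_rate_hz is None:
                raise ValidationError(f"{self.name}: theta-burst needs burst parameters")
            if self.pulses_per_train % self.pulses_per_burst != 0:
                raise ValidationError(
                    f"{self.name}: pulses_per_train must be divisible by pulses_per_burst"
                )

    @property
    def is_theta_burst(self) -> bool:
        return self.burst_rate_hz is not None or self.pulses_per_burst is not None


def default_protocols() -> dict[str, TMSProtocol]:
    """The three treatment arms: iTBS, 10 Hz high-frequency, 1 Hz low-frequency."""
    return {
        "iTBS": TMSProtocol(
            name="iTBS", motor_threshold_fraction=0.80,
            stimulation_frequency_hz=50.0, burst_rate_hz=5.0,
            pulses_per_burst=3, intra_burst_hz=50.0,
            trains=20, pulses_per_train=30, inter_train_interval_s=8.0,
            side="ipsilesional",
        ),
        "high_frequency": TMSProtocol(
            name="high_frequency", motor_threshold_fraction=0.90,
            stimulation_frequency_hz=10.0,
            trains=100, pulses_per_train=10, inter_train_interval_s=10.0,
            side="ipsilesional",
        ),
        "low_frequency": TMSProtocol(
            name="low_frequency", motor_threshold_fraction=0.90,
            stimulation_frequency_hz=1.0,
            trains=100, pulses_per_train=10, inter_train_interval_s=2.0,
            side="contralesional",
        ),
    }


def total_pulses(protocol: TMSProtocol) -> int:
    """Total pulses delivered in one session: trains x pulses per train."""
    return protocol.trains * protocol.pulses_per_train


def session_duration_minutes(protocol: TMSProtocol) -> int:
    """Whole-minute session duration.

    Active time per train is pulses/frequency (bursts/burst-rate for theta
    burst); the inter-train interval is counted after every train, including
    the last, and the total is floored to whole minutes. This convention
    reproduces the printed durations of all three default protocols.
    """
    if protocol.is_theta_burst:
        bursts = protocol.pulses_per_train // protocol.pulses_per_burst
        active_s = bursts / protocol.burst_rate_hz
    else:
        active_s = protocol.pulses_per_train / protocol.stimulation_frequency_hz
    total_s = protocol.trains * (active_s + protocol.inter_train_interval_s)
    return int(math.floor(total_s / 60.0))


@dataclass(frozen=True)
class PatientRecord:
    subject_id: str
    age: float
    sex: str
    lesion_side: str
    hospitalization_days: float
    protocol: str
    tms_side_relative: str
    hypertension: bool = False
    diabetes: bool = False
    chd: bool = False
    hyperlipidemia: bool = False

    def __post_init__(self) -> None:
        if self.lesion_side not in ("left", "right"):
            raise ValidationError(f"{self.subject_id}: lesion_side must be left/right")
        if self.tms_side_relative not in ("ipsilateral", "contralateral"):
            raise ValidationError(f"{self.subject_id}: bad tms_side_relative")

    @property
    def stimulated_hemisphere(self) -> str:
        if self.tms_side_relative == "ipsilateral":
            return self.lesion_side
        return "right" if self.lesion_side == "left" else "left"


TRACT_CLASSES = ("CST", "cortical_subcortical_projection", "subcortical")


@dataclass(frozen=True)
class StructuralRating:
    """Visual white-matter ratings: integrity (0 intact, 1 injured, 2 absent)
    and lesion proximity (0 not adjacent, 1 adjacent <1 cm, 2 inside)."""

    subject_id: str
    tract_class: str
    integrity: int
    proximity: int

    def __post_init__(self) -> None:
        if self.tract_class not in TRACT_CLASSES:
            raise ValidationError(f"unknown tract class {self.tract_class!r}")
        if self.integrity not in (0, 1, 2) or self.proximity not in (0, 1, 2):
            raise ValidationError(
                f"{self.subject_id}/{self.tract_class}: ratings must be 0, 1 or 2"
            )


@dataclass
class ScoreTable:
    """Validated long-format clinical scores with complete/incomplete split."""

    records: pd.DataFrame  # columns: subject_id, scale, timepoint, value
    scales: dict[str, StrokeScaleDefinition] = field(default_factory=lambda: dict(SCALES))

    def wide(self, scale: str) -> pd.DataFrame:
        """Subject x timepoint table for one scale, complete subjects only."""
        sub = self.records[self.records["scale"] == scale]
        wide = sub.pivot(index="subject_id", columns="timepoint", values="value")
        wide = wide.reindex(columns=list(TIMEPOINTS))
        complete = wide.dropna()
        return complete.sort_index()

    def incomplete_subjects(self, scale: str) -> list[str]:
        sub = self.records[self.records["scale"] == scale]
        wide = sub.pivot(index="subject_id", columns="timepoint", values="value")
        wide = wide.reindex(columns=list(TIMEPOINTS))
        return sorted(wide.index[wide.isna().any(axis=1)])


def validate_scores(
    records, scales: dict[str, StrokeScaleDefinition] | None = None
) -> ScoreTable:
    """Validate score records and assemble a :class:`ScoreTable`.

    Accepts a list of :class:`ScoreRecord`, a long DataFrame with columns
    subject_id/scale/timepoint/value, or an existing :class:`ScoreTable`
    (idempotent). Values outside the referenced scale's range raise
    :class:`ScoreRangeError` naming the offending record; duplicate
    (subject, scale, timepoint) entries raise :class:`ValidationError`.
    """
    scales = dict(scales) if scales is not None else dict(SCALES)
    if isinstance(records, ScoreTable):
        df = records.records.copy()
    elif isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [(r.subject_id, r.scale, r.timepoint, r.value) for r in records],
            columns=["subject_id", "scale", "timepoint", "value"],
        )
    required = {"subject_id", "scale", "timepoint", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"score table needs columns {sorted(required)}")
    df = df[["subject_id", "scale", "timepoint", "value"]]
    df["subject_id"] = df["subject_id"].astype(str)

    unknown_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if unknown_tp:
        raise ValidationError(f"unknown timepoints: {sorted(unknown_tp)}")
    unknown_sc = set(df["scale"]) - set(scales)
    if unknown_sc:
        raise ValidationError(f"unknown scales: {sorted(unknown_sc)}")

    dup = df.duplicated(["subject_id", "scale", "timepoint"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate record for {first['subject_id']}/{first['scale']}/{first['timepoint']}"
        )
    for row in df.itertuples(index=False):
        scale = scales[row.scale]
        if not (scale.min_score <= row.value <= scale.max_score):
            raise ScoreRangeError(
                f"{row.subject_id}/{row.scale}/{row.timepoint}: value {row.value} "
                f"outside [{scale.min_score}, {scale.max_score}]"
            )
    ordered = df.sort_values(["scale", "subject_id", "timepoint"], key=_timepoint_key)
    return ScoreTable(records=ordered.reset_index(drop=True), scales=scales)


def _timepoint_key(col: pd.Series) -> pd.Series:
    if col.name == "timepoint":
        return col.map(TIMEPOINT_ORDINALS)
    return col


def summarize_cohort(
    patients: pd.DataFrame | list[PatientRecord],
    grouping: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Demographics-style summary table.

    Continuous columns are reported as ``median (q1, q3)`` with
    linear-interpolation quartiles; categorical/boolean columns as
    ``count (percent)`` of nonmissing values with percent rounded to the
    nearest integer. With ``grouping`` (subject -> cluster label), one summary
    column per group is added next to the overall column; empty groups get an
    em-dash marker.
    """
    if not isinstance(patients, pd.DataFrame):
        patients = pd.DataFrame([vars(p) for p in patients])
    if patients.empty:
        raise ValidationError("empty cohort")
    df = patients.set_index("subject_id") if "subject_id" in patients.columns else patients.copy()

    groups: dict[str, pd.DataFrame] = {"all": df}
    if grouping is not None:
        grouping = pd.Series(grouping)
        for g in sorted(grouping.unique()):
            members = grouping.index[grouping == g]
            groups[f"cluster_{g}"] = df.loc[df.index.intersection(members)]

    rows: list[dict[str, str]] = []
    for col in df.columns:
        series = df[col]
        if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
            row = {"variable": col, "kind": "continuous"}
            for gname, gdf in groups.items():
                row[gname] = _summarize_continuous(gdf[col])
            rows.append(row)
        else:
            levels = sorted(series.dropna().astype(str).unique())
            for level in levels:
                row = {"variable": f"{col}={level}", "kind": "categorical"}
                for gname, gdf in groups.items():
                    row[gname] = _summarize_categorical(gdf[col], level)
                rows.append(row)
    return pd.DataFrame(rows)


def _summarize_continuous(values: pd.Series) -> str:
    values = values.dropna()
    if values.empty:
        return "—"
    med = values.quantile(0.5)
    q1 = values.quantile(0.25)
    q3 = values.quantile(0.75)
    return f"{_fmt(med)} ({_fmt(q1)}, {_fmt(q3)})"


def _summarize_categorical(values: pd.Series, level: str) -> str:
    values = values.dropna().astype(str)
    if values.empty:
        return "—"
    n = int((values == level).sum())
    pct = int(round(100.0 * n / len(values)))
    return f"{n} ({pct}%)"


def _fmt(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return f"{x:.2f}".rstrip("0").rstrip(".")
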