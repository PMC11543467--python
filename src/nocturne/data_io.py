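"""CSV schemas, record types and run configuration.

All pipeline inputs are plain CSV files:

``glucose.csv``   ``participant_id,timestamp,value_mmol_l,source``
``wearable.csv``  ``participant_id,timestamp,channel,value,quality``
``static.csv``    ``participant_id,age_years,weight_kg,height_m,bmi,sex``
``activity.csv``  ``participant_id,timestamp,activity_class``
``labels.csv``    ``participant_id,date,night_hypo,n_events`` (output)

Timestamps are ISO-8601 and stored time-zone aware; all clock-window logic
(10:00, 22:00, 07:00) operates on local wall time.  Naive timestamps are
localized to :data:`DEFAULT_TZ`.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

log = logging.getLogger(__name__)

DEFAULT_TZ = "Europe/Zurich"

GLUCOSE_SOURCES = ("cgm", "smbg")

#: Wearable channels retained for analysis (the bold subset of the device's
#: signal list).  ``quality`` applies to channels where the device reports one.
WEARABLE_CHANNELS = (
    "activity_classification",
    "blood_pulse_wave",
    "core_temperature",
    "gsr_electrode",
    "heart_rate",
    "heart_rate_variability",
    "motion_activity",
    "number_of_steps",
    "perfusion_index",
    "respiration_rate",
)


class SchemaError(ValueError):
    """A CSV file does not match the documented column schema."""


class ValidationError(ValueError):
    """A record violates a field invariant; the message names the row."""


@dataclass(frozen=True)
class RawGlucoseRecord:
    """One glucose measurement (CGM sample or SMBG fingerstick), mmol/l."""

    participant_id: str
    timestamp: pd.Timestamp
    value: float
    source: str  # "cgm" | "smbg"

    def __post_init__(self) -> None:
        if self.source not in GLUCOSE_SOURCES:
            raise ValidationError(f"unknown glucose source {self.source!r}")
        if not (0 < self.value < 50):
            raise ValidationError(
                f"glucose value {self.value} mmol/l outside (0, 50)"
            )
        if self.timestamp.tzinfo is None:
            raise ValidationError("glucose timestamp must be time-zone aware")


@dataclass(frozen=True)
class RawWearableRecord:
    """One wearable sample: a named channel value plus optional quality %."""

    participant_id: str
    timestamp: pd.Timestamp
    channel: str
    value: float
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and not (0 <= self.quality <= 100):
            raise ValidationError(
                f"quality {self.quality} outside [0, 100]"
            )


@dataclass(frozen=True)
class StaticInfo:
    """Per-participant anthropometrics."""

    participant_id: str
    age: float  # years
    weight: float  # kg
    height: float  # m
    bmi: float  # kg/m^2
    sex: str  # "male" | "female"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        if not (0 < self.age < 25):
            raise ValidationError(f"age {self.age} outside (0, 25)")
        expected = self.weight / self.height**2
        if abs(self.bmi - expected) > 0.05 * expected:
            raise ValidationError(
                f"bmi {self.bmi} inconsistent with weight/height^2 = "
                f"{expected:.2f}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults are the study's protocol constants.

    day_window / night_window
        Wall-clock windows: the day is 10:00-22:00, the night 22:00-07:00
        of the next morning (a 9-h prediction horizon).
    grid_step
        Target resampling step in minutes (5 min, i.e. 3.33 mHz).
    hypo_threshold
        Hypoglycemia threshold in mmol/l (3.9 = 70 mg/dl).
    quality_min
        Wearable samples with device quality below this percent are dropped.
    availability_min
        Minimum available fraction for a participant-day-channel to be kept.
    """

    day_window: tuple[dt.time, dt.time] = (dt.time(10, 0), dt.time(22, 0))
    night_window: tuple[dt.time, dt.time] = (dt.time(22, 0), dt.time(7, 0))
    grid_step: int = 5  # minutes
    hypo_threshold: float = 3.9  # mmol/l
    quality_min: float = 50.0  # percent
    availability_min: float = 0.30
    n_features: int = 15
    cv_folds: int = 6
    cv_runs: int = 5
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if 60 % self.grid_step != 0:
            raise ValidationError(f"grid_step {self.grid_step} must divide 60")

    @property
    def night_hours(self) -> float:
        """Length of the night window in hours (crosses midnight)."""
        start, end = self.night_window
        span = (24 - start.hour - start.minute / 60) + end.hour + end.minute / 60
        return span


_CONFIG_TIME_KEYS = {"day_window", "night_window"}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file, or the defaults if absent.

    Partial files override only the named keys; unknown keys raise with the
    list of valid keys.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise SchemaError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: "
            f"{sorted(valid)}"
        )
    for key in _CONFIG_TIME_KEYS & set(raw):
        raw[key] = tuple(dt.time.fromisoformat(str(t)) for t in raw[key])
    return RunConfig(**raw)


def _parse_timestamps(series: pd.Series, *, what: str) -> pd.Series:
    ts = pd.to_datetime(series, format="ISO8601", utc=False)
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(DEFAULT_TZ)
    return ts


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_glucose(
    path: str | Path, source: str | None = None
) -> list[RawGlucoseRecord]:
    """Read ``glucose.csv``; returns records sorted by (participant, time).

    ``source`` overrides the file's ``source`` column (required when the file
    has none).  Duplicate (participant, timestamp) rows pass through
    unmerged; conflict resolution is the preprocess stage's job.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "timestamp", "value_mmol_l"], path)
    if source is None and "source" not in df.columns:
        raise SchemaError(f"{path}: no 'source' column and no source argument")
    ts = _parse_timestamps(df["timestamp"], what="glucose")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                RawGlucoseRecord(
                    participant_id=str(row.participant_id),
                    timestamp=ts.iloc[i],
                    value=float(row.value_mmol_l),
                    source=source if source is not None else str(row.source),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from exc
    records.sort(key=lambda r: (r.participant_id, r.timestamp))
    log.info("read_glucose: %d records from %s", len(records), path)
    return records


def read_wearable(path: str | Path) -> list[RawWearableRecord]:
    """Read ``wearable.csv``; quality may be blank (channels without one)."""
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "timestamp", "channel", "value"], path)
    ts = _parse_timestamps(df["timestamp"], what="wearable")
    has_q = "quality" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        quality = None
        if has_q and pd.notna(row.quality):
            quality = float(row.quality)
        try:
            records.append(
                RawWearableRecord(
                    participant_id=str(row.participant_id),
                    timestamp=ts.iloc[i],
                    channel=str(row.channel),
                    value=float(row.value),
                    quality=quality,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from exc
    records.sort(key=lambda r: (r.participant_id, r.channel, r.timestamp))
    log.info("read_wearable: %d records from %s", len(records), path)
    return records


def read_static(path: str | Path) -> list[StaticInfo]:
    """Read ``static.csv``."""
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["participant_id", "age_years", "weight_kg", "height_m", "bmi", "sex"],
        path,
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                StaticInfo(
                    participant_id=str(row.participant_id),
                    age=float(row.age_years),
                    weight=float(row.weight_kg),
                    height=float(row.height_m),
                    bmi=float(row.bmi),
                    sex=str(row.sex),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from exc
    return out


def read_activity(path: str | Path) -> pd.DataFrame:
    """Read ``activity.csv``; returns a sorted DataFrame (categorical stream,
    not a numeric wearable channel)."""
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "timestamp", "activity_class"], path)
    df["timestamp"] = _parse_timestamps(df["timestamp"], what="activity")
    df["participant_id"] = df["participant_id"].astype(str)
    return df.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)


def write_activity(path: str | Path, df: pd.DataFrame) -> None:
    out = df.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def write_glucose(path: str | Path, records: Iterable[RawGlucoseRecord]) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "timestamp": r.timestamp.isoformat(),
                "value_mmol_l": r.value,
                "source": r.source,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_wearable(path: str | Path, records: Iterable[RawWearableRecord]) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "timestamp": r.timestamp.isoformat(),
                "channel": r.channel,
                "value": r.value,
                "quality": r.quality,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_static(path: str | Path, rows: Iterable[StaticInfo]) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "age_years": s.age,
                "weight_kg": s.weight,
                "height_m": s.height,
                "bmi": s.bmi,
                "sex": s.sex,
            }
            for s in rows
        ]
    ).to_csv(path, index=False)


def write_labels(path: str | Path, labels) -> None:
    """Write ``labels.csv`` from a list of :class:`nocturne.labeling.NightLabel`."""
    pd.DataFrame(
        [
            {
                "participant_id": lab.participant_id,
                "date": lab.date.isoformat(),
                "night_hypo": int(lab.is_nh),
                "n_events": len(lab.events),
            }
            for lab in labels
        ]
    ).to_csv(path, index=False)
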