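"""Curation cascade: glucose fusion and gridding, wearable cleaning, MET map.

Glucose branch
    1. :func:`fuse_glucose` — merge CGM and SMBG; on a shared 5-min grid slot
       the lower value wins (hypoglycemia detection is the focus, so the
       pessimistic reading is kept).
    2. :func:`to_grid` — time-weighted linear interpolation onto the 5-min
       grid.
    3. :func:`fill_gaps` — remaining gaps filled with the mean of that
       calendar day's non-missing values.

Wearable branch (per channel)
    :func:`dedupe_mean` → :func:`quality_gate` → :func:`availability_filter`
    → :func:`window_mean_resample` → day-mean gap fill, mirroring the glucose
    rule.

Activity classes are mapped to MET values (1 MET = 1 kcal/kg/h) via
:data:`MET_TABLE`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nocturne.data_io import RawGlucoseRecord, RawWearableRecord

log = logging.getLogger(__name__)

# provenance markers
MEASURED = "measured"
INTERPOLATED = "interpolated"
SMBG = "smbg"
GAP_FILLED = "gap_filled"

#: Activity class -> MET value (kcal/kg/h).  ``None`` marks classes with no
#: defined intensity; they map to missing rather than zero.
MET_TABLE: dict[str, float | None] = {
    "Undefined": None,
    "Resting": 1.5,
    "Walking flat": 3.0,
    "Running flat": 7.0,
    "Biking flat": 7.0,
    "Walking up": 5.5,
    "Running up": 13.0,
    "Biking up": 10.0,
    "Rowing": 6.0,
    "Other": None,
    "Biking": 7.0,
    "Running": 7.0,
    "Walking": 3.0,
    "Walking down": 3.5,
    "Running down": 6.0,
    "Biking down": 3.0,
    "Sitting": 1.5,
    "Standing": 2.0,
    "Driving car": 2.5,
    "Driving public": 1.5,
    "Sleeping": 1.0,
    "Awake": 1.5,
    "Ctrl rest med ee": None,
    "Measured and relevant improvement in Relax": None,
    "Measured and relevant improvement in Sleep": None,
    "Measured and relevant improvement in Exercise": None,
    "Measured and relevant improvement in Move": None,
}


@dataclass
class GlucoseSeries:
    """A participant's glucose trace on the uniform grid with provenance.

    ``values`` is indexed by a strictly increasing tz-aware DatetimeIndex at
    constant ``grid_step``-minute spacing; ``provenance`` is aligned and
    holds one of ``measured``/``interpolated``/``smbg``/``gap_filled`` (NaN
    values carry NaN provenance until gap filling).
    """

    participant_id: str
    values: pd.Series
    provenance: pd.Series
    grid_step: int = 5

    def __post_init__(self) -> None:
        idx = self.values.index
        if len(idx) > 1:
            steps = np.diff(idx.asi8)
            if not (steps == self.grid_step * 60 * 10**9).all():
                raise ValueError("grid timestamps must be uniformly spaced")
        if not self.values.index.equals(self.provenance.index):
            raise ValueError("values/provenance indexes differ")

    def slice_window(self, start: pd.Timestamp, end: pd.Timestamp) -> "GlucoseSeries":
        """Samples with start <= t < end."""
        m = (self.values.index >= start) & (self.values.index < end)
        return GlucoseSeries(
            self.participant_id, self.values[m], self.provenance[m], self.grid_step
        )


@dataclass
class WearableFrame:
    """Curated wearable channels on the shared grid, with cell provenance."""

    participant_id: str
    values: pd.DataFrame  # columns = channels, index = grid
    provenance: pd.DataFrame
    grid_step: int = 5

    def slice_window(self, start: pd.Timestamp, end: pd.Timestamp) -> "WearableFrame":
        m = (self.values.index >= start) & (self.values.index < end)
        return WearableFrame(
            self.participant_id,
            self.values[m],
            self.provenance[m],
            self.grid_step,
        )


@dataclass
class MetSeries:
    """MET intensity on the grid; missing where the class has no MET."""

    participant_id: str
    met: pd.Series

    def met_hours(self, start=None, end=None, rest: float = 1.5) -> float:
        """Integral of above-rest MET over time, in MET·h."""
        s = self.met
        if start is not None:
            s = s[s.index >= start]
        if end is not None:
            s = s[s.index < end]
        if len(s) < 2:
            return 0.0
        dt_h = (s.index[1] - s.index[0]).total_seconds() / 3600
        excess = (s - rest).clip(lower=0).fillna(0.0)
        return float(excess.sum() * dt_h)


def _floor_to_slot(ts: pd.Timestamp, grid_step: int) -> pd.Timestamp:
    return ts.floor(f"{grid_step}min")


def fuse_glucose(
    cgm_records: list[RawGlucoseRecord],
    smbg_records: list[RawGlucoseRecord],
    grid_step: int = 5,
) -> list[RawGlucoseRecord]:
    """Merge CGM and SMBG records of one participant, keeping the minimum.

    "Same timestamp" means the same ``grid_step``-minute slot after flooring
    (devices report at minute precision, so exact equality would almost never
    fire).  Where both sources occupy a slot the record with the lower value
    is kept; SMBG-only slots are inserted at their original timestamps.
    """
    pids = {r.participant_id for r in cgm_records} | {
        r.participant_id for r in smbg_records
    }
    if len(pids) > 1:
        raise ValueError(f"fuse_glucose: mixed participants {sorted(pids)}")
    cgm_slots: dict[pd.Timestamp, list[RawGlucoseRecord]] = {}
    for r in cgm_records:
        cgm_slots.setdefault(_floor_to_slot(r.timestamp, grid_step), []).append(r)
    smbg_slots: dict[pd.Timestamp, list[RawGlucoseRecord]] = {}
    for r in smbg_records:
        smbg_slots.setdefault(_floor_to_slot(r.timestamp, grid_step), []).append(r)

    fused: list[RawGlucoseRecord] = []
    for slot in sorted(set(cgm_slots) | set(smbg_slots)):
        in_slot = cgm_slots.get(slot, []) + smbg_slots.get(slot, [])
        if slot in cgm_slots and slot in smbg_slots:
            fused.append(min(in_slot, key=lambda r: r.value))
        else:
            fused.extend(sorted(in_slot, key=lambda r: r.timestamp))
    fused.sort(key=lambda r: r.timestamp)
    log.info(
        "fuse_glucose: %d cgm + %d smbg -> %d fused",
        len(cgm_records), len(smbg_records), len(fused),
    )
    return fused


def to_grid(
    records: list[RawGlucoseRecord], grid_step: int = 5
) -> GlucoseSeries:
    """Time-weighted linear interpolation of fused records onto the grid.

    Grid points bracketed by two records get the time-weighted linear
    interpolant; points outside the record span stay missing (they are the
    gaps :func:`fill_gaps` handles).  A record falling exactly on a grid
    timestamp passes through unchanged with its own provenance.
    """
    if not records:
        raise ValueError("to_grid: need at least one record")
    pid = records[0].participant_id
    times = pd.DatetimeIndex([r.timestamp for r in records])
    vals = np.array([r.value for r in records], dtype=float)
    src = [SMBG if r.source == "smbg" else MEASURED for r in records]

    start = times[0].ceil(f"{grid_step}min")
    end = times[-1].floor(f"{grid_step}min")
    grid = pd.date_range(start, end, freq=f"{grid_step}min")

    t_ns = times.asi8.astype(float)
    g_ns = grid.asi8.astype(float)
    out = np.interp(g_ns, t_ns, vals)
    prov = np.array([INTERPOLATED] * len(grid), dtype=object)
    exact = {int(t): s for t, s in zip(times.asi8, src)}
    for i, gi in enumerate(grid.asi8):
        if int(gi) in exact:
            prov[i] = exact[int(gi)]
    return GlucoseSeries(
        pid,
        pd.Series(out, index=grid, name="glucose_mmol_l"),
        pd.Series(prov, index=grid, name="provenance"),
        grid_step,
    )


def fill_gaps(series: GlucoseSeries) -> GlucoseSeries:
    """Fill every missing grid value with its calendar day's non-missing mean.

    A calendar day with zero non-missing values is an error — such a day
    should have been excluded upstream.
    """
    vals = series.values.copy()
    prov = series.provenance.copy()
    if not vals.isna().any():
        return series
    for day, chunk in vals.groupby(vals.index.date):
        if chunk.isna().any():
            observed = chunk.dropna()
            if observed.empty:
                raise ValueError(
                    f"fill_gaps: day {day} has no non-missing values"
                )
            missing_idx = chunk.index[chunk.isna()]
            vals.loc[missing_idx] = observed.mean()
            prov.loc[missing_idx] = GAP_FILLED
    return GlucoseSeries(series.participant_id, vals, prov, series.grid_step)


def dedupe_mean(records: list[RawWearableRecord]) -> list[RawWearableRecord]:
    """Replace duplicated timestamps of one channel with their mean value
    (and mean quality)."""
    by_ts: dict[pd.Timestamp, list[RawWearableRecord]] = {}
    for r in records:
        by_ts.setdefault(r.timestamp, []).append(r)
    out = []
    for ts in sorted(by_ts):
        group = by_ts[ts]
        if len(group) == 1:
            out.append(group[0])
            continue
        qualities = [r.quality for r in group if r.quality is not None]
        out.append(
            RawWearableRecord(
                participant_id=group[0].participant_id,
                timestamp=ts,
                channel=group[0].channel,
                value=float(np.mean([r.value for r in group])),
                quality=float(np.mean(qualities)) if qualities else None,
            )
        )
    return out


def quality_gate(
    records: list[RawWearableRecord], quality_min: float = 50.0
) -> list[RawWearableRecord]:
    """Drop samples whose device quality is below ``quality_min`` percent.

    Samples without a quality measure pass unchanged ("less than 50%" is
    strict: quality exactly at the threshold is kept).
    """
    kept = [
        r for r in records if r.quality is None or r.quality >= quality_min
    ]
    log.info("quality_gate: %d -> %d records", len(records), len(kept))
    return kept


def availability_filter(
    day_records: list[RawWearableRecord],
    day_span_s: float,
    native_step_s: float,
    availability_min: float = 0.30,
) -> bool:
    """Keep a participant-day-channel iff available/expected >= the minimum.

    The expected count is the day span divided by the channel's native
    sampling step.
    """
    expected = day_span_s / native_step_s
    frac = len(day_records) / expected if expected > 0 else 0.0
    keep = frac >= availability_min
    log.info(
        "availability_filter: %.1f%% available -> %s",
        100 * frac, "keep" if keep else "drop",
    )
    return keep


def window_mean_resample(
    records: list[RawWearableRecord], grid_step: int = 5
) -> pd.Series:
    """Mean in non-overlapping ``[t, t + grid_step)`` windows.

    Grid timestamps label window starts; empty windows are missing (they are
    later filled by the same day-mean rule as glucose).
    """
    if not records:
        return pd.Series(dtype=float)
    ts = pd.DatetimeIndex([r.timestamp for r in records])
    vals = pd.Series([r.value for r in records], index=ts).sort_index()
    slots = vals.index.floor(f"{grid_step}min")
    means = vals.groupby(slots).mean()
    grid = pd.date_range(means.index[0], means.index[-1], freq=f"{grid_step}min")
    return means.reindex(grid)


def map_activity_to_met(activity_class: str) -> float | None:
    """Table lookup from activity class to MET; unknown classes raise."""
    if activity_class not in MET_TABLE:
        raise KeyError(
            f"unknown activity class {activity_class!r}; known classes: "
            f"{sorted(MET_TABLE)}"
        )
    return MET_TABLE[activity_class]


def curate_glucose(
    cgm_records: list[RawGlucoseRecord],
    smbg_records: list[RawGlucoseRecord],
    grid_step: int = 5,
) -> GlucoseSeries:
    """Full glucose branch: fuse → grid → gap-fill, for one participant."""
    fused = fuse_glucose(cgm_records, smbg_records, grid_step)
    return fill_gaps(to_grid(fused, grid_step))


def curate_wearable(
    records: list[RawWearableRecord],
    native_step_s: float = 1.0,
    grid_step: int = 5,
    quality_min: float = 50.0,
    availability_min: float = 0.30,
) -> WearableFrame:
    """Full wearable branch for one participant, all channels.

    Per channel: duplicate averaging, quality gating, per-calendar-day
    availability filtering against the native rate, 5-min window means, and
    day-mean gap filling of empty windows within retained days.
    """
    if not records:
        raise ValueError("curate_wearable: no records")
    pid = records[0].participant_id
    columns: dict[str, pd.Series] = {}
    prov_cols: dict[str, pd.Series] = {}
    channels = sorted({r.channel for r in records})
    for channel in channels:
        chan = [r for r in records if r.channel == channel]
        chan = quality_gate(dedupe_mean(chan), quality_min)
        kept: list[RawWearableRecord] = []
        by_day: dict = {}
        for r in chan:
            by_day.setdefault(r.timestamp.date(), []).append(r)
        for day, day_records in sorted(by_day.items()):
            span = (
                day_records[-1].timestamp - day_records[0].timestamp
            ).total_seconds() + native_step_s
            if availability_filter(
                day_records, span, native_step_s, availability_min
            ):
                kept.extend(day_records)
            else:
                log.info(
                    "curate_wearable: dropping %s %s %s (availability)",
                    pid, channel, day,
                )
        if not kept:
            continue
        col = window_mean_resample(kept, grid_step)
        prov = pd.Series(
            np.where(col.isna(), None, MEASURED), index=col.index, dtype=object
        )
        # day-mean fill of empty windows, mirroring the glucose rule
        for day, chunk in col.groupby(col.index.date):
            observed = chunk.dropna()
            if chunk.isna().any() and not observed.empty:
                missing_idx = chunk.index[chunk.isna()]
                col.loc[missing_idx] = observed.mean()
                prov.loc[missing_idx] = GAP_FILLED
        columns[channel] = col
        prov_cols[channel] = prov
    values = pd.DataFrame(columns)
    provenance = pd.DataFrame(prov_cols).reindex(values.index)
    return WearableFrame(pid, values, provenance, grid_step)


def resample_activity(activity: pd.DataFrame, grid_step: int = 5) -> pd.Series:
    """Modal activity class per ``grid_step``-minute window (class streams are
    categorical, so window means do not apply)."""
    s = pd.Series(
        activity["activity_class"].values,
        index=pd.DatetimeIndex(activity["timestamp"]),
    ).sort_index()
    slots = s.index.floor(f"{grid_step}min")
    modal = s.groupby(slots).agg(lambda x: x.mode().iloc[0])
    grid = pd.date_range(modal.index[0], modal.index[-1], freq=f"{grid_step}min")
    return modal.reindex(grid)


def met_series_from_activity(
    activity: pd.Series, participant_id: str = ""
) -> MetSeries:
    """Map a grid-aligned activity-class series to MET intensities."""
    met = activity.map(lambda c: np.nan if pd.isna(c) else map_activity_to_met(c))
    return MetSeries(participant_id, met.astype(float))
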