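"""Day/night segmentation and the nocturnal-hypoglycemia (NH) label.

The day is 10:00-22:00 and the following night 22:00-07:00 (next morning).
A night is hypoglycemic when either

(1) a single or multiple SMBG reading is strictly below 3.9 mmol/l, or
(2) there is an interval longer than 15 min in which all continuous glucose
    samples are strictly below 3.9 mmol/l.

Duration convention for clause (2): each 5-min grid sample covers its
half-open slot, so a maximal run of ``k`` consecutive sub-threshold samples
covers ``k * grid_step`` minutes; "greater than 15 min" on the 5-min grid
therefore means ``k >= 4``.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nocturne.data_io import RawGlucoseRecord, RunConfig
from nocturne.preprocess import GAP_FILLED, GlucoseSeries, WearableFrame

log = logging.getLogger(__name__)


@dataclass
class NhEvent:
    start: pd.Timestamp
    end: pd.Timestamp
    trigger: str  # "smbg" | "cgm_interval"


@dataclass
class DayNightPair:
    """One labeled unit: a day's data plus the following night's glucose."""

    participant_id: str
    date: dt.date
    day_glucose: GlucoseSeries
    day_wearable: WearableFrame | None
    night_glucose: GlucoseSeries
    night_smbg: list[RawGlucoseRecord]


@dataclass
class NightLabel:
    participant_id: str
    date: dt.date  # the preceding day the label attaches to
    is_nh: bool
    events: list[NhEvent]


class UnlabelableNightError(ValueError):
    """A night with no glucose samples and no SMBG cannot be labeled."""


def _wall(date: dt.date, time: dt.time, tz) -> pd.Timestamp:
    return pd.Timestamp(dt.datetime.combine(date, time)).tz_localize(tz)


def split_day_night(
    glucose: GlucoseSeries,
    smbg_records: list[RawGlucoseRecord],
    config: RunConfig,
    wearable: WearableFrame | None = None,
) -> list[DayNightPair]:
    """Segment one participant's curated data into (day, following night) pairs.

    A calendar day yields a pair when the day window is retained — measured
    or SMBG provenance covers at least ``availability_min`` of the 10:00-22:00
    grid (interpolated/gap-filled samples do not count toward retention) —
    and the following night has any glucose data.  Days failing either
    condition are dropped and logged.
    """
    idx = glucose.values.index
    if len(idx) == 0:
        return []
    tz = idx.tz
    day_start_t, day_end_t = config.day_window
    night_start_t, night_end_t = config.night_window
    pairs: list[DayNightPair] = []
    for date in sorted({t.date() for t in idx}):
        d0 = _wall(date, day_start_t, tz)
        d1 = _wall(date, day_end_t, tz)
        n0 = _wall(date, night_start_t, tz)
        n1 = _wall(date + dt.timedelta(days=1), night_end_t, tz)
        day = glucose.slice_window(d0, d1)
        night = glucose.slice_window(n0, n1)
        expected = int((d1 - d0).total_seconds() // (glucose.grid_step * 60))
        observed = int(day.provenance.isin(["measured", "smbg"]).sum())
        if expected == 0 or observed / expected < config.availability_min:
            log.info(
                "split_day_night: dropping %s %s (day retention %.0f%%)",
                glucose.participant_id, date,
                100 * observed / max(expected, 1),
            )
            continue
        if len(night.values) == 0:
            log.info(
                "split_day_night: dropping %s %s (no night data)",
                glucose.participant_id, date,
            )
            continue
        night_smbg = [
            r for r in smbg_records if n0 <= r.timestamp < n1
        ]
        pairs.append(
            DayNightPair(
                participant_id=glucose.participant_id,
                date=date,
                day_glucose=day,
                day_wearable=(
                    wearable.slice_window(d0, d1) if wearable is not None else None
                ),
                night_glucose=night,
                night_smbg=night_smbg,
            )
        )
    log.info(
        "split_day_night: %s -> %d pairs", glucose.participant_id, len(pairs)
    )
    return pairs


def detect_nh_events(
    night_glucose: GlucoseSeries,
    night_smbg: list[RawGlucoseRecord],
    threshold: float = 3.9,
    include_gap_filled: bool = True,
) -> list[NhEvent]:
    """Detect nocturnal-hypoglycemia events in one night.

    Clause (1): each SMBG reading strictly below ``threshold`` is one event.
    Clause (2): each maximal run of consecutive grid samples all strictly
    below ``threshold`` whose covered duration (k * grid_step min) exceeds
    15 min is one event.  ``include_gap_filled=False`` excludes gap-filled
    samples from clause (2), breaking runs at them.
    """
    if len(night_glucose.values) == 0 and not night_smbg:
        raise UnlabelableNightError("night has no glucose data and no SMBG")
    events: list[NhEvent] = []
    for r in night_smbg:
        if r.value < threshold:
            events.append(NhEvent(r.timestamp, r.timestamp, "smbg"))

    vals = night_glucose.values
    step = pd.Timedelta(minutes=night_glucose.grid_step)
    min_run = int(np.floor(15 / night_glucose.grid_step)) + 1  # "> 15 min"
    below = vals < threshold
    if not include_gap_filled:
        below &= night_glucose.provenance != GAP_FILLED
    run_start = None
    run_len = 0

    def close_run(end_i: int) -> None:
        nonlocal run_start, run_len
        if run_start is not None and run_len >= min_run:
            start_ts = vals.index[run_start]
            events.append(
                NhEvent(start_ts, start_ts + run_len * step, "cgm_interval")
            )
        run_start, run_len = None, 0

    for i, flag in enumerate(below.to_numpy()):
        if flag:
            if run_start is None:
                run_start = i
            run_len += 1
        else:
            close_run(i)
    close_run(len(below))
    events.sort(key=lambda e: e.start)
    return events


def label_nights(
    pairs: list[DayNightPair],
    threshold: float = 3.9,
    include_gap_filled: bool = True,
) -> list[NightLabel]:
    """Attach the NH label of each night to its preceding day.

    Nights that cannot be labeled (no glucose, no SMBG) are excluded with a
    log entry rather than guessed.
    """
    labels: list[NightLabel] = []
    for pair in pairs:
        try:
            events = detect_nh_events(
                pair.night_glucose, pair.night_smbg, threshold, include_gap_filled
            )
        except UnlabelableNightError:
            log.warning(
                "label_nights: excluding unlabelable night %s %s",
                pair.participant_id, pair.date,
            )
            continue
        labels.append(
            NightLabel(pair.participant_id, pair.date, bool(events), events)
        )
    n_pos = sum(lab.is_nh for lab in labels)
    log.info("label_nights: %d nights, %d hypoglycemic", len(labels), n_pos)
    return labels
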