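"""Synthetic camp-like cohort generator with ground-truth bookkeeping.

The generator emulates a one-week sports day camp for children with type 1
diabetes: 13 participants over 6 scheduled days, CGM at a 5- or 15-min
native step (5 of 13 children wear the 5-min device), daytime exercise
bouts, an SMBG logbook kept hourly during exercise, wearable heart-rate and
motion channels with quality scores and dropout segments, and nights whose
hypoglycemia risk is causally linked to the day's activity load.

Model
-----
Daytime glucose follows a mean-reverting (Ornstein-Uhlenbeck) process whose
target level carries meal bumps upward and an exercise effect downward
(proportional to accumulated MET·h).  The night's hypoglycemia indicator is
drawn from

    NH ~ Bernoulli( sigmoid(α + β_met · MET·h − β_g · G_bedtime) )

so the generative truth is exactly the hypothesis the classifiers must
detect: more daytime activity and lower bedtime glucose raise nocturnal
risk.  An NH night receives a contiguous glucose dip strictly below the
3.9 mmol/l threshold lasting ``dip_duration`` (> 15 min) placed uniformly
in 23:00-05:00; nights without an injected dip are floored just above the
threshold, so the recorded truth coincides exactly with the labeling
module's verdict.

12 of the 78 scheduled participant-days are marked absent (no daytime data),
matching the camp's attendance pattern of 66 analyzable days.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from nocturne import data_io
from nocturne.data_io import (
    DEFAULT_TZ,
    RawGlucoseRecord,
    RawWearableRecord,
    StaticInfo,
)

log = logging.getLogger(__name__)

STEP_MIN = 5  # internal simulation step, minutes
DAY_SIM_START = 7.0  # 07:00, hours
DAY_SIM_END = 22.0  # 22:00
NIGHT_SIM_END = 7.0  # 07:00 next day
_T_DAY = int((DAY_SIM_END - DAY_SIM_START) * 60 / STEP_MIN)  # 180
_T_NIGHT = int((24 - DAY_SIM_END + NIGHT_SIM_END) * 60 / STEP_MIN)  # 108

#: bout MET -> activity class emitted in the activity stream
_MET_CLASS = {3.0: "Walking", 5.5: "Walking up", 6.0: "Rowing",
              7.0: "Running flat", 10.0: "Biking up", 13.0: "Running up"}


@dataclass
class SynthConfig:
    """Generative parameters; defaults emulate the camp cohort.

    ``risk_intercept`` is calibrated so the expected nocturnal-hypoglycemia
    rate at the default effect sizes is ≈ 18/66 nights.
    """

    n_participants: int = 13
    n_days: int = 6
    n_fast_cgm: int = 5  # participants on the 5-min device; rest 15-min
    n_absent_days: int = 12  # scheduled participant-days without daytime data
    age_range: tuple[float, float] = (7.5, 13.9)
    female_fraction: float = 4 / 13
    bmi_mean: float = 19.8
    bmi_sd: float = 4.4
    bmi_range: tuple[float, float] = (13.2, 27.7)

    baseline_glucose: float = 8.0  # mmol/l
    ou_reversion: float = 1.0  # 1/h
    ou_noise: float = 1.1  # mmol/l per sqrt(h)
    meal_times_h: tuple[float, ...] = (8.0, 12.5, 18.5)
    meal_amplitude: float = 2.5  # mmol/l
    meal_width_h: float = 0.75
    exercise_drop: float = 0.10  # mmol/l per accumulated MET·h

    # each menu bout: (start hour, duration min, MET); kept with bout_prob,
    # duration jittered by ±bout_jitter
    bout_schedule: tuple[tuple[float, float, float], ...] = (
        (11.0, 60.0, 7.0),
        (14.5, 60.0, 6.0),
        (16.5, 45.0, 10.0),
    )
    bout_prob: float = 0.75
    bout_jitter: float = 0.5

    risk_intercept: float = -4.63  # α, calibrated to ≈18/66 expected NH
    risk_met_slope: float = 0.35  # β_met per MET·h
    risk_bedtime_slope: float = 0.40  # β_g per mmol/l
    hypo_threshold: float = 3.9
    dip_depth: float = 0.9  # dip level = threshold − dip_depth
    dip_duration: float = 40.0  # minutes, > 15 by construction
    night_floor: float = 4.2  # non-dip night glucose never below this
    smbg_noise: float = 0.3  # mmol/l fingerstick noise
    dip_smbg_prob: float = 0.5  # chance a symptom fingerstick lands in a dip

    wearable_step_s: float = 60.0  # native wearable step (1-min summaries)
    dropout_rate: float = 0.12  # fraction of the day the wearable is off
    quality_noise: float = 12.0
    seed: int = 0

    start_date: dt.date = dt.date(2023, 7, 10)
    tz: str = DEFAULT_TZ


@dataclass
class NightTruth:
    participant_id: str
    date: str  # the preceding day, ISO
    is_nh: bool
    dip_start: str | None
    dip_end: str | None
    met_h: float
    bedtime_glucose: float
    p_nh: float


@dataclass
class SynthBundle:
    static: list[StaticInfo]
    cgm: list[RawGlucoseRecord]
    smbg: list[RawGlucoseRecord]
    wearable: list[RawWearableRecord]
    activity: pd.DataFrame
    truth: list[NightTruth]
    absent: list[tuple[str, str]]  # (participant_id, date)


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    """Named substream of the master seed (1 cohort, 2 day, 3 night,
    4 noise, 5 attendance)."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# --- cohort ---------------------------------------------------------------

def gen_cohort(config: SynthConfig) -> list[StaticInfo]:
    """Static table: ages uniform on the configured range, heights from an
    age-linked growth line, BMI sampled and weight derived (so the
    BMI = weight/height² invariant holds by construction)."""
    rng = _rng(config, 1)
    n = config.n_participants
    ages = rng.uniform(*config.age_range, size=n)
    heights = 0.85 + 0.052 * ages + rng.normal(0, 0.04, size=n)
    bmi = np.clip(
        rng.normal(config.bmi_mean, config.bmi_sd, size=n), *config.bmi_range
    )
    weights = bmi * heights**2
    n_female = int(round(config.female_fraction * n))
    sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sexes)
    return [
        StaticInfo(
            participant_id=f"P{i + 1:02d}",
            age=round(float(ages[i]), 1),
            weight=round(float(weights[i]), 1),
            height=round(float(heights[i]), 2),
            bmi=round(float(weights[i] / heights[i] ** 2), 2),
            sex=str(sexes[i]),
        )
        for i in range(n)
    ]


# --- vectorized day/night simulation ---------------------------------------

def simulate_days(
    config: SynthConfig, n: int, rng: np.random.Generator
) -> dict:
    """Simulate ``n`` independent camp days (07:00-22:00) at 5-min steps.

    Returns glucose paths (n, T+1), per-day realized bouts, MET·h integrals
    and bedtime glucose.  Used both to emit fixture records and, at large
    ``n``, for Monte-Carlo checks of the night-risk model.
    """
    m = len(config.bout_schedule)
    keep = rng.random((n, m)) < config.bout_prob
    jitter = rng.uniform(1 - config.bout_jitter, 1 + config.bout_jitter, (n, m))
    starts = np.array([b[0] for b in config.bout_schedule])  # hours
    durs = np.array([b[1] for b in config.bout_schedule]) / 60 * jitter  # h
    mets = np.array([b[2] for b in config.bout_schedule])

    t_h = DAY_SIM_START + np.arange(_T_DAY + 1) * STEP_MIN / 60  # (T+1,)
    # MET path: bout MET where inside a kept bout, else daytime rest
    met_path = np.full((n, _T_DAY + 1), 1.5)
    for j in range(m):
        inside = (t_h[None, :] >= starts[j]) & (
            t_h[None, :] < starts[j] + durs[:, j][:, None]
        )
        met_path = np.where(inside & keep[:, j][:, None], mets[j], met_path)
    met_h = (keep * mets[None, :] * durs).sum(axis=1)  # bout integral

    # target level: baseline + meal bumps − exercise effect
    mu = np.full((n, _T_DAY + 1), config.baseline_glucose)
    for mt in config.meal_times_h:
        mu += config.meal_amplitude * np.exp(
            -0.5 * ((t_h[None, :] - mt) / config.meal_width_h) ** 2
        )
    cum_met_h = np.cumsum(
        np.where(met_path[:, :-1] > 1.5, met_path[:, :-1], 0.0) * STEP_MIN / 60,
        axis=1,
    )
    mu[:, 1:] -= config.exercise_drop * cum_met_h

    dt_h = STEP_MIN / 60
    g = np.empty((n, _T_DAY + 1))
    g[:, 0] = config.baseline_glucose + rng.normal(0, 0.5, n)
    noise = rng.normal(0, config.ou_noise * math.sqrt(dt_h), (n, _T_DAY))
    for t in range(_T_DAY):
        drift = config.ou_reversion * (mu[:, t] - g[:, t]) * dt_h
        g[:, t + 1] = g[:, t] + drift + noise[:, t]
    np.clip(g, 2.5, 25.0, out=g)
    return {
        "glucose": g,
        "t_hours": t_h,
        "met_path": met_path,
        "met_h": met_h,
        "g_bed": g[:, -1],
        "bouts": [
            [
                (float(starts[j]), float(durs[i, j] * 60), float(mets[j]))
                for j in range(m)
                if keep[i, j]
            ]
            for i in range(n)
        ],
    }


def night_probability(
    config: SynthConfig, met_h: np.ndarray, g_bed: np.ndarray
) -> np.ndarray:
    """P(NH) = sigmoid(α + β_met·MET·h − β_g·bedtime glucose)."""
    logit = (
        config.risk_intercept
        + config.risk_met_slope * np.asarray(met_h)
        - config.risk_bedtime_slope * np.asarray(g_bed)
    )
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_nights(
    config: SynthConfig,
    n: int,
    rng: np.random.Generator,
    nh: np.ndarray,
    g_start: np.ndarray,
) -> dict:
    """Night glucose paths (22:00-07:00) with injected dips for NH nights.

    Non-NH paths are floored at ``night_floor`` (> threshold) so the truth
    labels are exact; NH paths carry one contiguous dip strictly below the
    threshold of ``dip_duration`` minutes starting uniformly in 23:00-05:00.
    """
    dt_h = STEP_MIN / 60
    g = np.empty((n, _T_NIGHT + 1))
    g[:, 0] = np.maximum(g_start, config.night_floor + 0.3)
    noise = rng.normal(0, 0.7 * config.ou_noise * math.sqrt(dt_h), (n, _T_NIGHT))
    for t in range(_T_NIGHT):
        drift = config.ou_reversion * (config.baseline_glucose - 1.0 - g[:, t]) * dt_h
        g[:, t + 1] = g[:, t] + drift + noise[:, t]
    g = np.clip(g, config.night_floor, 25.0)

    # dip placement: offsets in steps from 22:00; 23:00 = step 12, 05:00 = 84
    n_dip = int(round(config.dip_duration / STEP_MIN))
    lo = int(1.0 * 60 / STEP_MIN)
    hi = int((24 - DAY_SIM_END + 5.0) * 60 / STEP_MIN)
    dip_start = rng.integers(lo, hi + 1, size=n)
    dip_level = config.hypo_threshold - config.dip_depth
    dip_starts_out = np.full(n, -1)
    for i in range(n):
        if not nh[i]:
            continue
        s = int(dip_start[i])
        vals = dip_level + rng.normal(0, 0.15, n_dip)
        g[i, s : s + n_dip] = np.minimum(vals, config.hypo_threshold - 0.2)
        dip_starts_out[i] = s
    return {"glucose": g, "dip_start_step": dip_starts_out, "n_dip_steps": n_dip}


# --- record emission --------------------------------------------------------

def _ts(date: dt.date, hour_float: float, tz: str) -> pd.Timestamp:
    base = pd.Timestamp(dt.datetime.combine(date, dt.time(0, 0))).tz_localize(tz)
    return base + pd.Timedelta(hours=hour_float)


def generate(config: SynthConfig) -> SynthBundle:
    """Generate the full cohort bundle in memory."""
    static = gen_cohort(config)
    rng_day = _rng(config, 2)
    rng_night = _rng(config, 3)
    rng_noise = _rng(config, 4)
    rng_attend = _rng(config, 5)

    n_sched = config.n_participants * config.n_days
    absent_flat = rng_attend.choice(
        n_sched, size=min(config.n_absent_days, n_sched), replace=False
    )
    absent = {
        (idx // config.n_days, idx % config.n_days) for idx in absent_flat
    }

    cgm: list[RawGlucoseRecord] = []
    smbg: list[RawGlucoseRecord] = []
    wearable: list[RawWearableRecord] = []
    activity_rows: list[dict] = []
    truth: list[NightTruth] = []
    absent_list: list[tuple[str, str]] = []

    for i, person in enumerate(static):
        pid = person.participant_id
        native_min = 5 if i < config.n_fast_cgm else 15
        for d in range(config.n_days):
            date = config.start_date + dt.timedelta(days=d)
            day = simulate_days(config, 1, rng_day)
            is_absent = (i, d) in absent
            if is_absent:
                absent_list.append((pid, date.isoformat()))
            else:
                _emit_day(
                    config, pid, date, day, native_min,
                    cgm, smbg, wearable, activity_rows, rng_noise,
                )
            # the night after this day always has glucose (sensor worn at home)
            met_h = float(day["met_h"][0])
            g_bed = float(day["g_bed"][0])
            p_nh = float(night_probability(config, [met_h], [g_bed])[0])
            nh = bool(rng_night.random() < p_nh)
            night = simulate_nights(
                config, 1, rng_night, np.array([nh]), np.array([g_bed])
            )
            dip_start_ts = dip_end_ts = None
            if nh:
                s = int(night["dip_start_step"][0])
                dip_start_ts = _ts(date, DAY_SIM_END + s * STEP_MIN / 60, config.tz)
                dip_end_ts = dip_start_ts + pd.Timedelta(minutes=config.dip_duration)
            _emit_night(
                config, pid, date, night, native_min, cgm, smbg, rng_noise, nh
            )
            if not is_absent:
                truth.append(
                    NightTruth(
                        participant_id=pid,
                        date=date.isoformat(),
                        is_nh=nh,
                        dip_start=None if dip_start_ts is None else dip_start_ts.isoformat(),
                        dip_end=None if dip_end_ts is None else dip_end_ts.isoformat(),
                        met_h=met_h,
                        bedtime_glucose=g_bed,
                        p_nh=p_nh,
                    )
                )
    cgm.sort(key=lambda r: (r.participant_id, r.timestamp))
    smbg.sort(key=lambda r: (r.participant_id, r.timestamp))
    activity = pd.DataFrame(activity_rows)
    log.info(
        "generate: %d participants, %d truth nights, %d NH",
        len(static), len(truth), sum(t.is_nh for t in truth),
    )
    return SynthBundle(static, cgm, smbg, wearable, activity, truth, absent_list)


def _emit_day(
    config, pid, date, day, native_min,
    cgm, smbg, wearable, activity_rows, rng,
) -> None:
    tz = config.tz
    g = day["glucose"][0]
    t_h = day["t_hours"]
    met_path = day["met_path"][0]
    stride = native_min // STEP_MIN
    for t in range(0, len(g), stride):
        cgm.append(
            RawGlucoseRecord(pid, _ts(date, t_h[t], tz), round(float(g[t]), 2), "cgm")
        )
    # hourly fingersticks during exercise bouts
    for start_h, dur_min, _met in day["bouts"][0]:
        h = start_h
        while h < start_h + dur_min / 60 + 1e-9:
            t_idx = int(round((h - DAY_SIM_START) * 60 / STEP_MIN))
            t_idx = min(t_idx, len(g) - 1)
            val = float(g[t_idx]) + float(rng.normal(0, config.smbg_noise))
            smbg.append(
                RawGlucoseRecord(pid, _ts(date, h, tz), round(max(val, 2.2), 1), "smbg")
            )
            h += 1.0

    # wearable channels at the native step, with one dropout segment
    step_h = config.wearable_step_s / 3600
    n_w = int((DAY_SIM_END - DAY_SIM_START) / step_h)
    w_hours = DAY_SIM_START + np.arange(n_w) * step_h
    met_at = np.interp(w_hours, t_h, met_path)
    hr = 65 + 9 * (met_at - 1) + rng.normal(0, 3, n_w)
    motion = np.maximum(0, (met_at - 1) * 10 + rng.normal(0, 2, n_w))
    base_q = np.where(met_at > 1.5, 68.0, 85.0)
    quality = np.clip(rng.normal(base_q, config.quality_noise), 0, 100)
    drop_len = int(config.dropout_rate * n_w)
    drop_at = int(rng.integers(0, n_w - drop_len)) if 0 < drop_len < n_w else 0
    keep_mask = np.ones(n_w, dtype=bool)
    keep_mask[drop_at : drop_at + drop_len] = False
    for t in range(n_w):
        if not keep_mask[t]:
            continue
        ts = _ts(date, float(w_hours[t]), tz)
        wearable.append(
            RawWearableRecord(pid, ts, "heart_rate", round(float(hr[t]), 1),
                              round(float(quality[t]), 1))
        )
        wearable.append(
            RawWearableRecord(pid, ts, "motion_activity",
                              round(float(motion[t]), 2), None)
        )
        cls = "Sitting"
        for start_h, dur_min, met in day["bouts"][0]:
            if start_h <= w_hours[t] < start_h + dur_min / 60:
                cls = _MET_CLASS.get(met, "Running flat")
        activity_rows.append(
            {"participant_id": pid, "timestamp": ts, "activity_class": cls}
        )


def _emit_night(config, pid, date, night, native_min, cgm, smbg, rng, nh) -> None:
    tz = config.tz
    g = night["glucose"][0]
    stride = native_min // STEP_MIN
    # skip t=0 (22:00, already emitted as the day's last sample) and the
    # final 07:00 sample (the next day's first)
    for t in range(stride, len(g) - 1, stride):
        cgm.append(
            RawGlucoseRecord(
                pid,
                _ts(date, DAY_SIM_END + t * STEP_MIN / 60, tz),
                round(float(g[t]), 2),
                "cgm",
            )
        )
    if nh and rng.random() < config.dip_smbg_prob:
        s = int(night["dip_start_step"][0])
        mid = s + night["n_dip_steps"] // 2
        val = float(g[mid]) + float(rng.normal(0, 0.1))
        val = min(val, config.hypo_threshold - 0.2)
        smbg.append(
            RawGlucoseRecord(
                pid,
                _ts(date, DAY_SIM_END + mid * STEP_MIN / 60, tz),
                round(max(val, 2.2), 1),
                "smbg",
            )
        )


def make_fixture(config: SynthConfig, out_dir: str | Path) -> SynthBundle:
    """Write the CSV bundle plus ``truth.json`` to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate(config)
    data_io.write_static(out / "static.csv", bundle.static)
    data_io.write_glucose(out / "glucose.csv", bundle.cgm + bundle.smbg)
    data_io.write_wearable(out / "wearable.csv", bundle.wearable)
    data_io.write_activity(out / "activity.csv", bundle.activity)
    (out / "truth.json").write_text(
        json.dumps(
            {
                "config_seed": config.seed,
                "n_nights": len(bundle.truth),
                "n_nh": sum(t.is_nh for t in bundle.truth),
                "absent_days": bundle.absent,
                "nights": [asdict(t) for t in bundle.truth],
            },
            indent=1,
        )
    )
    log.info("make_fixture: wrote bundle to %s", out)
    return bundle
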