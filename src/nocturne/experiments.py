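"""End-to-end experiment grids.

``run_overnight_grid`` evaluates the 9-h overnight prediction (day
10:00-22:00 → night 22:00-07:00 label) across dataset combinations ×
classifier families, with the same cross-evaluation partitions reused for
every combination within a run.  ``run_replication`` evaluates the 15-min
sliding-window scheme (45-min windows, 20-min stride, midnight-06:00).

Dataset combinations (columns of the overnight report):

``glucose_literature_features``  the eight glucose-dynamics features only,
                                 no bank, no selection
``glucose``                      glucose features + glucose feature bank,
                                 sequential selection to 15
``glucose+static``               + anthropometrics
``glucose+physio``               + wearable-channel banks and activity load
``glucose+physio+static``        everything

The recurrent families consume raw 5-min day tensors instead of engineered
features; they are not applicable to the literature-features column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nocturne import data_io, glucometrics, labeling, model_eval, preprocess
from nocturne.data_io import RunConfig, StaticInfo
from nocturne.labeling import DayNightPair, NightLabel

log = logging.getLogger(__name__)

COMBINATIONS = (
    "glucose_literature_features",
    "glucose",
    "glucose+static",
    "glucose+physio",
    "glucose+physio+static",
)
BANK_COMBINATIONS = COMBINATIONS[1:]


@dataclass
class ExperimentGrid:
    dataset_combinations: tuple[str, ...] = COMBINATIONS
    families: tuple[str, ...] = ("logreg_lasso", "random_forest")
    config: RunConfig = field(default_factory=RunConfig)
    fixture_dir: str | Path | None = None

    def __post_init__(self) -> None:
        bad = set(self.dataset_combinations) - set(COMBINATIONS)
        if bad:
            raise ValueError(f"unknown combination(s) {sorted(bad)}")
        if not self.dataset_combinations or not self.families:
            raise ValueError("grid needs >= 1 combination and >= 1 family")


# --- pipeline assembly ------------------------------------------------------

@dataclass
class CuratedCohort:
    pairs: list[DayNightPair]
    labels: list[NightLabel]
    y: np.ndarray
    static_by_pid: dict[str, StaticInfo]
    met_by_pid: dict[str, preprocess.MetSeries]


def load_fixture(fixture_dir: str | Path):
    """Read the CSV bundle written by the synthetic generator (or any data
    following the same schemas)."""
    d = Path(fixture_dir)
    glucose = data_io.read_glucose(d / "glucose.csv")
    wearable = data_io.read_wearable(d / "wearable.csv")
    static = data_io.read_static(d / "static.csv")
    activity_path = d / "activity.csv"
    activity = data_io.read_activity(activity_path) if activity_path.exists() else None
    return glucose, wearable, static, activity


def curate_cohort(
    glucose_records,
    wearable_records,
    static,
    activity,
    config: RunConfig,
    wearable_native_step_s: float = 60.0,
) -> CuratedCohort:
    """Full curation + labeling for a cohort of raw records."""
    static_by_pid = {s.participant_id: s for s in static}
    by_pid_cgm: dict[str, list] = {}
    by_pid_smbg: dict[str, list] = {}
    for r in glucose_records:
        (by_pid_smbg if r.source == "smbg" else by_pid_cgm).setdefault(
            r.participant_id, []
        ).append(r)
    wear_by_pid: dict[str, list] = {}
    for r in wearable_records:
        wear_by_pid.setdefault(r.participant_id, []).append(r)

    pairs: list[DayNightPair] = []
    met_by_pid: dict[str, preprocess.MetSeries] = {}
    for pid in sorted(by_pid_cgm):
        series = preprocess.curate_glucose(
            by_pid_cgm[pid], by_pid_smbg.get(pid, []), config.grid_step
        )
        frame = None
        if pid in wear_by_pid:
            frame = preprocess.curate_wearable(
                wear_by_pid[pid],
                native_step_s=wearable_native_step_s,
                grid_step=config.grid_step,
                quality_min=config.quality_min,
                availability_min=config.availability_min,
            )
        if activity is not None:
            act = activity[activity["participant_id"] == pid]
            if len(act):
                grid_classes = preprocess.resample_activity(act, config.grid_step)
                met_by_pid[pid] = preprocess.met_series_from_activity(
                    grid_classes, pid
                )
        pairs.extend(
            labeling.split_day_night(
                series, by_pid_smbg.get(pid, []), config, wearable=frame
            )
        )
    labels = labeling.label_nights(pairs, config.hypo_threshold)
    labeled = {(lab.participant_id, lab.date) for lab in labels}
    pairs = [p for p in pairs if (p.participant_id, p.date) in labeled]
    y = np.array([int(lab.is_nh) for lab in labels], dtype=int)
    return CuratedCohort(pairs, labels, y, static_by_pid, met_by_pid)


def _static_features(s: StaticInfo) -> dict[str, float]:
    return {
        "age": s.age,
        "weight": s.weight,
        "height": s.height,
        "bmi": s.bmi,
        "sex_female": 1.0 if s.sex == "female" else 0.0,
    }


def build_feature_matrix(
    cohort: CuratedCohort, combination: str, config: RunConfig
) -> pd.DataFrame:
    """One row per labeled day; columns per the dataset combination."""
    if combination not in COMBINATIONS:
        raise ValueError(f"unknown combination {combination!r}")
    rows = []
    for pair in cohort.pairs:
        day = pair.day_glucose.values
        feats: dict[str, float] = glucometrics.glucose_features(day)
        if combination != "glucose_literature_features":
            feats.update(glucometrics.feature_bank(day, "glucose"))
        if "physio" in combination:
            if pair.day_wearable is not None:
                for channel in pair.day_wearable.values.columns:
                    feats.update(
                        glucometrics.feature_bank(
                            pair.day_wearable.values[channel], channel
                        )
                    )
            met = cohort.met_by_pid.get(pair.participant_id)
            if met is not None:
                d0, d1 = day.index[0], day.index[-1]
                feats["met_hours"] = met.met_hours(d0, d1)
            else:
                feats["met_hours"] = 0.0
        if "static" in combination:
            feats.update(_static_features(cohort.static_by_pid[pair.participant_id]))
        rows.append(feats)
    X = pd.DataFrame(rows).fillna(0.0)
    if X.columns.duplicated().any():
        raise ValueError("duplicate feature names")
    return X


def build_sequence_dataset(
    cohort: CuratedCohort, combination: str, config: RunConfig
) -> model_eval.SequenceDataset:
    """Raw 5-min day tensors for the recurrent families.

    Channels are standardized over the dataset; gap-filled or absent steps
    are masked (set to 0, the standardized mean) so the recurrence carries
    its state through them unchanged.
    """
    step = config.grid_step
    T = int(12 * 60 / step)  # 10:00-22:00
    use_physio = "physio" in combination
    channel_names = ["glucose"]
    if use_physio:
        all_channels = sorted(
            {
                c
                for p in cohort.pairs
                if p.day_wearable is not None
                for c in p.day_wearable.values.columns
            }
        )
        channel_names += all_channels
    n, C = len(cohort.pairs), len(channel_names)
    seq = np.zeros((n, T, C))
    mask = np.zeros((n, T))
    for i, pair in enumerate(cohort.pairs):
        day = pair.day_glucose
        start = day.values.index[0]
        pos = ((day.values.index - start).total_seconds() // (step * 60)).astype(int)
        valid = pos < T
        seq[i, pos[valid], 0] = day.values.to_numpy()[valid]
        real = day.provenance.isin([preprocess.MEASURED, preprocess.SMBG,
                                    preprocess.INTERPOLATED]).to_numpy()
        mask[i, pos[valid & real]] = 1.0
        if use_physio and pair.day_wearable is not None:
            w = pair.day_wearable.values
            wpos = ((w.index - start).total_seconds() // (step * 60)).astype(int)
            ok = (wpos >= 0) & (wpos < T)
            for j, ch in enumerate(channel_names[1:], start=1):
                if ch in w.columns:
                    seq[i, wpos[ok], j] = w[ch].to_numpy()[ok]
    # standardize channels over unmasked steps, then zero the masked ones
    for j in range(C):
        vals = seq[:, :, j][mask == 1]
        mu = vals.mean() if len(vals) else 0.0
        sd = vals.std() if len(vals) and vals.std() > 0 else 1.0
        seq[:, :, j] = (seq[:, :, j] - mu) / sd
    seq[mask == 0] = 0.0
    static = None
    if "static" in combination:
        raw = np.array(
            [
                list(_static_features(cohort.static_by_pid[p.participant_id]).values())
                for p in cohort.pairs
            ]
        )
        mu, sd = raw.mean(axis=0), raw.std(axis=0)
        sd[sd == 0] = 1.0
        static = (raw - mu) / sd
    return model_eval.SequenceDataset(seq, mask, static)


# --- grids ------------------------------------------------------------------

def _resolve_family(family: str, combination: str) -> str:
    if family in ("dnn", "dnn_rnn", "dnn_rnn_mlp"):
        return "dnn_rnn_mlp" if "static" in combination else "dnn_rnn"
    return family


def _family_classifier_factory(family: str, seed: int):
    """Selection-time scorer matched to the downstream classifier."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression

    if family == "random_forest":
        return lambda: RandomForestClassifier(
            n_estimators=10, class_weight="balanced", random_state=seed
        )
    return lambda: LogisticRegression(
        l1_ratio=1.0, C=1.0, solver="saga", max_iter=2000,
        class_weight="balanced", random_state=seed,
    )


def run_overnight_grid(grid: ExperimentGrid, cohort: CuratedCohort | None = None) -> dict:
    """Evaluate every (combination, family) cell; failures mark the cell
    without aborting siblings."""
    config = grid.config
    if cohort is None:
        if grid.fixture_dir is None:
            raise ValueError("grid needs a fixture_dir or a curated cohort")
        cohort = curate_cohort(*load_fixture(grid.fixture_dir), config)
    y = cohort.y
    report: dict = {
        "kind": "overnight",
        "n_nights": int(len(y)),
        "n_nh": int(y.sum()),
        "seed": config.seed,
        "cells": {},
    }
    try:
        partitions = model_eval.make_partitions(y, config)
    except ValueError as exc:
        log.exception("partitioning failed; marking every cell failed")
        for combination in grid.dataset_combinations:
            for family in grid.families:
                report["cells"][f"{family}|{combination}"] = {
                    "status": "failed",
                    "error": str(exc),
                }
        report["any_failed"] = True
        return report
    for combination in grid.dataset_combinations:
        for family in grid.families:
            resolved = _resolve_family(family, combination)
            cell_key = f"{family}|{combination}"
            if (
                family.startswith("dnn")
                and combination == "glucose_literature_features"
            ):
                report["cells"][cell_key] = {"status": "n.a."}
                continue
            try:
                report["cells"][cell_key] = _run_cell(
                    cohort, combination, resolved, config, partitions
                )
            except Exception as exc:  # isolate cell failures
                log.exception("cell %s failed", cell_key)
                report["cells"][cell_key] = {"status": "failed", "error": str(exc)}
    report["any_failed"] = any(
        c.get("status") == "failed" for c in report["cells"].values()
    )
    return report


def _run_cell(cohort, combination, family, config, partitions) -> dict:
    if family in model_eval.SEQUENCE_FAMILIES:
        data = build_sequence_dataset(cohort, combination, config)
        spec = model_eval.ClassifierSpec(family, seed=config.seed)
        cv = model_eval.run_cv(data, cohort.y, spec, config, partitions)
        selected = None
    else:
        X = build_feature_matrix(cohort, combination, config)
        selected = None
        if combination in BANK_COMBINATIONS and X.shape[1] > config.n_features:
            sel = glucometrics.sequential_select(
                X, cohort.y, config.n_features,
                _family_classifier_factory(family, config.seed),
                seed=config.seed,
            )
            X = X[sel.selected]
            selected = sel.selected
        spec = model_eval.ClassifierSpec(family, seed=config.seed)
        cv = model_eval.run_cv(
            X.to_numpy(dtype=float), cohort.y, spec, config, partitions
        )
    fold_hash = int(
        np.sum([np.sum(f * np.arange(1, len(f) + 1)) for f in cv.fold_assignments])
    )
    return {
        "status": "ok",
        "mean": cv.mean,
        "sd": cv.sd,
        "per_fold_sd": cv.per_fold_sd,
        "selected_features": selected,
        "fold_hash": fold_hash,
    }


def render_overnight_markdown(report: dict) -> str:
    """Markdown matrix: rows = family × metric, columns = combinations."""
    lines = [
        f"# Overnight prediction (22:00-07:00), {report['n_nights']} nights "
        f"({report['n_nh']} hypoglycemic)",
        "",
    ]
    combos = sorted({k.split("|")[1] for k in report["cells"]},
                    key=lambda c: COMBINATIONS.index(c))
    families = sorted({k.split("|")[0] for k in report["cells"]})
    header = "| model | metric | " + " | ".join(combos) + " |"
    lines += [header, "|" + "---|" * (len(combos) + 2)]
    for family in families:
        for metric in ("f2", "f1", "auc"):
            row = [family, metric.upper()]
            for combo in combos:
                cell = report["cells"].get(f"{family}|{combo}", {})
                if cell.get("status") != "ok":
                    row.append(cell.get("status", ""))
                else:
                    row.append(
                        f"{100 * cell['mean'][metric]:.1f} ± "
                        f"{100 * cell['sd'][metric]:.1f}"
                    )
            lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"


REPLICATION_METRIC_ROWS = (
    "specificity", "sensitivity", "precision", "f2", "f1", "auc"
)


def run_replication(grid: ExperimentGrid, cohort: CuratedCohort | None = None) -> dict:
    """The 15-min sliding-window scheme for LR / RF / MLP."""
    config = grid.config
    if cohort is None:
        cohort = curate_cohort(*load_fixture(grid.fixture_dir), config)
    report: dict = {"kind": "replication_15min", "models": {}, "seed": config.seed}
    families = [
        f for f in grid.families if f in ("logreg_lasso", "random_forest", "mlp")
    ] or ["logreg_lasso", "random_forest", "mlp"]
    for family in families:
        spec = model_eval.ClassifierSpec(family, seed=config.seed)
        try:
            cv, X, yw = model_eval.run_berikov(
                cohort.pairs, cohort.static_by_pid, spec, config
            )
        except Exception as exc:
            log.exception("replication %s failed", family)
            report["models"][family] = {"status": "failed", "error": str(exc)}
            continue
        if cv is None:
            report["models"][family] = {
                "status": "degenerate",
                "n_windows": int(len(yw)),
                "n_positive": int(yw.sum()) if len(yw) else 0,
            }
            continue
        report["models"][family] = {
            "status": "ok",
            "n_windows": int(len(yw)),
            "n_positive": int(yw.sum()),
            "mean": {k: cv.mean[k] for k in REPLICATION_METRIC_ROWS},
            "sd": {k: cv.sd[k] for k in REPLICATION_METRIC_ROWS},
        }
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = "report_overnight" if report["kind"] == "overnight" else "report_replication"
    (out / f"{name}.json").write_text(json.dumps(report, indent=1, default=str))
    if report["kind"] == "overnight":
        (out / f"{name}.md").write_text(render_overnight_markdown(report))
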