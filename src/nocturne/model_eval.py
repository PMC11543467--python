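"""Classifiers, F2-first metrics, repeated stratified cross-evaluation, and
the 15-min sliding-window replication scheme.

Model families
--------------
``logreg_lasso``   L1-regularized logistic regression; the penalty strength
                   is chosen by internal cross-validated F2 over a small
                   logarithmic grid.
``random_forest``  Random forest with 10 trees.
``dnn_rnn``        Masked bidirectional GRU + LSTM on the 5-min day grid.
``dnn_rnn_mlp``    LSTM temporal branch fused with an MLP static branch.
``mlp``            Plain MLP on flat feature vectors (replication scheme).

All families receive class weights inversely proportional to class
frequencies, ``w_c = N / (2 · N_c)``.  Evaluation follows the protocol:
stratified 6-fold cross-evaluation repeated 5 times with re-shuffled
partitions, per-run metrics from the pooled test-fold predictions, and
mean ± SD reported across runs.  A score at or above 0.5 counts as a
positive prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from nocturne import nn
from nocturne.data_io import RunConfig

log = logging.getLogger(__name__)

FAMILIES = ("logreg_lasso", "random_forest", "dnn_rnn", "dnn_rnn_mlp", "mlp")
SEQUENCE_FAMILIES = ("dnn_rnn", "dnn_rnn_mlp")

_DNN_DEFAULTS = {
    "learning_rate": 0.001,
    "batch_size": 1,
    "max_epochs": 30,
    "patience": 5,
    "dropout": 0.2,
}


@dataclass
class ClassifierSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        defaults: dict = {}
        if self.family == "random_forest":
            defaults = {"n_estimators": 10}
        elif self.family == "logreg_lasso":
            defaults = {"c_grid": tuple(np.logspace(-2, 2, 7))}
        elif self.family in SEQUENCE_FAMILIES or self.family == "mlp":
            defaults = dict(_DNN_DEFAULTS)
        self.hyperparameters = {**defaults, **self.hyperparameters}


@dataclass
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tn + self.fp + self.fn + self.tp == 0:
            raise ValueError("confusion matrix must have at least one count")


@dataclass
class MetricsReport:
    specificity: float
    sensitivity: float
    precision: float
    f1: float
    f2: float
    auc: float
    beta: float = 2.0
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "f2": self.f2,
            "auc": self.auc,
        }


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Weights inversely proportional to class frequency: N / (2 · N_c)."""
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("class_weights needs both classes present")
    n = len(y)
    return {0: n / (2 * counts[0]), 1: n / (2 * counts[1])}


def confusion(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionMatrix:
    """2×2 counts at the threshold; score >= threshold predicts positive."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    return ConfusionMatrix(
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tp=int(((pred == 1) & (y == 1)).sum()),
    )


def fbeta_from_rates(precision: float, sensitivity: float, beta: float = 2.0) -> float:
    """Fβ = (1+β²)·P·S / (β²·P + S); 0 when both rates are 0."""
    denom = beta**2 * precision + sensitivity
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * sensitivity / denom


def fbeta_from_counts(tp: int, fp: int, fn: int, beta: float = 2.0) -> float:
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    return fbeta_from_rates(precision, sensitivity, beta)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC with tie correction (Mann-Whitney U / n0·n1)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("auc needs both classes present")
    ranks = sp_stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def metrics(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    beta: float = 2.0,
) -> MetricsReport:
    """The six evaluation metrics; zero-denominator ratios report 0 with a
    degenerate flag instead of raising."""
    flags: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    specificity = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    sensitivity = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    if scores is not None and labels is not None:
        try:
            auc = auc_score(scores, labels)
        except ValueError:
            flags.append("auc")
            auc = 0.0
    else:
        flags.append("auc")
        auc = 0.0
    return MetricsReport(
        specificity=specificity,
        sensitivity=sensitivity,
        precision=precision,
        f1=fbeta_from_rates(precision, sensitivity, beta=1.0),
        f2=fbeta_from_rates(precision, sensitivity, beta=beta),
        auc=auc,
        beta=beta,
        degenerate=tuple(flags),
    )


# --- sequence container -----------------------------------------------------

@dataclass
class SequenceDataset:
    """Temporal tensors for the recurrent families.

    ``seq``: (n, T, C) standardized channel values with masked steps set to
    0; ``mask``: (n, T) with 1 where the step carries real data; ``static``:
    (n, k) standardized static features or None.
    """

    seq: np.ndarray
    mask: np.ndarray
    static: np.ndarray | None = None

    def __len__(self) -> int:
        return self.seq.shape[0]

    def subset(self, idx: np.ndarray) -> "SequenceDataset":
        return SequenceDataset(
            self.seq[idx],
            self.mask[idx],
            None if self.static is None else self.static[idx],
        )


# --- fitted-model wrappers --------------------------------------------------

class _SklearnModel:
    def __init__(self, clf, mu: np.ndarray, sd: np.ndarray):
        self.clf, self.mu, self.sd = clf, mu, sd

    def score(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mu) / self.sd
        return self.clf.predict_proba(Xs)[:, 1]


class _NetModel:
    def __init__(self, net, family: str):
        self.net, self.family = net, family
        self.mu = None  # set post-training for the flat mlp family
        self.sd = None

    def score(self, data) -> np.ndarray:
        if self.family in SEQUENCE_FAMILIES:
            out = []
            for i in range(len(data)):
                if self.family == "dnn_rnn_mlp":
                    p = self.net.forward(
                        data.seq[i], data.mask[i], static=data.static[i]
                    )
                else:
                    p = self.net.forward(data.seq[i], data.mask[i])
                out.append(float(p.data[0]))
            return np.array(out)
        Xs = np.asarray(data, dtype=float)
        if self.mu is not None:
            Xs = (Xs - self.mu) / self.sd
        return np.array(
            [float(self.net.forward(x).data[0]) for x in Xs]
        )


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def _fit_lasso_logreg(
    X: np.ndarray, y: np.ndarray, weights: dict, spec: ClassifierSpec
) -> LogisticRegression:
    """L1 logistic regression; C chosen by internal 3-fold CV on F2."""
    c_grid = spec.hyperparameters["c_grid"]
    best_c, best_f2 = c_grid[0], -np.inf
    n_per_class = np.bincount(y, minlength=2)
    if n_per_class.min() >= 3 and len(c_grid) > 1:
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=spec.seed)
        for c in c_grid:
            f2s = []
            for tr, te in skf.split(X, y):
                clf = LogisticRegression(
                    l1_ratio=1.0, C=c, solver="saga", max_iter=5000,
                    tol=1e-6, class_weight=weights, random_state=spec.seed,
                )
                clf.fit(X[tr], y[tr])
                prob = clf.predict_proba(X[te])[:, 1]
                cm = confusion(prob, y[te])
                f2s.append(fbeta_from_counts(cm.tp, cm.fp, cm.fn))
            mean_f2 = float(np.mean(f2s))
            if mean_f2 > best_f2:
                best_c, best_f2 = c, mean_f2
    clf = LogisticRegression(
        l1_ratio=1.0, C=best_c, solver="saga", max_iter=5000,
        tol=1e-6, class_weight=weights, random_state=spec.seed,
    )
    clf.fit(X, y)
    return clf


def _train_net(
    net,
    family: str,
    data: SequenceDataset | np.ndarray,
    y: np.ndarray,
    weights: dict,
    val_data,
    val_y: np.ndarray,
    spec: ClassifierSpec,
):
    """Adam / batch-1 / class-weighted BCE with early stopping on val F2."""
    hp = spec.hyperparameters
    rng = np.random.default_rng(spec.seed)
    opt = nn.Adam(net.params, lr=hp["learning_rate"])
    model = _NetModel(net, family)

    def forward_one(i, container, train_rng):
        if family in SEQUENCE_FAMILIES:
            if family == "dnn_rnn_mlp":
                return net.forward(
                    container.seq[i], container.mask[i], rng=train_rng,
                    static=container.static[i],
                )
            return net.forward(container.seq[i], container.mask[i], rng=train_rng)
        return net.forward(container[i], rng=train_rng)

    best_f2, best_state, patience_left = -np.inf, None, hp["patience"]
    n = len(y)
    for epoch in range(hp["max_epochs"]):
        order = rng.permutation(n)
        for i in order:
            opt.zero_grad()
            p = forward_one(int(i), data, rng)
            loss = nn.weighted_bce(p, int(y[i]), weights[int(y[i])])
            loss.backward()
            opt.step()
        val_scores = model.score(val_data)
        cm = confusion(val_scores, val_y)
        f2 = fbeta_from_counts(cm.tp, cm.fp, cm.fn)
        if f2 > best_f2:
            best_f2 = f2
            best_state = [p.data.copy() for p in net.params]
            patience_left = hp["patience"]
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_state is not None:
        for p, saved in zip(net.params, best_state):
            p.data[...] = saved
    log.info("_train_net: %s stopped at epoch %d, best val F2 %.3f",
             family, epoch + 1, best_f2)
    return model


def train(
    spec: ClassifierSpec,
    X,
    y: np.ndarray,
    weights: dict | None = None,
    validation: tuple | None = None,
):
    """Fit one classifier; returns a model exposing ``score(X) -> P(NH)``.

    Features are standardized on training statistics.  The neural families
    require a ``validation=(X_val, y_val)`` pair for F2 early stopping.
    """
    y = np.asarray(y, dtype=int)
    if weights is None:
        weights = class_weights(y)
    if spec.family in SEQUENCE_FAMILIES or spec.family == "mlp":
        if validation is None:
            raise ValueError(f"{spec.family} requires a validation set")
        val_X, val_y = validation
        rng = np.random.default_rng(spec.seed)
        if spec.family == "dnn_rnn":
            net = nn.RnnClassifier(
                X.seq.shape[2], rng, dropout=spec.hyperparameters["dropout"]
            )
        elif spec.family == "dnn_rnn_mlp":
            net = nn.RnnMlpClassifier(
                X.seq.shape[2], X.static.shape[1], rng,
                dropout=spec.hyperparameters["dropout"],
            )
        else:
            X = np.asarray(X, dtype=float)
            mu, sd = _standardize_fit(X)
            net = nn.MlpClassifier(X.shape[1], rng)
            model = _train_net(
                net, spec.family, (X - mu) / sd, y, weights,
                (np.asarray(val_X, dtype=float) - mu) / sd,
                np.asarray(val_y, dtype=int), spec,
            )
            model.mu, model.sd = mu, sd
            return model
        return _train_net(net, spec.family, X, y, weights,
                          val_X, np.asarray(val_y, dtype=int), spec)

    X = np.asarray(X, dtype=float)
    mu, sd = _standardize_fit(X)
    Xs = (X - mu) / sd
    if spec.family == "logreg_lasso":
        clf = _fit_lasso_logreg(Xs, y, weights, spec)
    else:
        clf = RandomForestClassifier(
            n_estimators=spec.hyperparameters["n_estimators"],
            class_weight=weights,
            random_state=spec.seed,
        )
        clf.fit(Xs, y)
    return _SklearnModel(clf, mu, sd)


# --- repeated stratified cross-evaluation ----------------------------------

@dataclass
class CVResult:
    per_run_metrics: list[MetricsReport]
    per_run_scores: list[np.ndarray]  # pooled test predictions, dataset order
    fold_assignments: list[np.ndarray]  # (runs, n) fold index per sample
    mean: dict[str, float]
    sd: dict[str, float]
    per_fold_sd: dict[str, float]
    seeds: list[int]


def make_partitions(
    y: np.ndarray, config: RunConfig
) -> list[np.ndarray]:
    """Stratified fold assignments for each of the ``cv_runs`` runs.

    Derived only from labels and the master seed, so the same partitions can
    be reused across dataset combinations within a run.
    """
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"need >= {config.cv_folds} samples per class, have {counts}"
        )
    assignments = []
    for run in range(config.cv_runs):
        seed = (config.seed * 1000 + run) % 2**31
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=seed
        )
        folds = np.empty(len(y), dtype=int)
        for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            folds[test_idx] = k
        assignments.append(folds)
    return assignments


def _val_split(
    y: np.ndarray, frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified carve-out of a validation subset; returns (train, val) idx."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(y == cls)
        rng.shuffle(cls_idx)
        n_val = max(1, int(round(frac * len(cls_idx))))
        val_idx.extend(cls_idx[:n_val])
        train_idx.extend(cls_idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def run_cv(
    X,
    y: np.ndarray,
    spec: ClassifierSpec,
    config: RunConfig,
    partitions: list[np.ndarray] | None = None,
) -> CVResult:
    """Six-fold stratified cross-evaluation, repeated ``cv_runs`` times.

    Per run the pooled test-fold predictions yield one MetricsReport;
    ``mean``/``sd`` aggregate the runs.  ``per_fold_sd`` additionally reports
    the SD over individual fold F2/F1/AUC within runs.
    """
    y = np.asarray(y, dtype=int)
    is_seq = isinstance(X, SequenceDataset)
    if partitions is None:
        partitions = make_partitions(y, config)
    needs_val = spec.family in SEQUENCE_FAMILIES or spec.family == "mlp"
    per_run, per_run_scores, seeds = [], [], []
    fold_f2s: list[float] = []
    fold_f1s: list[float] = []
    fold_aucs: list[float] = []
    for run, folds in enumerate(partitions):
        run_seed = (config.seed * 1000 + 7 * run + spec.seed) % 2**31
        seeds.append(run_seed)
        scores = np.empty(len(y), dtype=float)
        for k in range(config.cv_folds):
            test_idx = np.flatnonzero(folds == k)
            train_idx = np.flatnonzero(folds != k)
            fold_spec = ClassifierSpec(
                spec.family, dict(spec.hyperparameters),
                seed=(run_seed + k) % 2**31,
            )
            y_tr = y[train_idx]
            if needs_val:
                sub_tr, sub_val = _val_split(
                    y_tr, config.val_fraction, (run_seed + k) % 2**31
                )
                tr_idx, val_idx = train_idx[sub_tr], train_idx[sub_val]
                X_tr = X.subset(tr_idx) if is_seq else np.asarray(X)[tr_idx]
                X_val = X.subset(val_idx) if is_seq else np.asarray(X)[val_idx]
                model = train(
                    fold_spec, X_tr, y[tr_idx],
                    weights=class_weights(y_tr),
                    validation=(X_val, y[val_idx]),
                )
            else:
                X_tr = X.subset(train_idx) if is_seq else np.asarray(X)[train_idx]
                model = train(fold_spec, X_tr, y_tr)
            X_te = X.subset(test_idx) if is_seq else np.asarray(X)[test_idx]
            scores[test_idx] = model.score(X_te)
            cm_k = confusion(scores[test_idx], y[test_idx])
            fold_f2s.append(fbeta_from_counts(cm_k.tp, cm_k.fp, cm_k.fn))
            fold_f1s.append(
                fbeta_from_counts(cm_k.tp, cm_k.fp, cm_k.fn, beta=1.0)
            )
            try:
                fold_aucs.append(auc_score(scores[test_idx], y[test_idx]))
            except ValueError:
                pass
        per_run.append(metrics(confusion(scores, y), scores, y))
        per_run_scores.append(scores)
    keys = ("specificity", "sensitivity", "precision", "f1", "f2", "auc")
    table = {k: np.array([getattr(m, k) for m in per_run]) for k in keys}
    return CVResult(
        per_run_metrics=per_run,
        per_run_scores=per_run_scores,
        fold_assignments=partitions,
        mean={k: float(v.mean()) for k, v in table.items()},
        sd={k: float(v.std(ddof=1)) for k, v in table.items()},
        per_fold_sd={
            "f2": float(np.std(fold_f2s, ddof=1)) if len(fold_f2s) > 1 else 0.0,
            "f1": float(np.std(fold_f1s, ddof=1)) if len(fold_f1s) > 1 else 0.0,
            "auc": float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
        },
        seeds=seeds,
    )


# --- 15-min sliding-window replication scheme -------------------------------

@dataclass(frozen=True)
class SlidingWindow:
    """Offsets in minutes from the night frame start (midnight)."""

    start: int
    end: int  # start + 45
    target_time: int  # end + 15


def berikov_windows(
    frame_min: int = 360,
    window_min: int = 45,
    stride_min: int = 20,
    horizon_min: int = 15,
) -> list[SlidingWindow]:
    """Sliding windows over the 00:00-06:00 night frame.

    Starts at 0, 20, 40, ... while the 15-min-ahead target still falls
    inside the frame; the default yields 16 windows (last 05:00-05:45 →
    target 06:00).
    """
    windows = []
    start = 0
    while start + window_min + horizon_min <= frame_min:
        windows.append(
            SlidingWindow(start, start + window_min,
                          start + window_min + horizon_min)
        )
        start += stride_min
    return windows


def build_berikov_dataset(
    pairs,
    static_by_pid: dict,
    config: RunConfig,
    conga_lag_min: int = 15,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Window-level feature matrix for the replication scheme.

    Per window: the eight glucose-dynamics features on the 45-min glucose
    slice (CONGA at a 15-min lag — a 1-h lag cannot fit the window) plus
    age, BMI and sex.  The label is the sub-threshold state exactly at the
    target time: the grid sample there, or an SMBG within half a grid step.
    Windows whose target sample is absent are skipped.
    """
    import datetime as dt
    from nocturne.glucometrics import glucose_features

    rows, labels, meta = [], [], []
    threshold = config.hypo_threshold
    half_step = pd.Timedelta(minutes=config.grid_step / 2)
    for pair in pairs:
        night = pair.night_glucose
        if len(night.values) == 0:
            continue
        tz = night.values.index.tz
        midnight = pd.Timestamp(
            dt.datetime.combine(pair.date + dt.timedelta(days=1), dt.time(0, 0))
        ).tz_localize(tz)
        static = static_by_pid[pair.participant_id]
        for w in berikov_windows():
            w0 = midnight + pd.Timedelta(minutes=w.start)
            w1 = midnight + pd.Timedelta(minutes=w.end)
            target = midnight + pd.Timedelta(minutes=w.target_time)
            sl = night.values[(night.values.index >= w0) & (night.values.index <= w1)]
            if len(sl) < 4:
                continue
            if target in night.values.index:
                is_hypo = bool(night.values.loc[target] < threshold)
            else:
                continue
            for r in pair.night_smbg:
                if abs(r.timestamp - target) <= half_step and r.value < threshold:
                    is_hypo = True
            try:
                feats = glucose_features(sl, conga_lag_min=conga_lag_min)
            except ValueError:
                continue
            feats["age"] = static.age
            feats["bmi"] = static.bmi
            feats["sex_female"] = 1.0 if static.sex == "female" else 0.0
            rows.append(feats)
            labels.append(int(is_hypo))
            meta.append(
                {
                    "participant_id": pair.participant_id,
                    "date": pair.date.isoformat(),
                    "window_start_min": w.start,
                }
            )
    return pd.DataFrame(rows), np.array(labels, dtype=int), pd.DataFrame(meta)


def run_berikov(
    pairs,
    static_by_pid: dict,
    spec: ClassifierSpec,
    config: RunConfig,
) -> tuple[CVResult | None, pd.DataFrame, np.ndarray]:
    """Replication scheme end-to-end: window dataset → cross-evaluation.

    With a degenerate label distribution (no positive windows) no model is
    trained; the caller receives ``None`` plus the dataset for inspection.
    """
    X, y, meta = build_berikov_dataset(pairs, static_by_pid, config)
    if len(np.unique(y)) < 2 or np.bincount(y, minlength=2).min() < config.cv_folds:
        log.warning(
            "run_berikov: degenerate window labels (counts %s); skipping fit",
            np.bincount(y, minlength=2) if len(y) else "none",
        )
        return None, X, y
    result = run_cv(X.to_numpy(dtype=float), y, spec, config)
    return result, X, y
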