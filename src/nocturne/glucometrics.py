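"""Glucose-dynamics features, a generic time-series feature bank, and
performance-based sequential forward feature selection.

The eight glucose-dynamics statistics are standard clinical
glycemic-variability measures:

coefficient of variation (CV)
    sample SD / mean (dimensionless).
lability index (LI)
    mean over consecutive sample pairs of (ΔG)²/Δt with Δt in hours,
    in (mmol/l)²/h — a swing-rate measure.
low blood glucose index (LBGI)
    mean of the symmetrized low-range risk transform
    f(G) = 1.509·((ln G_mg/dl)^1.084 − 5.381),
    rl(G) = 10·f(G)² when f(G) < 0 else 0,
    with the mmol/l → mg/dl conversion factor 18.016.
CONGA (1 h)
    sample SD of lagged differences G_t − G_{t−lag} at a 60-min lag.
minimal value, last difference, acceleration, linear trend
    window minimum; G_T − G_{T−1}; the second-order backward difference
    G_T − 2·G_{T−1} + G_{T−2} (per grid-step²); OLS slope of G on time in
    mmol/l per hour.

The feature bank is a fixed, named catalogue of generic shape statistics
computed per channel (a compact stand-in for exhaustive automated
time-series featurization, kept small so that wrapper selection stays
tractable); :func:`sequential_select` then greedily grows the best-15 set by
downstream-classifier validation F2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MGDL_PER_MMOLL = 18.016

GLUCOSE_FEATURE_NAMES = (
    "cv",
    "lability_index",
    "lbgi",
    "conga1",
    "min_value",
    "last_diff",
    "acceleration",
    "linear_trend",
)


def glucose_cv(values: pd.Series) -> float:
    """Coefficient of variation: sample SD / mean."""
    if len(values) < 2:
        raise ValueError("cv needs >= 2 samples")
    mean = float(values.mean())
    if mean <= 0:
        raise ValueError(f"cv undefined for mean {mean} <= 0")
    return float(values.std(ddof=1) / mean)


def lability_index(values: pd.Series) -> float:
    """Mean squared glucose change per hour over consecutive samples."""
    if len(values) < 2:
        raise ValueError("lability index needs >= 2 samples")
    t_h = values.index.asi8 / 3.6e12
    dg = np.diff(values.to_numpy(dtype=float))
    dt = np.diff(t_h)
    return float(np.mean(dg**2 / dt))


def _risk_f(g_mgdl: np.ndarray) -> np.ndarray:
    return 1.509 * (np.log(g_mgdl) ** 1.084 - 5.381)


def lbgi(values: pd.Series) -> float:
    """Low blood glucose index (mean symmetrized low-range risk)."""
    g = values.to_numpy(dtype=float)
    if (g <= 0).any():
        raise ValueError("lbgi undefined for non-positive glucose")
    f = _risk_f(g * MGDL_PER_MMOLL)
    rl = np.where(f < 0, 10 * f**2, 0.0)
    return float(rl.mean())


def conga(values: pd.Series, lag_min: int = 60) -> float:
    """Continuous overlapping net glycemic action: sample SD of the
    ``lag_min``-lagged differences."""
    idx = values.index
    span_min = (idx[-1] - idx[0]).total_seconds() / 60
    if span_min <= lag_min:
        raise ValueError(
            f"conga needs a span > {lag_min} min, got {span_min:.0f} min"
        )
    lagged = values.reindex(idx - pd.Timedelta(minutes=lag_min))
    diffs = values.to_numpy(dtype=float) - lagged.to_numpy(dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    if len(diffs) < 2:
        raise ValueError("conga: fewer than 2 lagged differences")
    return float(np.std(diffs, ddof=1))


def tail_features(values: pd.Series) -> tuple[float, float, float, float]:
    """(min_value, last_diff, acceleration, linear_trend).

    ``acceleration`` is the second-order backward difference of the final
    three samples (per grid-step²); ``linear_trend`` the OLS slope of G on
    time in mmol/l per hour over the whole window.
    """
    if len(values) < 3:
        raise ValueError("tail features need >= 3 samples")
    g = values.to_numpy(dtype=float)
    t_h = values.index.asi8 / 3.6e12
    slope = float(np.polyfit(t_h - t_h[0], g, 1)[0])
    return (
        float(g.min()),
        float(g[-1] - g[-2]),
        float(g[-1] - 2 * g[-2] + g[-3]),
        slope,
    )


def glucose_features(
    values: pd.Series, conga_lag_min: int = 60
) -> dict[str, float]:
    """The eight glucose-dynamics statistics as a named dict."""
    mn, last_diff, accel, trend = tail_features(values)
    return {
        "cv": glucose_cv(values),
        "lability_index": lability_index(values),
        "lbgi": lbgi(values),
        "conga1": conga(values, conga_lag_min),
        "min_value": mn,
        "last_diff": last_diff,
        "acceleration": accel,
        "linear_trend": trend,
    }


# --- generic time-series feature bank -------------------------------------

def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for flag in mask:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    return best


def _autocorr(x: np.ndarray, lag: int) -> float:
    n = len(x)
    if n <= lag + 1:
        return 0.0
    x0 = x - x.mean()
    denom = float((x0**2).sum())
    if denom == 0:
        return 0.0
    return float((x0[:-lag] * x0[lag:]).sum() / denom)


BANK_STAT_NAMES = (
    "mean", "sd", "min", "max", "range", "median", "iqr",
    "skewness", "kurtosis", "slope", "energy", "mean_abs_change",
    "longest_run_above_mean", "longest_run_below_mean",
    "count_above_mean", "count_below_mean",
    "autocorr_lag1", "autocorr_lag6", "autocorr_lag12",
    "argmax_frac", "argmin_frac", "empty",
)


def feature_bank(values: pd.Series, channel: str) -> dict[str, float]:
    """Fixed catalogue of shape statistics for one channel.

    The output schema (names and length) is identical for every input; an
    empty or too-short series emits zeros plus the ``empty`` flag so that
    downstream matrices never contain missing cells.
    """
    x = values.dropna().to_numpy(dtype=float)
    prefix = f"{channel}__"
    if len(x) < 3:
        out = {prefix + n: 0.0 for n in BANK_STAT_NAMES}
        out[prefix + "empty"] = 1.0
        return out
    t = np.arange(len(x), dtype=float)
    mean = x.mean()
    above = x > mean
    below = x < mean
    q75, q25 = np.percentile(x, [75, 25])
    out = {
        prefix + "mean": mean,
        prefix + "sd": x.std(ddof=1),
        prefix + "min": x.min(),
        prefix + "max": x.max(),
        prefix + "range": x.max() - x.min(),
        prefix + "median": float(np.median(x)),
        prefix + "iqr": q75 - q25,
        prefix + "skewness": float(stats.skew(x)) if x.std() > 0 else 0.0,
        prefix + "kurtosis": float(stats.kurtosis(x)) if x.std() > 0 else 0.0,
        prefix + "slope": float(np.polyfit(t, x, 1)[0]),
        prefix + "energy": float((x**2).sum()),
        prefix + "mean_abs_change": float(np.abs(np.diff(x)).mean()),
        prefix + "longest_run_above_mean": float(_longest_run(above)),
        prefix + "longest_run_below_mean": float(_longest_run(below)),
        prefix + "count_above_mean": float(above.sum()),
        prefix + "count_below_mean": float(below.sum()),
        prefix + "autocorr_lag1": _autocorr(x, 1),
        prefix + "autocorr_lag6": _autocorr(x, 6),
        prefix + "autocorr_lag12": _autocorr(x, 12),
        prefix + "argmax_frac": float(np.argmax(x) / (len(x) - 1)),
        prefix + "argmin_frac": float(np.argmin(x) / (len(x) - 1)),
        prefix + "empty": 0.0,
    }
    return {k: float(v) for k, v in out.items()}


# --- sequential forward selection ------------------------------------------

@dataclass
class SelectionResult:
    selected: list[str]
    f2_trace: list[float]
    seed: int


def sequential_select(
    X: pd.DataFrame,
    y: np.ndarray,
    n_features: int,
    make_classifier,
    seed: int = 0,
    n_splits: int = 3,
) -> SelectionResult:
    """Greedy forward selection maximizing downstream validation F2.

    At each step the candidate feature whose addition maximizes the mean F2
    of ``make_classifier()`` over an internal stratified ``n_splits``-fold
    split is added; ties break by column order, so the result is
    deterministic under a fixed seed.  The classifier factory should return
    a fresh estimator whose selection scoring matches the model used
    afterward.
    """
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedKFold
    from nocturne.model_eval import confusion, fbeta_from_counts

    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("sequential_select needs both classes present")
    cols = list(X.columns)
    if n_features >= len(cols):
        return SelectionResult(cols, [], seed)

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    def score(subset: list[str]) -> float:
        f2s = []
        Xs = X[subset].to_numpy(dtype=float)
        for tr, te in splits:
            clf = clone(make_classifier())
            mu, sd = Xs[tr].mean(axis=0), Xs[tr].std(axis=0)
            sd[sd == 0] = 1.0
            clf.fit((Xs[tr] - mu) / sd, y[tr])
            prob = clf.predict_proba((Xs[te] - mu) / sd)[:, 1]
            cm = confusion(prob, y[te])
            f2s.append(fbeta_from_counts(cm.tp, cm.fp, cm.fn, beta=2.0))
        return float(np.mean(f2s))

    selected: list[str] = []
    trace: list[float] = []
    remaining = list(cols)
    while len(selected) < n_features and remaining:
        best_col, best_f2 = None, -np.inf
        for col in remaining:  # column order breaks ties
            f2 = score(selected + [col])
            if f2 > best_f2:
                best_col, best_f2 = col, f2
        selected.append(best_col)
        remaining.remove(best_col)
        trace.append(best_f2)
        log.info(
            "sequential_select: step %d -> %s (F2 %.3f)",
            len(selected), best_col, best_f2,
        )
    return SelectionResult(selected, trace, seed)
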