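import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from nocturne.glucometrics import (
    BANK_STAT_NAMES,
    conga,
    feature_bank,
    glucose_cv,
    glucose_features,
    lability_index,
    lbgi,
    sequential_select,
    tail_features,
)
from tests.conftest import make_series


class TestCv:
    def test_constant_series_is_zero(self):
        assert glucose_cv(make_series([5.0] * 10).values) == 0.0

    def test_two_point_closed_form(self):
        # sd = sqrt(2), mean = 5
        assert glucose_cv(make_series([4.0, 6.0]).values) == pytest.approx(
            0.28284, abs=1e-5
        )

    def test_scale_invariance(self):
        g = make_series([4.0, 7.0, 5.5, 6.0]).values
        assert glucose_cv(2 * g) == pytest.approx(glucose_cv(g))

    def test_non_positive_mean_rejected(self):
        s = make_series([1.0, 1.0]).values - 2.0
        with pytest.raises(ValueError):
            glucose_cv(s)


class TestLabilityIndex:
    def test_constant_series_is_zero(self):
        assert lability_index(make_series([5.0] * 5).values) == 0.0

    def test_single_pair_closed_form(self):
        # 5 -> 7 mmol/l in 30 min: (2)^2 / 0.5 h = 8
        s = make_series([5.0, 7.0], step_min=30).values
        assert lability_index(s) == pytest.approx(8.0)

    def test_time_reversal_invariance(self):
        vals = [4.0, 6.5, 5.0, 8.0]
        fwd = lability_index(make_series(vals).values)
        rev = lability_index(make_series(vals[::-1]).values)
        assert fwd == pytest.approx(rev)


class TestLbgi:
    def test_zero_in_euglycemic_range(self):
        # all samples >= 6.25 mmol/l (112.5 mg/dl) -> risk transform >= 0
        assert lbgi(make_series([6.5, 8.0, 12.0]).values) == 0.0

    def test_single_low_sample_closed_form(self):
        # 50 mg/dl: f = 1.509*((ln 50)^1.084 - 5.381) = -1.500 -> rl = 22.50
        s = make_series([50 / 18.016]).values
        assert lbgi(s) == pytest.approx(22.50, abs=0.05)

    def test_lowering_a_sample_never_decreases_lbgi(self):
        base = [5.0, 4.0, 6.0]
        lowered = [5.0, 3.0, 6.0]
        assert lbgi(make_series(lowered).values) >= lbgi(make_series(base).values)

    def test_reorder_invariance(self):
        vals = [3.2, 4.5, 3.8, 6.0]
        assert lbgi(make_series(vals).values) == pytest.approx(
            lbgi(make_series(sorted(vals)).values)
        )


class TestConga:
    def test_constant_series_is_zero(self):
        assert conga(make_series([5.0] * 30).values) == 0.0

    def test_linear_ramp_is_zero(self):
        ramp = np.linspace(4, 10, 30)
        assert conga(make_series(ramp).values) == pytest.approx(0.0, abs=1e-9)

    def test_lag_differences_closed_form(self):
        # hourly samples 0,2,2,0: lag-1h diffs {+2, 0, -2}, sample SD = 2
        s = make_series([0.1, 2.1, 2.1, 0.1], step_min=60).values
        assert conga(s) == pytest.approx(2.0)

    def test_span_not_exceeding_lag_rejected(self):
        with pytest.raises(ValueError, match="span"):
            conga(make_series([5.0] * 12).values)  # 55-min span

    def test_order_sensitivity(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(4, 10, 40)
        shuffled = rng.permutation(vals)
        a = conga(make_series(vals).values)
        b = conga(make_series(shuffled).values)
        assert a != pytest.approx(b)


class TestTailFeatures:
    def test_constant_series(self):
        mn, last_diff, accel, trend = tail_features(make_series([5.0] * 6).values)
        assert (mn, last_diff, accel) == (5.0, 0.0, 0.0)
        assert trend == pytest.approx(0.0, abs=1e-9)

    def test_last_three_values_arithmetic(self):
        mn, last_diff, accel, _ = tail_features(make_series([4.0, 5.0, 7.0]).values)
        assert (mn, last_diff, accel) == (4.0, 2.0, 1.0)

    def test_perfect_line_recovers_slope_per_hour(self):
        # 1 mmol/l per hour at 5-min steps
        vals = 5.0 + np.arange(24) / 12
        *_, trend = tail_features(make_series(vals).values)
        assert trend == pytest.approx(1.0)


class TestTranslationInvariance:
    def test_all_eight_features_ignore_window_position(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(3.5, 12, 144)
        a = glucose_features(make_series(vals, start="2023-07-10 10:00").values)
        b = glucose_features(make_series(vals, start="2023-07-12 08:00").values)
        for k in a:
            assert a[k] == pytest.approx(b[k]), k


class TestFeatureBank:
    def test_schema_stable_across_inputs(self):
        a = feature_bank(make_series([5.0] * 20).values, "glucose")
        rng = np.random.default_rng(0)
        b = feature_bank(
            make_series(rng.uniform(4, 9, 144)).values, "glucose"
        )
        assert list(a) == list(b)
        assert len(a) == len(BANK_STAT_NAMES)

    def test_constant_series_degenerate_stats(self):
        f = feature_bank(make_series([5.0] * 20).values, "g")
        assert f["g__sd"] == 0 and f["g__range"] == 0
        assert f["g__mean_abs_change"] == 0

    def test_alternating_series_mean_abs_change(self):
        f = feature_bank(make_series([0.1, 1.0] * 10).values, "g")
        assert f["g__mean_abs_change"] == pytest.approx(0.9)

    def test_linear_ramp_has_positive_lag1_autocorrelation(self):
        f = feature_bank(make_series(np.arange(20.0)).values, "g")
        assert f["g__autocorr_lag1"] > 0

    def test_empty_input_emits_zeros_with_flag(self):
        f = feature_bank(pd.Series(dtype=float), "g")
        assert f["g__empty"] == 1.0
        assert all(v == 0.0 for k, v in f.items() if k != "g__empty")


def _lr_factory():
    return lambda: LogisticRegression(max_iter=1000, random_state=0)


class TestSequentialSelect:
    def test_label_equal_feature_selected_first(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 15)
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        X["oracle"] = y.astype(float)
        res = sequential_select(X, y, 2, _lr_factory(), seed=0)
        assert res.selected[0] == "oracle"

    def test_requesting_all_columns_returns_original_order(self):
        X = pd.DataFrame(np.zeros((10, 3)), columns=list("abc"))
        y = np.array([0, 1] * 5)
        res = sequential_select(X, y, 5, _lr_factory(), seed=0)
        assert res.selected == ["a", "b", "c"]

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.zeros((6, 2)))
        with pytest.raises(ValueError, match="both classes"):
            sequential_select(X, np.zeros(6, dtype=int), 1, _lr_factory())

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        y = (rng.random(40) < 0.4).astype(int)
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        a = sequential_select(X, y, 3, _lr_factory(), seed=9)
        b = sequential_select(X, y, 3, _lr_factory(), seed=9)
        assert a.selected == b.selected and a.f2_trace == b.f2_trace

    def test_first_step_matches_exhaustive_single_feature_search(self):
        """Greedy step 1 == argmax over all single features scored with the
        same internal splits (brute-force oracle)."""
        from nocturne.model_eval import confusion, fbeta_from_counts

        rng = np.random.default_rng(2)
        n = 60
        y = (rng.random(n) < 0.4).astype(int)
        X = pd.DataFrame(
            {
                "noise1": rng.normal(size=n),
                "weak": y + rng.normal(0, 2.0, n),
                "strong": y + rng.normal(0, 0.3, n),
                "noise2": rng.normal(size=n),
            }
        )
        seed = 4
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(n), y))

        def brute_score(col):
            f2s = []
            Xc = X[[col]].to_numpy(float)
            for tr, te in splits:
                mu, sd = Xc[tr].mean(0), Xc[tr].std(0)
                sd[sd == 0] = 1
                clf = _lr_factory()()
                clf.fit((Xc[tr] - mu) / sd, y[tr])
                prob = clf.predict_proba((Xc[te] - mu) / sd)[:, 1]
                cm = confusion(prob, y[te])
                f2s.append(fbeta_from_counts(cm.tp, cm.fp, cm.fn))
            return np.mean(f2s)

        best = max(X.columns, key=brute_score)
        res = sequential_select(X, y, 1, _lr_factory(), seed=seed)
        assert res.selected[0] == best == "strong"
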