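import numpy as np
import pytest

from nocturne import experiments, model_eval
from nocturne.data_io import RunConfig
from nocturne.experiments import (
    COMBINATIONS,
    ExperimentGrid,
    build_feature_matrix,
    build_sequence_dataset,
    render_overnight_markdown,
    run_overnight_grid,
    run_replication,
)
from nocturne.synthetic_data import SynthConfig, generate


class TestFeatureMatrix:
    def test_literature_combination_has_exactly_eight_features(
        self, default_cohort, default_config
    ):
        X = build_feature_matrix(
            default_cohort, "glucose_literature_features", default_config
        )
        assert X.shape == (66, 8)

    def test_no_missing_cells_in_any_combination(
        self, default_cohort, default_config
    ):
        for combo in COMBINATIONS:
            X = build_feature_matrix(default_cohort, combo, default_config)
            assert not X.isna().any().any(), combo
            assert not X.columns.duplicated().any()

    def test_static_columns_only_in_static_combinations(
        self, default_cohort, default_config
    ):
        X = build_feature_matrix(default_cohort, "glucose", default_config)
        assert "age" not in X.columns
        Xs = build_feature_matrix(default_cohort, "glucose+static", default_config)
        assert {"age", "bmi", "sex_female"} <= set(Xs.columns)


class TestSequenceDataset:
    def test_day_grid_has_144_steps(self, default_cohort, default_config):
        ds = build_sequence_dataset(default_cohort, "glucose", default_config)
        assert ds.seq.shape == (66, 144, 1)
        assert ds.mask.shape == (66, 144)
        assert ds.static is None

    def test_masked_steps_are_zeroed(self, default_cohort, default_config):
        ds = build_sequence_dataset(default_cohort, "glucose", default_config)
        assert (ds.seq[ds.mask == 0] == 0).all()

    def test_static_branch_present_when_requested(
        self, default_cohort, default_config
    ):
        ds = build_sequence_dataset(
            default_cohort, "glucose+static", default_config
        )
        assert ds.static is not None and ds.static.shape == (66, 5)


@pytest.fixture(scope="module")
def small_report(default_cohort, default_config):
    grid = ExperimentGrid(
        dataset_combinations=("glucose_literature_features",),
        families=("random_forest",),
        config=default_config,
    )
    return run_overnight_grid(grid, cohort=default_cohort)


class TestOvernightGrid:
    def test_single_cell_report_has_mean_sd_triple(self, small_report):
        cell = small_report["cells"]["random_forest|glucose_literature_features"]
        assert cell["status"] == "ok"
        assert {"f2", "f1", "auc"} <= set(cell["mean"])
        assert {"f2", "f1", "auc"} <= set(cell["sd"])

    def test_identical_seeds_identical_reports(
        self, default_cohort, default_config, small_report
    ):
        grid = ExperimentGrid(
            dataset_combinations=("glucose_literature_features",),
            families=("random_forest",),
            config=default_config,
        )
        again = run_overnight_grid(grid, cohort=default_cohort)
        assert again["cells"] == small_report["cells"]

    def test_partitions_reused_across_combinations(
        self, default_cohort, default_config
    ):
        grid = ExperimentGrid(
            dataset_combinations=(
                "glucose_literature_features",
                "glucose+static",
            ),
            families=("random_forest",),
            config=default_config,
        )
        # restrict the bank combination to avoid the full selection cost:
        # feature count <= n_features skips selection but keeps the cell
        cohort = default_cohort
        report = run_overnight_grid(
            ExperimentGrid(
                dataset_combinations=("glucose_literature_features",),
                families=("random_forest", "logreg_lasso"),
                config=default_config,
            ),
            cohort=cohort,
        )
        hashes = {
            c["fold_hash"]
            for c in report["cells"].values()
            if c.get("status") == "ok"
        }
        assert len(hashes) == 1

    def test_dnn_not_applicable_to_literature_features(
        self, default_cohort, default_config
    ):
        grid = ExperimentGrid(
            dataset_combinations=("glucose_literature_features",),
            families=("dnn",),
            config=default_config,
        )
        report = run_overnight_grid(grid, cohort=default_cohort)
        assert report["cells"]["dnn|glucose_literature_features"]["status"] == "n.a."

    def test_markdown_rendering_contains_matrix(self, small_report):
        md = render_overnight_markdown(small_report)
        assert "glucose_literature_features" in md
        assert "F2" in md and "AUC" in md

    def test_failed_cell_does_not_abort_grid(self, default_config):
        # a cohort with a single class makes every fit impossible
        bad = ExperimentGrid(
            dataset_combinations=("glucose_literature_features",),
            families=("random_forest",),
            config=default_config,
        )
        cfg = SynthConfig(seed=0, n_participants=2, n_days=2, n_absent_days=0,
                          risk_intercept=-50.0, risk_met_slope=0.0,
                          risk_bedtime_slope=0.0)
        b = generate(cfg)
        cohort = experiments.curate_cohort(
            b.cgm + b.smbg, [], b.static, None, default_config
        )
        report = run_overnight_grid(bad, cohort=cohort)
        cell = report["cells"]["random_forest|glucose_literature_features"]
        assert cell["status"] == "failed"
        assert report["any_failed"]

    def test_activity_signal_improves_f2_under_strong_effect(self):
        """With a large activity effect, adding the daytime MET·h load to the
        glucose features improves cross-validated F2 on most seeds (the
        generator controls the ordering)."""
        wins = 0
        for seed in range(5):
            cfg = SynthConfig(seed=200 + seed, risk_met_slope=0.7,
                              risk_intercept=-9.0)
            b = generate(cfg)
            rc = RunConfig(seed=seed)
            cohort = experiments.curate_cohort(
                b.cgm + b.smbg, b.wearable, b.static, b.activity, rc
            )
            parts = model_eval.make_partitions(cohort.y, rc)
            Xg = build_feature_matrix(cohort, "glucose_literature_features", rc)
            Xp = build_feature_matrix(cohort, "glucose+physio", rc)
            Xgm = Xg.copy()
            Xgm["met_hours"] = Xp["met_hours"]
            f2 = {}
            for name, Xm in (("glucose", Xg), ("glucose_met", Xgm)):
                cv = model_eval.run_cv(
                    Xm.to_numpy(float), cohort.y,
                    model_eval.ClassifierSpec("random_forest", seed=seed),
                    rc, parts,
                )
                f2[name] = cv.mean["f2"]
            wins += f2["glucose_met"] > f2["glucose"]
        assert wins >= 3


class TestReplication:
    def test_report_contains_six_metric_rows(self, default_cohort, default_config):
        grid = ExperimentGrid(
            families=("random_forest",), config=default_config
        )
        report = run_replication(grid, cohort=default_cohort)
        model = report["models"]["random_forest"]
        assert model["status"] == "ok"
        assert set(model["mean"]) == {
            "specificity", "sensitivity", "precision", "f2", "f1", "auc"
        }
        # every full night contributes 16 windows
        assert model["n_windows"] == 16 * len(default_cohort.pairs)

    def test_zero_dip_fixture_is_degenerate(self, default_config):
        cfg = SynthConfig(seed=0, n_participants=3, n_days=3, n_absent_days=0,
                          risk_intercept=-50.0, risk_met_slope=0.0,
                          risk_bedtime_slope=0.0)
        b = generate(cfg)
        cohort = experiments.curate_cohort(
            b.cgm + b.smbg, [], b.static, None, default_config
        )
        grid = ExperimentGrid(families=("random_forest",), config=default_config)
        report = run_replication(grid, cohort=cohort)
        assert report["models"]["random_forest"]["status"] == "degenerate"
        assert report["models"]["random_forest"]["n_positive"] == 0
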