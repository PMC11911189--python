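"""Clinical preprocessing, random forest, importance ranking, tuning."""

import numpy as np
import pandas as pd
import pytest

from lymphrisk.clinical import (
    ClinicalRandomForest,
    ImportanceRanking,
    PreprocessReport,
    RFConfig,
    VariableSchema,
    apply_report,
    predict_proba,
    preprocess,
    rank_features,
    select_features,
    train_rf,
    tune_hyperparameters,
)


@pytest.fixture()
def small_table():
    return pd.DataFrame(
        {
            "label": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
            "mostly_missing": ["A", "", "", None, "A", "B", "", "A", "A", "B"],
            "ldh": [1.0, 2.0, np.nan, 4.0, 3.0, 2.5, 1.5, 3.5, 2.2, 2.8],
            "stage": ["A", "B", "C", "A", None, "B", "C", "A", "B", "C"],
            "response": ["CR", "PD", "CR", "PD", "CR", "PD", "CR", "PD", "CR", "PD"],
        }
    )


@pytest.fixture()
def small_schema():
    return {
        "mostly_missing": VariableSchema(kind="binary", levels=["A", "B"]),
        "ldh": VariableSchema(kind="continuous"),
        "stage": VariableSchema(kind="multicategory", levels=["A", "B", "C"]),
        "response": VariableSchema(kind="multicategory", is_outcome=True),
    }


class TestPreprocess:
    def test_variable_missing_above_one_third_dropped(self, small_table, small_schema):
        X, report = preprocess(small_table, small_schema)
        assert "mostly_missing" in report.dropped_variables
        assert not any(c.startswith("mostly_missing") for c in X.columns)

    def test_outcome_variables_never_enter_design(self, small_table, small_schema):
        X, report = preprocess(small_table, small_schema)
        assert "response" in report.outcome_variables
        assert not any(c.startswith("response") for c in X.columns)
        assert "label" not in X.columns

    def test_continuous_imputed_by_median_of_observed(self):
        table = pd.DataFrame({"label": [0, 1, 0, 1], "v": [1.0, 2.0, np.nan, 4.0]})
        X, report = preprocess(table, {"v": VariableSchema(kind="continuous")})
        assert report.imputation_values["v"] == 2.0
        assert X["v"].tolist() == [1.0, 2.0, 2.0, 4.0]

    def test_mode_ties_break_lexicographically(self):
        table = pd.DataFrame(
            {"label": [0, 1, 0, 1, 0], "v": ["B", "A", "B", "A", None]}
        )
        _, report = preprocess(table, {"v": VariableSchema(kind="binary")})
        assert report.imputation_values["v"] == "A"

    def test_three_level_variable_expands_to_three_onehot_columns(
        self, small_table, small_schema
    ):
        X, _ = preprocess(small_table, small_schema)
        cols = [c for c in X.columns if c.startswith("stage=")]
        assert sorted(cols) == ["stage=A", "stage=B", "stage=C"]
        assert (X[cols].sum(axis=1) == 1.0).all()

    def test_binning_applied_before_encoding(self):
        table = pd.DataFrame({"label": [0, 1, 0, 1], "wbc": [2.0, 5.0, 12.0, 7.0]})
        schema = {
            "wbc": VariableSchema(
                kind="continuous",
                binning=([4.0, 10.0], ["low", "normal", "high"]),
            )
        }
        X, report = preprocess(table, schema)
        assert sorted(c for c in X.columns) == ["wbc=high", "wbc=low", "wbc=normal"]
        assert X.loc[0, "wbc=low"] == 1.0
        assert X.loc[2, "wbc=high"] == 1.0

    def test_replay_reproduces_design_matrix_exactly(self, small_table, small_schema):
        X, report = preprocess(small_table, small_schema)
        X2 = apply_report(small_table, small_schema, report)
        pd.testing.assert_frame_equal(X, X2)

    def test_replay_round_trips_through_json(self, small_table, small_schema):
        X, report = preprocess(small_table, small_schema)
        restored = PreprocessReport.from_json(report.to_json())
        X2 = apply_report(small_table, small_schema, restored)
        pd.testing.assert_frame_equal(X, X2)

    def test_unknown_category_at_replay_is_named(self, small_table, small_schema):
        _, report = preprocess(small_table, small_schema)
        new = small_table.copy()
        new.loc[0, "stage"] = "D"
        with pytest.raises(ValueError, match="D"):
            apply_report(new, small_schema, report)


class TestRanking:
    def _planted(self, rng, n=200, noise_features=10):
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(
            rng.standard_normal((n, noise_features)),
            columns=[f"noise{i}" for i in range(noise_features)],
        )
        X["planted"] = y.astype(float)  # perfectly predictive
        return X, y

    def test_perfect_predictor_ranks_first_across_seeds(self, rng):
        X, y = self._planted(rng)
        for seed in range(10):
            ranking = rank_features(X, y, RFConfig(n_estimators=50, seed=seed))
            assert ranking.features()[0] == "planted"

    def test_constant_feature_has_zero_importance(self, rng):
        X, y = self._planted(rng)
        X["constant"] = 1.0
        ranking = rank_features(X, y, RFConfig(seed=0))
        assert dict(ranking.pairs)["constant"] == 0.0

    def test_importances_sum_to_one(self, rng):
        X, y = self._planted(rng)
        ranking = rank_features(X, y, RFConfig(seed=1))
        assert sum(v for _, v in ranking.pairs) == pytest.approx(1.0, abs=1e-6)

    def test_selection_drops_zero_importance_keeps_planted(self, rng):
        X, y = self._planted(rng)
        X["constant"] = 0.0
        ranking = rank_features(X, y, RFConfig(seed=2))
        selected = select_features(ranking)
        assert "planted" in selected
        assert "constant" not in selected

    def test_empty_selection_is_error(self):
        ranking = ImportanceRanking([("a", 0.0), ("b", 0.0)])
        with pytest.raises(ValueError, match="empty"):
            select_features(ranking)


class TestForest:
    def test_overfit_deep_forest_memorises_training_point(self, rng):
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        model = train_rf(X, y, RFConfig(n_estimators=50, max_depth=20, seed=0))
        p = predict_proba(model, [[1.0]])
        assert p[0] > 0.9

    def test_probabilities_complementary(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 3)))
        y = rng.integers(0, 2, 50)
        model = train_rf(X, y, RFConfig(seed=0))
        both = model.predict_proba(X.to_numpy())
        np.testing.assert_allclose(both.sum(axis=1), 1.0)

    def test_feature_count_mismatch_at_predict(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)))
        y = rng.integers(0, 2, 30)
        model = train_rf(X, y, RFConfig(seed=0))
        with pytest.raises(ValueError, match="mismatch"):
            predict_proba(model, np.ones((2, 5)))

    def test_single_class_labels_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError, match="single-class"):
            train_rf(X, np.ones(10, int), RFConfig(seed=0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RFConfig(n_estimators=0)
        with pytest.raises(ValueError):
            RFConfig(min_samples_split=1)


class TestTuning:
    def _data(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.standard_normal((n, 5)))
        X[0] += y * 1.5
        return X, y

    def test_single_trial_returns_the_sampled_config(self, rng):
        X, y = self._data(rng)
        best, log = tune_hyperparameters(
            X[:80], y[:80], X[80:], y[80:], n_trials=1, seed=3
        )
        assert len(log) == 1
        assert log[0]["config"]["n_estimators"] == best.n_estimators

    def test_trial_log_has_n_trials_entries(self, rng):
        X, y = self._data(rng)
        _, log = tune_hyperparameters(
            X[:80], y[:80], X[80:], y[80:], n_trials=12, seed=0
        )
        assert len(log) == 12
        assert [e["trial"] for e in log] == list(range(12))

    def test_best_at_least_matches_default_config(self, rng):
        X, y = self._data(rng)
        Xt, yt, Xv, yv = X[:80], y[:80], X[80:], y[80:]
        best, log = tune_hyperparameters(Xt, yt, Xv, yv, n_trials=20, seed=1)
        default = train_rf(Xt, yt, RFConfig(seed=1))
        base_acc = float((default.predict(Xv.to_numpy()) == yv).mean())
        best_acc = max(e["val_accuracy"] for e in log)
        assert best_acc >= base_acc - 1e-12

    def test_empty_space_is_error(self, rng):
        X, y = self._data(rng)
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, X, y, n_trials=0)


class TestRecovery:
    def test_rf_recovers_planted_logistic_signal(self):
        # log-OR 1.0 per SD on 3 of 20 continuous covariates, n=400
        from lymphrisk.experiments import clinical_recovery_experiment

        assert clinical_recovery_experiment(seed=11)["auroc"] >= 0.75

    def test_predictions_independent_of_never_split_feature(self, rng):
        X = pd.DataFrame(
            {"signal": rng.standard_normal(100), "constant": np.zeros(100)}
        )
        y = (X["signal"] > 0).astype(int)
        model = train_rf(X, y, RFConfig(n_estimators=30, seed=0))
        assert dict(
            zip(X.columns, model.feature_importances_)
        )["constant"] == 0.0
        X2 = X.copy()
        X2["constant"] = 99.0  # the forest never split on it
        np.testing.assert_array_equal(
            model.predict_proba(X.to_numpy()), model.predict_proba(X2.to_numpy())
        )


class TestModelFacade:
    def test_fit_produces_report_ranking_and_predictions(self, rng):
        n = 80
        y = rng.integers(0, 2, n)
        table = pd.DataFrame(
            {
                "label": y,
                "age": rng.normal(60, 10, n) + 5 * y,
                "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            }
        )
        schema = {
            "age": VariableSchema(kind="continuous"),
            "sex": VariableSchema(kind="binary", levels=["F", "M"]),
        }
        res = ClinicalRandomForest.from_dataframe(table, schema).fit(
            RFConfig(n_estimators=40, seed=0)
        )
        proba = res.predict_proba(table)
        assert proba.shape == (n,)
        assert ((proba >= 0) & (proba <= 1)).all()
        text = res.summary()
        assert "Gini" in text and "age" in text
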