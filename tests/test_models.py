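"""Learner contracts and LOSO-CV structural invariants."""

import numpy as np
import pandas as pd
import pytest

from actimet.evaluation import mape, rmse
from actimet.models import (
    ModelConfig,
    holdout_evaluate,
    loso_cv,
    predict,
    train,
)

ALGOS = ("rf", "svm_rbf", "ann")


def _flat_table(n=300, seed=0, subjects=("A",)):
    rng = np.random.default_rng(seed)
    tab = pd.DataFrame(
        {
            "f1": rng.normal(size=n),
            "f2": rng.normal(size=n),
            "participant_id": np.resize(list(subjects), n),
            "window_start_s": np.arange(n) * 10.0,
            "ree_kcal_min": 0.6,
        }
    )
    return tab


class TestTrainPredict:
    @pytest.mark.parametrize("algo", ALGOS)
    def test_constant_target_reproduced(self, algo):
        tab = _flat_table()
        tab["ee_kcal_min"] = 2.0
        tol = 1e-6 if algo == "rf" else 1e-3
        run = train(ModelConfig(algorithm=algo, site="hip", seed=5),
                    tab, selected_features=["f1", "f2"])
        assert np.abs(predict(run, tab) - 2.0).max() < tol

    @pytest.mark.parametrize("algo", ALGOS)
    def test_deterministic_given_seed(self, algo):
        tab = _flat_table(seed=1)
        tab["ee_kcal_min"] = 1.5 + 0.5 * tab["f1"] + 0.1 * np.random.default_rng(2).normal(size=len(tab))
        cfg = ModelConfig(algorithm=algo, site="hip", seed=11)
        p1 = predict(train(cfg, tab, selected_features=["f1", "f2"]), tab)
        p2 = predict(train(cfg, tab, selected_features=["f1", "f2"]), tab)
        assert np.array_equal(p1, p2)

    @pytest.mark.parametrize("algo", ALGOS)
    def test_linear_rule_learnable(self, algo):
        """y = 2*x1 noiseless: held-out RMSE far below SD(y) for every learner."""
        rng = np.random.default_rng(3)
        tab = _flat_table(n=2000, seed=3)
        tab["ee_kcal_min"] = 2.0 * tab["f1"] + 5.0
        fit, held = tab.iloc[:1500], tab.iloc[1500:]
        run = train(ModelConfig(algorithm=algo, site="hip", seed=5),
                    fit, selected_features=["f1"])
        err = rmse(predict(run, held), np.clip(held["ee_kcal_min"], 0, None))
        assert err < 0.05 * tab["ee_kcal_min"].std()

    def test_predictions_clipped_at_zero(self):
        tab = _flat_table(n=200, seed=4)
        tab["ee_kcal_min"] = np.clip(tab["f1"], 0, None)  # many zeros, linear above
        run = train(ModelConfig(algorithm="ann", site="hip", seed=5),
                    tab, selected_features=["f1"])
        probe = tab.copy()
        probe["f1"] = -5.0
        assert (predict(run, probe) >= 0).all()

    def test_missing_feature_rejected(self):
        tab = _flat_table()
        tab["ee_kcal_min"] = 1.0
        run = train(ModelConfig(algorithm="rf", site="hip", seed=5,
                                hyperparameters={"n_trees": 20}),
                    tab, selected_features=["f1"])
        with pytest.raises(ValueError):
            predict(run, tab.drop(columns=["f1"]))

    def test_empty_prediction(self):
        tab = _flat_table()
        tab["ee_kcal_min"] = 1.0
        run = train(ModelConfig(algorithm="rf", site="hip", seed=5,
                                hyperparameters={"n_trees": 20}),
                    tab, selected_features=["f1", "f2"])
        assert predict(run, tab.iloc[0:0]).size == 0

    def test_in_sample_rf_optimistic(self, cohort6_hip_table, fast_rf_config):
        tab = cohort6_hip_table
        run = train(fast_rf_config, tab)
        in_sample = rmse(predict(run, tab), tab["ee_kcal_min"])
        held = loso_cv(fast_rf_config, tab).summary()["rmse_kcal_mean"]
        assert in_sample < held


class TestLoso:
    def test_fold_partition_and_leakage(self, cohort6_hip_table, fast_rf_config):
        """n subjects -> n folds; each subject tested exactly once."""
        cv = loso_cv(fast_rf_config, cohort6_hip_table)
        subjects = set(cohort6_hip_table["participant_id"])
        assert set(cv.per_subject["participant_id"]) == subjects
        assert len(cv.per_subject) == len(subjects)
        # per-subject prediction rows cover each subject's windows exactly
        counts = cv.predictions.groupby("participant_id").size()
        expected = cohort6_hip_table.groupby("participant_id").size()
        assert counts.sort_index().equals(expected.sort_index())

    def test_metrics_recomputable_from_predictions(self, cohort6_hip_table,
                                                   fast_rf_config):
        cv = loso_cv(fast_rf_config, cohort6_hip_table)
        for _, row in cv.per_subject.iterrows():
            p = cv.predictions[cv.predictions["participant_id"] == row["participant_id"]]
            assert rmse(p["ee_pred_kcal_min"], p["ee_obs_kcal_min"]) == pytest.approx(
                row["rmse_kcal"]
            )
            assert mape(p["ee_pred_kcal_min"], p["ee_obs_kcal_min"])[0] == pytest.approx(
                row["mape"]
            )

    def test_met_metrics_are_ree_scaled(self, cohort6_hip_table, fast_rf_config):
        cv = loso_cv(fast_rf_config, cohort6_hip_table)
        ree = cohort6_hip_table.groupby("participant_id")["ree_kcal_min"].first()
        for _, row in cv.per_subject.iterrows():
            assert row["rmse_met"] == pytest.approx(
                row["rmse_kcal"] / ree[row["participant_id"]]
            )

    def test_single_subject_rejected(self, fast_rf_config):
        tab = _flat_table(subjects=("A",))
        tab["ee_kcal_min"] = 1.0
        with pytest.raises(ValueError):
            loso_cv(fast_rf_config, tab)


class TestHoldout:
    def test_disjoint_evaluation_and_overlap_guard(self, cohort6_hip_table,
                                                   fast_rf_config):
        tab = cohort6_hip_table
        subjects = sorted(tab["participant_id"].unique())
        fit_tab = tab[tab["participant_id"].isin(subjects[:4])]
        held_tab = tab[tab["participant_id"].isin(subjects[4:])]
        run = train(fast_rf_config, fit_tab)
        res = holdout_evaluate([run], held_tab, subjects[:4])
        assert set(res[fast_rf_config.name].per_subject["participant_id"]) == set(subjects[4:])
        with pytest.raises(ValueError):
            holdout_evaluate([run], held_tab, subjects)  # overlapping ids

    def test_holdout_metrics_match_evaluation_module(self, cohort6_hip_table,
                                                     fast_rf_config):
        """Cross-module consistency: exported predictions reproduce metrics."""
        tab = cohort6_hip_table
        subjects = sorted(tab["participant_id"].unique())
        run = train(fast_rf_config, tab[tab["participant_id"].isin(subjects[:4])])
        res = holdout_evaluate(
            [run], tab[tab["participant_id"].isin(subjects[4:])], subjects[:4]
        )[fast_rf_config.name]
        for _, row in res.per_subject.iterrows():
            p = res.predictions[res.predictions["participant_id"] == row["participant_id"]]
            assert rmse(p["ee_pred_kcal_min"], p["ee_obs_kcal_min"]) == pytest.approx(
                row["rmse_kcal"]
            )
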