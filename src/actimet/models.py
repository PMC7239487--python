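"""EE prediction models and leave-one-subject-out cross-validation.

Three learner configurations are supported, with hyperparameters fixed at
the values reported as optimal for preschool EE prediction: a random
forest (500 trees, 3 features sampled per split), an RBF-kernel support
vector regressor (cost 6.0, gamma 0.1) and a single-hidden-layer neural
network (11 neurons, weight decay 0.1).  SVM and ANN inputs are
standardised with training-fold statistics; the forest consumes raw
features.  Predictions are clipped below at zero — EE is physically
non-negative.

Two provenance arms mirror the study design: ``free_living`` models use
per-fold (nested) mRMR selection, while ``retrained_lab`` models reuse the
laboratory architectures refit on the free-living data with a feature set
selected once on the pooled training windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .evaluation import mape, rmse
from .selection import SelectionResult, mrmr_select

ALGORITHMS = ("rf", "svm_rbf", "ann")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "rf": {"n_trees": 500, "mtry": 3},
    "svm_rbf": {"cost": 6.0, "gamma": 0.1, "epsilon": 0.1},
    "ann": {"neurons": 11, "weight_decay": 0.1, "max_iter": 500},
}

META_COLUMNS = {"participant_id", "site", "window_start_s", "activity",
                "ree_kcal_min", "ee_kcal_min", "met"}


@dataclass(frozen=True)
class ModelConfig:
    """One learner configuration of the study design."""

    algorithm: str
    site: str
    provenance: str = "free_living"
    k_features: int = 20
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.site not in ("hip", "wrist"):
            raise ValueError("site must be 'hip' or 'wrist'")
        if self.provenance not in ("free_living", "retrained_lab"):
            raise ValueError("provenance must be 'free_living' or 'retrained_lab'")
        merged = {**DEFAULT_HYPERPARAMETERS[self.algorithm], **self.hyperparameters}
        object.__setattr__(self, "hyperparameters", merged)

    @property
    def name(self) -> str:
        return f"{self.provenance}_{self.site}_{self.algorithm}_k{self.k_features}"


def build_estimator(config: ModelConfig):
    """scikit-learn estimator implementing a :class:`ModelConfig`."""
    hp = config.hyperparameters
    if config.algorithm == "rf":
        return RandomForestRegressor(
            n_estimators=int(hp["n_trees"]),
            max_features=int(hp["mtry"]),
            random_state=config.seed,
            n_jobs=1,
        )
    if config.algorithm == "svm_rbf":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svr", SVR(kernel="rbf", C=float(hp["cost"]),
                            gamma=float(hp["gamma"]), epsilon=float(hp["epsilon"]))),
            ]
        )
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("mlp", MLPRegressor(
                hidden_layer_sizes=(int(hp["neurons"]),),
                alpha=float(hp["weight_decay"]),
                solver="lbfgs",
                max_iter=int(hp["max_iter"]),
                random_state=config.seed,
            )),
        ]
    )


@dataclass
class ModelRun:
    """A fitted predictor with the exact feature list it consumes."""

    config: ModelConfig
    selected_features: list[str]
    estimator: object
    n_windows: int
    n_subjects: int
    selection: SelectionResult | None = None


def train(
    config: ModelConfig,
    table: pd.DataFrame,
    selected_features: Sequence[str] | None = None,
    target: str = "ee_kcal_min",
    selection_method: str = "f_quotient",
) -> ModelRun:
    """Fit a model on a labelled window table.

    When ``selected_features`` is omitted, mRMR selection with
    ``config.k_features`` is run on ``table`` first.
    """
    if len(table) == 0:
        raise ValueError("empty training table")
    selection = None
    if selected_features is None:
        selection = mrmr_select(table, config.k_features, target=target,
                                method=selection_method)
        selected_features = selection.ordered_features
    selected_features = list(selected_features)
    missing = [f for f in selected_features if f not in table.columns]
    if missing:
        raise ValueError(f"training table lacks features: {missing}")

    X = table[selected_features].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)
    est = build_estimator(config)
    est.fit(X, y)
    return ModelRun(
        config=config,
        selected_features=selected_features,
        estimator=est,
        n_windows=len(table),
        n_subjects=table["participant_id"].nunique() if "participant_id" in table else 1,
        selection=selection,
    )


def predict(run: ModelRun, table: pd.DataFrame) -> np.ndarray:
    """Predict EE (kcal/min) for each window; clipped below at 0."""
    if len(table) == 0:
        return np.empty(0)
    missing = [f for f in run.selected_features if f not in table.columns]
    if missing:
        raise ValueError(f"prediction table lacks features: {missing}")
    X = table[run.selected_features].to_numpy(dtype=float)
    return np.clip(run.estimator.predict(X), 0.0, None)


@dataclass
class CVResult:
    """Per-subject error metrics and their across-subject summary."""

    per_subject: pd.DataFrame
    predictions: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> dict[str, float]:
        s = self.per_subject
        return {
            "rmse_kcal_mean": float(s["rmse_kcal"].mean()),
            "rmse_kcal_sd": float(s["rmse_kcal"].std(ddof=1)),
            "rmse_met_mean": float(s["rmse_met"].mean()),
            "rmse_met_sd": float(s["rmse_met"].std(ddof=1)),
            "mape_mean": float(s["mape"].mean()),
            "mape_sd": float(s["mape"].std(ddof=1)),
            "n_subjects": int(len(s)),
        }


def _subject_metrics(sub: pd.DataFrame, pred: np.ndarray, target: str) -> dict:
    obs = sub[target].to_numpy(dtype=float)
    ree = float(sub["ree_kcal_min"].iloc[0]) if "ree_kcal_min" in sub else np.nan
    mape_val, n_excl = mape(pred, obs)
    return {
        "rmse_kcal": rmse(pred, obs),
        "rmse_met": rmse(pred / ree, obs / ree) if np.isfinite(ree) else np.nan,
        "mape": mape_val,
        "n_windows": len(sub),
        "n_zero_obs_excluded": n_excl,
    }


def loso_cv(
    config: ModelConfig,
    table: pd.DataFrame,
    target: str = "ee_kcal_min",
    nested_selection: bool = True,
    fixed_features: Sequence[str] | None = None,
    selection_method: str = "f_quotient",
) -> CVResult:
    """Leave-one-subject-out cross-validation.

    Each subject is predicted by a model fit on every other subject's
    windows.  By default mRMR selection is re-run inside each training fold
    (leakage-safe); with ``nested_selection=False`` a single feature set —
    ``fixed_features`` if given, else a pooled-table selection — is reused
    across folds.
    """
    subjects = list(pd.unique(table["participant_id"]))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least two subjects")
    counts = table.groupby("participant_id").size()
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"subjects without labelled windows: {list(empty.index)}")

    if not nested_selection and fixed_features is None:
        fixed_features = mrmr_select(
            table, config.k_features, target=target, method=selection_method
        ).ordered_features

    rows = []
    pred_frames = []
    for subject in subjects:
        test = table[table["participant_id"] == subject]
        train_tab = table[table["participant_id"] != subject]
        assert subject not in set(train_tab["participant_id"]), "subject leakage"
        run = train(
            config, train_tab,
            selected_features=None if nested_selection else fixed_features,
            target=target, selection_method=selection_method,
        )
        pred = predict(run, test)
        rows.append({"participant_id": subject, **_subject_metrics(test, pred, target)})
        pred_frames.append(
            pd.DataFrame(
                {
                    "participant_id": subject,
                    "window_start_s": test["window_start_s"].to_numpy(),
                    "ee_obs_kcal_min": test[target].to_numpy(dtype=float),
                    "ee_pred_kcal_min": pred,
                }
            )
        )
    return CVResult(
        per_subject=pd.DataFrame(rows),
        predictions=pd.concat(pred_frames, ignore_index=True),
    )


def holdout_evaluate(
    runs: Sequence[ModelRun],
    holdout_table: pd.DataFrame,
    train_subjects: Sequence[str],
    target: str = "ee_kcal_min",
) -> dict[str, CVResult]:
    """Evaluate fitted models on a disjoint hold-out sample.

    Raises if any hold-out subject also appears in ``train_subjects``.
    Returns one :class:`CVResult` per model, keyed by the config name.
    """
    holdout_subjects = set(pd.unique(holdout_table["participant_id"]))
    overlap = holdout_subjects & set(train_subjects)
    if overlap:
        raise ValueError(f"hold-out subjects overlap training sample: {sorted(overlap)}")

    out: dict[str, CVResult] = {}
    for run in runs:
        rows = []
        pred_frames = []
        for subject, sub in holdout_table.groupby("participant_id", sort=False):
            pred = predict(run, sub)
            rows.append({"participant_id": subject, **_subject_metrics(sub, pred, target)})
            pred_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": subject,
                        "window_start_s": sub["window_start_s"].to_numpy(),
                        "ee_obs_kcal_min": sub[target].to_numpy(dtype=float),
                        "ee_pred_kcal_min": pred,
                    }
                )
            )
        out[run.config.name] = CVResult(
            per_subject=pd.DataFrame(rows),
            predictions=pd.concat(pred_frames, ignore_index=True),
        )
    return out
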