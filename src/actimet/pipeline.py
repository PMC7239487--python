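"""End-to-end orchestration: simulate -> preprocess -> features -> select ->
train -> evaluate, with deterministic seed splitting and artifact output.

All stage seeds derive from the master seed via ``numpy`` ``SeedSequence``
spawning, so a run is a pure function of its :class:`~actimet.config.RunConfig`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .calorimetry import RestingEE, criterion_ee, schofield_ree
from .config import RunConfig
from .evaluation import bland_altman, rm_anova, session_total
from .features import extract_features, synchronize
from .models import CVResult, ModelConfig, holdout_evaluate, loso_cv, train
from .records import SyntheticSession
from .selection import mrmr_select
from .synthetic import default_schedule, make_cohort, synthesize_session

logger = logging.getLogger(__name__)


def _stage_seed(master: int, index: int) -> int:
    state = np.random.SeedSequence([master & 0x7FFFFFFF, index]).generate_state(1)
    return int(state[0] & 0x7FFFFFFF)


def simulate_cohort(config: RunConfig) -> tuple[list[SyntheticSession], dict[str, str]]:
    """Generate the full cohort's sessions and the train/hold-out split."""
    n = config.n_train + config.n_holdout
    cohort = make_cohort(n, seed=_stage_seed(config.seed, 0))
    rng_split = np.random.default_rng(_stage_seed(config.seed, 1))
    order = rng_split.permutation(n)
    groups = {
        cohort[i].id: ("train" if rank < config.n_train else "holdout")
        for rank, i in enumerate(order)
    }
    sessions = []
    for i, participant in enumerate(cohort):
        sched = default_schedule(
            seed=_stage_seed(config.seed, 100 + i),
            session_length_s=config.session_length_s,
            met_targets=config.session.met_targets,
        )
        sessions.append(
            synthesize_session(
                participant, sched, seed=_stage_seed(config.seed, 1000 + i),
                params=config.session,
            )
        )
    return sessions, groups


def label_session(
    session: SyntheticSession,
    site: str,
    sync_tolerance_s: float = 0.0,
) -> pd.DataFrame:
    """Labelled feature table for one session and wear site.

    Extracts the window features, runs the calorimetry criterion on the
    session's breaths (binned on the accelerometer's 10-s grid), and joins
    the two by window start time.  Adds participant metadata and the
    generator's per-slot activity label (used only by diagnostics such as
    the noise floor — never as a model feature).
    """
    rec = session.recording(site)
    feats = extract_features(rec)
    ree = RestingEE(ree_kcal_per_day=session.ree_kcal_min * 1440.0)
    ee = criterion_ee(session.breaths, ree=ree, origin_s=0.0,
                      span_s=session.duration_s)
    labelled, dropped = synchronize(feats, ee, tolerance_s=sync_tolerance_s)
    if dropped:
        logger.info("%s/%s: %d windows dropped in synchronization",
                    session.participant.id, site, dropped)
    truth = session.truth.set_index("slot_start_s")
    labelled.insert(0, "participant_id", session.participant.id)
    labelled.insert(1, "site", site)
    labelled["ree_kcal_min"] = session.ree_kcal_min
    labelled["activity"] = (
        truth["activity"].reindex(labelled["window_start_s"].to_numpy()).to_numpy()
    )
    return labelled


def build_tables(
    sessions: list[SyntheticSession],
    groups: dict[str, str] | None = None,
    sites: tuple[str, ...] = ("hip", "wrist"),
    sync_tolerance_s: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Pooled labelled tables per site (optionally filtered by group)."""
    tables: dict[str, pd.DataFrame] = {}
    for site in sites:
        frames = []
        for session in sessions:
            if groups is not None and groups.get(session.participant.id) is None:
                continue
            frames.append(label_session(session, site, sync_tolerance_s))
        tables[site] = pd.concat(frames, ignore_index=True)
    return tables


def _model_config(spec: dict, config: RunConfig, index: int) -> ModelConfig:
    hp = dict(config.hyperparameter_overrides.get(spec["algorithm"], {}))
    return ModelConfig(
        algorithm=spec["algorithm"],
        site=spec["site"],
        provenance=spec.get("provenance", "free_living"),
        k_features=int(spec.get("k", 20)),
        hyperparameters=hp,
        seed=_stage_seed(config.seed, 5000 + index),
    )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the full study replication and write all artifacts.

    Returns the run directory, which contains the serialized config, the
    cohort manifest, per-site labelled feature tables, mRMR selection
    reports, LOSO and hold-out metrics, exported predicted/observed pairs,
    the across-model repeated-measures ANOVA and per-model Bland-Altman
    agreement on session totals.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    logger.info("stage: simulate")
    sessions, groups = simulate_cohort(config)
    aio.write_cohort_manifest([s.participant for s in sessions], groups,
                              out / "cohort_manifest.csv")
    if config.write_raw:
        raw_dir = out / "raw"
        for session in sessions:
            aio.write_session(session, raw_dir)

    logger.info("stage: preprocess + features")
    tables = build_tables(sessions, sync_tolerance_s=config.sync_tolerance_s)
    for site, table in tables.items():
        table.to_csv(out / f"features_{site}.csv", index=False)
    train_tables = {
        s: t[t["participant_id"].map(groups).eq("train")].reset_index(drop=True)
        for s, t in tables.items()
    }
    holdout_tables = {
        s: t[t["participant_id"].map(groups).eq("holdout")].reset_index(drop=True)
        for s, t in tables.items()
    }

    logger.info("stage: select")
    sel_dir = out / "selection"
    sel_dir.mkdir(exist_ok=True)
    for site, table in train_tables.items():
        for k in config.selection_k:
            res = mrmr_select(table, k, method=config.selection_method)
            res.to_frame().to_csv(sel_dir / f"mrmr_{site}_k{k}.csv", index=False)

    logger.info("stage: train + evaluate")
    metrics: dict[str, dict] = {}
    loso_results: dict[str, CVResult] = {}
    runs = []
    train_subjects = [pid for pid, g in groups.items() if g == "train"]
    for i, spec in enumerate(config.model_specs):
        mc = _model_config(spec, config, i)
        table = train_tables[mc.site]
        nested = config.nested_selection and mc.provenance == "free_living"
        cv = loso_cv(mc, table, nested_selection=nested,
                     selection_method=config.selection_method)
        loso_results[mc.name] = cv
        metrics[mc.name] = {"loso": cv.summary()}
        cv.predictions.to_csv(out / f"predictions_loso_{mc.name}.csv", index=False)
        # final model on the full training sample, for hold-out evaluation
        runs.append(train(mc, table, selection_method=config.selection_method))

    anova_table = None
    if config.n_holdout >= 2:
        per_model_holdout: dict[str, CVResult] = {}
        for run in runs:
            res = holdout_evaluate([run], holdout_tables[run.config.site],
                                   train_subjects)[run.config.name]
            per_model_holdout[run.config.name] = res
            metrics[run.config.name]["holdout"] = res.summary()
            res.predictions.to_csv(
                out / f"predictions_holdout_{run.config.name}.csv", index=False
            )

        # across-model RM-ANOVA on per-subject hold-out RMSE
        anova_table = pd.DataFrame(
            {
                name: res.per_subject.set_index("participant_id")["rmse_kcal"]
                for name, res in per_model_holdout.items()
            }
        )
        anova = rm_anova(anova_table)
        metrics["rm_anova_holdout_rmse"] = {
            "f": anova.f_stat, "df_model": anova.df_model,
            "df_error": anova.df_error, "p": anova.p_value,
        }
        if anova.pairwise is not None:
            anova.pairwise.to_csv(out / "fisher_lsd.csv", index=False)

        # Bland-Altman agreement on session totals, per model
        if config.n_holdout >= 3:
            ba_out = {}
            for name, res in per_model_holdout.items():
                totals = res.predictions.groupby("participant_id").agg(
                    obs=("ee_obs_kcal_min", lambda v: session_total(v)),
                    pred=("ee_pred_kcal_min", lambda v: session_total(v)),
                )
                agr = bland_altman(totals["obs"], totals["pred"],
                                   at_kcal=config.bland_altman_at_kcal)
                ba_out[name] = {
                    "n": agr.n,
                    "mean_bias_pct": agr.mean_bias_pct,
                    "loa_pct": [agr.loa_low_pct, agr.loa_high_pct],
                    "mean_bias_kcal": agr.mean_bias_kcal,
                    "loa_kcal": [agr.loa_low_kcal, agr.loa_high_kcal],
                    "prop_bias_r": agr.prop_bias_r,
                    "fit_slope": agr.fit_slope,
                    "fit_intercept": agr.fit_intercept,
                    "prediction_limits": agr.prediction_limits.to_dict("records"),
                }
            (out / "bland_altman.json").write_text(json.dumps(ba_out, indent=2))

    provenance = {"config_hash": config.config_hash(), "seed": config.seed}
    (out / "metrics.json").write_text(
        json.dumps({"provenance": provenance, "models": metrics}, indent=2)
    )
    logger.info("run complete: %s", out)
    return out
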