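"""Prediction-accuracy metrics and agreement statistics.

Implements the evaluation battery used for free-living EE models: RMSE and
MAPE per subject, session-total EE, Bland-Altman agreement on session
totals (mean bias, 95% limits of agreement, proportional-bias regression
with magnitude-specific prediction limits), and a one-way repeated-measures
ANOVA across models with Fisher-LSD pairwise follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


def rmse(pred, obs) -> float:
    """Root-mean-square error, in the units of the inputs."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def mape(pred, obs) -> tuple[float, int]:
    """Mean absolute percent error relative to observed values.

    Observations equal to zero carry an undefined percent error; they are
    excluded and their count returned alongside the statistic.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    ok = obs != 0
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("all observed values are zero; MAPE undefined")
    value = float(np.mean(np.abs(pred[ok] - obs[ok]) / np.abs(obs[ok])) * 100.0)
    return value, n_excluded


def session_total(ee_kcal_min, bin_s: float = 10.0) -> float:
    """Total kcal over a session from an EE series at ``bin_s`` resolution."""
    ee = np.asarray(ee_kcal_min, dtype=float)
    if ee.size == 0:
        raise ValueError("empty EE series")
    return float(ee.sum() * bin_s / 60.0)


@dataclass
class AgreementResult:
    """Bland-Altman agreement between observed and predicted session totals.

    Differences are observed - predicted expressed as percent of observed
    (matching agreement plots of percent error against observed kcal); the
    raw-kcal mean bias and LOA are reported alongside.
    """

    n: int
    mean_bias_pct: float
    loa_low_pct: float
    loa_high_pct: float
    mean_bias_kcal: float
    loa_low_kcal: float
    loa_high_kcal: float
    prop_bias_r: float
    fit_slope: float
    fit_intercept: float
    fit_slope_se: float
    residual_sd: float
    prediction_limits: pd.DataFrame = field(repr=False, default=None)


def bland_altman(
    observed_kcal,
    predicted_kcal,
    at_kcal: tuple[float, ...] = (10.0, 30.0, 50.0),
) -> AgreementResult:
    """Agreement analysis of per-subject session totals.

    Percent error (observed - predicted)/observed*100 is regressed on
    observed kcal by OLS; ``prop_bias_r`` is the Pearson correlation of
    percent error with observed total; prediction limits at the requested
    observed-kcal values are the regression line +/- 1.96 * residual SD.
    LOA are mean +/- 1.96 * SD of the differences, in both percent and
    raw-kcal form.
    """
    obs = np.asarray(observed_kcal, dtype=float)
    pred = np.asarray(predicted_kcal, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need >= 3 paired subject totals")
    if (obs <= 0).any():
        raise ValueError("observed totals must be positive for percent errors")

    diff_pct = (obs - pred) / obs * 100.0
    diff_kcal = obs - pred
    sd_pct = float(diff_pct.std(ddof=1))
    sd_kcal = float(diff_kcal.std(ddof=1))

    if np.ptp(obs) > 0:
        X = sm.add_constant(obs)
        fit = sm.OLS(diff_pct, X).fit()
        intercept, slope = float(fit.params[0]), float(fit.params[1])
        slope_se = float(fit.bse[1])
        resid_sd = float(np.sqrt(fit.scale))
    else:  # all observed totals identical: no magnitude axis to regress on
        intercept, slope, slope_se = float(diff_pct.mean()), 0.0, 0.0
        resid_sd = float(diff_pct.std(ddof=1))
    if diff_pct.std(ddof=0) > 0 and obs.std(ddof=0) > 0:
        r = float(np.corrcoef(diff_pct, obs)[0, 1])
    else:
        r = 0.0

    at = np.asarray(at_kcal, dtype=float)
    line = intercept + slope * at
    limits = pd.DataFrame(
        {
            "observed_kcal": at,
            "fit_pct": line,
            "lower_pct": line - 1.96 * resid_sd,
            "upper_pct": line + 1.96 * resid_sd,
        }
    )

    return AgreementResult(
        n=obs.size,
        mean_bias_pct=float(diff_pct.mean()),
        loa_low_pct=float(diff_pct.mean() - 1.96 * sd_pct),
        loa_high_pct=float(diff_pct.mean() + 1.96 * sd_pct),
        mean_bias_kcal=float(diff_kcal.mean()),
        loa_low_kcal=float(diff_kcal.mean() - 1.96 * sd_kcal),
        loa_high_kcal=float(diff_kcal.mean() + 1.96 * sd_kcal),
        prop_bias_r=r,
        fit_slope=slope,
        fit_intercept=intercept,
        fit_slope_se=slope_se,
        residual_sd=resid_sd,
        prediction_limits=limits,
    )


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with Fisher-LSD follow-ups."""

    f_stat: float
    df_model: int
    df_error: int
    p_value: float
    ms_error: float
    pairwise: pd.DataFrame = field(repr=False, default=None)


def rm_anova(error_matrix: pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """Within-subject one-way ANOVA on a subjects x models error matrix.

    Subjects are the blocking factor; the error term is the model x subject
    interaction mean square (classic two-way decomposition without
    replication, no sphericity correction).  When the omnibus F is
    significant at ``alpha``, Fisher-LSD pairwise comparisons are computed
    with the pooled error MS and its df (unadjusted t tests).
    """
    M = error_matrix.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("error matrix must be complete")
    n, m = M.shape
    if n < 2 or m < 2:
        raise ValueError("need >= 2 subjects and >= 2 models")

    grand = M.mean()
    model_means = M.mean(axis=0)
    subject_means = M.mean(axis=1)
    ss_model = n * ((model_means - grand) ** 2).sum()
    ss_subject = m * ((subject_means - grand) ** 2).sum()
    ss_total = ((M - grand) ** 2).sum()
    ss_error = ss_total - ss_model - ss_subject

    df_model = m - 1
    df_error = (m - 1) * (n - 1)
    ms_model = ss_model / df_model
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f = 0.0 if ms_model == 0 else np.inf
        p = 1.0 if ms_model == 0 else 0.0
    else:
        f = ms_model / ms_error
        p = float(stats.f.sf(f, df_model, df_error))

    pairwise = None
    if p <= alpha and ms_error > 0:
        names = list(error_matrix.columns)
        rows = []
        for a in range(m):
            for b in range(a + 1, m):
                diff = model_means[a] - model_means[b]
                se = np.sqrt(2.0 * ms_error / n)
                t = diff / se
                p_ab = 2.0 * stats.t.sf(abs(t), df_error)
                rows.append((names[a], names[b], diff, t, p_ab))
        pairwise = pd.DataFrame(
            rows, columns=["model_a", "model_b", "mean_diff", "t", "p"]
        )

    return AnovaResult(
        f_stat=float(f),
        df_model=df_model,
        df_error=df_error,
        p_value=float(p),
        ms_error=float(ms_error),
        pairwise=pairwise,
    )
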