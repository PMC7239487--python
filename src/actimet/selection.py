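"""Minimum-redundancy maximum-relevance (mRMR) feature selection.

Greedy forward selection against the continuous EE target.  The default
scorer is an F-quotient variant for continuous targets: relevance is the
F-statistic of the univariate linear regression of the target on the
feature, and redundancy is the mean — over the already-selected set — of
the same F-statistic applied to the feature/selected-feature correlation,
so the quotient compares like with like.  Measuring redundancy on the F
scale (rather than raw mean |r|) makes an exact duplicate of a selected
feature infinitely redundant: it scores 0 and can never displace a
feature carrying independent signal, which is the behaviour greedy mRMR
is meant to deliver.  A mutual-information variant (equal-frequency
discretisation, MI on both sides of the quotient) is available via
``method="mi"``.

The greedy procedure makes the k=10 set a prefix of the k=15 set and of
the k=20 set by construction; ties are broken by catalog (column) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

REDUNDANCY_EPS = 1e-6


@dataclass
class SelectionResult:
    """Ordered mRMR selection with its per-step diagnostics."""

    k: int
    ordered_features: list[str]
    relevance: dict[str, float]
    redundancy_per_step: list[float] = field(default_factory=list)
    scores_per_step: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.k + 1),
                "feature": self.ordered_features,
                "relevance": [self.relevance[f] for f in self.ordered_features],
                "redundancy": self.redundancy_per_step,
                "score": self.scores_per_step,
            }
        )


def _pearson_with_target(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((sx > 0) & (sy > 0), Xc.T @ yc / np.where(sx > 0, sx, 1.0) / max(sy, 1e-300), 0.0)
    return np.clip(r, -1.0, 1.0)


def _f_relevance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """F-statistic of the univariate OLS of y on each column (constant -> 0)."""
    n = X.shape[0]
    r = _pearson_with_target(X, y)
    r2 = r**2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(r2 < 1.0, r2 * (n - 2) / np.maximum(1.0 - r2, 1e-300), np.inf)
    f[X.std(axis=0) == 0] = 0.0
    return f


def _equal_frequency_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    ranks = pd.Series(v).rank(method="average").to_numpy()
    return np.minimum((ranks - 1) / len(v) * n_bins, n_bins - 1).astype(int)


def mrmr_select(
    table: pd.DataFrame,
    k: int,
    feature_names: list[str] | None = None,
    target: str = "ee_kcal_min",
    method: str = "f_quotient",
    n_bins: int = 10,
) -> SelectionResult:
    """Select the ``k`` best features by greedy mRMR.

    ``table`` holds feature columns plus the target column; ``feature_names``
    (default: every column except known label/metadata columns) fixes the
    candidate set and the tie-break order.
    """
    if feature_names is None:
        reserved = {target, "participant_id", "site", "window_start_s",
                    "activity", "ree_kcal_min", "ee_kcal_min", "met"}
        feature_names = [c for c in table.columns if c not in reserved]
    if k > len(feature_names):
        raise ValueError(f"k={k} exceeds the {len(feature_names)} candidate features")
    if len(table) < 2:
        raise ValueError("need at least two windows for selection")

    X = table[feature_names].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)
    n, p = X.shape

    if method == "f_quotient":
        relevance = _f_relevance(X, y)
    elif method == "mi":
        yb = _equal_frequency_bins(y, n_bins)
        Xb = np.column_stack([_equal_frequency_bins(X[:, j], n_bins) for j in range(p)])
        relevance = np.array([mutual_info_score(Xb[:, j], yb) for j in range(p)])
        X = Xb.astype(float)  # redundancy measured on the same discretisation
    else:
        raise ValueError(f"unknown mRMR method {method!r}")

    def _f_scale(abs_r: np.ndarray) -> np.ndarray:
        r2 = np.minimum(abs_r**2, 1.0)
        with np.errstate(divide="ignore"):
            return np.where(r2 < 1.0, r2 * (n - 2) / np.maximum(1.0 - r2, 1e-300), np.inf)

    selected: list[int] = []
    redundancy_steps: list[float] = []
    score_steps: list[float] = []
    # running sum of F-scale |r| (or MI) against selected features, per candidate
    red_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)

    for step in range(k):
        if step == 0:
            scores = relevance.copy()
            red = np.zeros(p)
        else:
            red = red_sum / step
            with np.errstate(invalid="ignore"):
                scores = relevance / np.maximum(red, REDUNDANCY_EPS)
            scores = np.nan_to_num(scores, nan=0.0)  # inf/inf: fully redundant
        scores = np.where(available, scores, -np.inf)
        j = int(np.argmax(scores))  # first max -> catalog-order tie-break
        selected.append(j)
        redundancy_steps.append(float(red[j]))
        score_steps.append(float(scores[j]))
        available[j] = False
        if method == "f_quotient":
            xj = X[:, j]
            r_new = _f_scale(np.abs(_pearson_with_target(X, xj)))
        else:
            r_new = np.array(
                [mutual_info_score(X[:, m].astype(int), X[:, j].astype(int)) for m in range(p)]
            )
        red_sum += r_new

    names = [feature_names[j] for j in selected]
    rel_map = {feature_names[j]: float(relevance[j]) for j in range(p)}
    return SelectionResult(
        k=k,
        ordered_features=names,
        relevance=rel_map,
        redundancy_per_step=redundancy_steps,
        scores_per_step=score_steps,
    )
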