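"""Indirect-calorimetry preprocessing.

Breath-by-breath VO2/VCO2 is binned to 10-s averages, smoothed with a 60-s
moving average, and converted to energy expenditure (kcal/min) with the
abbreviated Weir equation.  Resting EE is predicted from sex, height and
body mass with Schofield's weight-and-height equations for children aged
3-10 y, and measured EE is normalised to METs by dividing by predicted
resting EE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: abbreviated Weir coefficients: EE [kcal/min] = 3.941*VO2 + 1.106*VCO2 [L/min]
WEIR_VO2 = 3.941
WEIR_VCO2 = 1.106

#: Schofield (weight + height, 3-10 y) BMR coefficients, MJ/day;
#: BMR = a*mass_kg + b*height_m + c
SCHOFIELD_3_10 = {
    "male": (0.082, 0.545, 1.736),
    "female": (0.071, 0.677, 1.553),
}

MJ_PER_DAY_TO_KCAL_PER_DAY = 239.006
MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class RestingEE:
    """Predicted resting energy expenditure in daily and per-minute units."""

    ree_kcal_per_day: float

    @property
    def ree_kcal_per_min(self) -> float:
        return self.ree_kcal_per_day / MINUTES_PER_DAY


def weir_ee(vo2_lpm, vco2_lpm):
    """Energy expenditure (kcal/min) from VO2 and VCO2 (L/min).

    Uses the abbreviated Weir equation (urinary nitrogen ignored), the
    standard form for portable calorimetry.  Accepts scalars or arrays.
    """
    vo2 = np.asarray(vo2_lpm, dtype=float)
    vco2 = np.asarray(vco2_lpm, dtype=float)
    if (vo2 < 0).any() or (vco2 < 0).any():
        raise ValueError("VO2 and VCO2 must be non-negative")
    ee = WEIR_VO2 * vo2 + WEIR_VCO2 * vco2
    return float(ee) if ee.ndim == 0 else ee


def schofield_ree(sex: str, height_m: float, mass_kg: float) -> RestingEE:
    """Predicted resting EE via Schofield's 3-10 y weight-and-height equations."""
    if sex not in SCHOFIELD_3_10:
        raise ValueError(f"sex must be one of {sorted(SCHOFIELD_3_10)}, got {sex!r}")
    if height_m <= 0 or mass_kg <= 0:
        raise ValueError("height and mass must be positive")
    a, b, c = SCHOFIELD_3_10[sex]
    bmr_mj_day = a * mass_kg + b * height_m + c
    return RestingEE(ree_kcal_per_day=bmr_mj_day * MJ_PER_DAY_TO_KCAL_PER_DAY)


def to_mets(ee_kcal_min, ree: RestingEE):
    """Normalise EE (kcal/min) to METs by predicted resting EE."""
    per_min = ree.ree_kcal_per_min
    if per_min <= 0:
        raise ValueError("resting EE must be positive")
    ee = np.asarray(ee_kcal_min, dtype=float)
    met = ee / per_min
    return float(met) if met.ndim == 0 else met


def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges.

    For even ``width`` the window at index i covers bins [i-w//2+1, i+w//2]
    (the extra bin on the trailing side), so a 60-s average of 10-s bins
    spans six bins.
    """
    n = len(values)
    out = np.empty(n)
    lo_off = -(width // 2) + (1 if width % 2 == 0 else 0)
    hi_off = width // 2
    for i in range(n):
        lo = max(0, i + lo_off)
        hi = min(n - 1, i + hi_off)
        out[i] = values[lo : hi + 1].mean()
    return out


def smooth_gas(
    breaths: pd.DataFrame,
    bin_s: float = 10.0,
    ma_s: float = 60.0,
    origin_s: float | None = None,
    span_s: float | None = None,
    centred: bool = True,
) -> pd.DataFrame:
    """Bin breath-by-breath gas exchange to ``bin_s`` averages and smooth.

    Breaths are assigned to consecutive left-closed right-open bins starting
    at ``origin_s`` (default: the first breath time floored to the bin
    grid).  Empty interior bins are linearly interpolated from neighbours.
    The per-bin means are then smoothed with a ``ma_s`` moving average —
    centred with shrinking edge windows by default, trailing when
    ``centred=False``.

    Returns a frame with columns ``bin_start_s``, ``vo2_lpm``, ``vco2_lpm``.
    """
    if len(breaths) == 0:
        raise ValueError("no breaths to bin")
    if ma_s % bin_s != 0:
        raise ValueError("bin width must divide the moving-average width")
    t = breaths["time_s"].to_numpy(dtype=float)
    if origin_s is None:
        origin_s = np.floor(t[0] / bin_s) * bin_s
    if span_s is None:
        span_s = t[-1] - origin_s
    n_bins = int(np.floor(span_s / bin_s + 1e-9))  # tolerate fp-accumulated spans
    if n_bins < 1:
        raise ValueError("breath record spans less than one bin")

    idx = np.floor((t - origin_s) / bin_s).astype(int)
    keep = (idx >= 0) & (idx < n_bins)
    idx = idx[keep]
    if idx.size == 0:
        raise ValueError("all breaths fall outside the binning span")

    binned = np.full((n_bins, 2), np.nan)
    for col, name in enumerate(("vo2_lpm", "vco2_lpm")):
        v = breaths[name].to_numpy(dtype=float)[keep]
        sums = np.bincount(idx, weights=v, minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            binned[:, col] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    # interpolate empty bins from neighbours (nearest values at the ends)
    bins = np.arange(n_bins)
    for col in range(2):
        v = binned[:, col]
        ok = ~np.isnan(v)
        binned[:, col] = np.interp(bins, bins[ok], v[ok])

    width = int(round(ma_s / bin_s))
    if centred:
        vo2 = _moving_average(binned[:, 0], width)
        vco2 = _moving_average(binned[:, 1], width)
    else:  # trailing window, shrinking at the start
        vo2 = np.array([binned[max(0, i - width + 1) : i + 1, 0].mean() for i in bins])
        vco2 = np.array([binned[max(0, i - width + 1) : i + 1, 1].mean() for i in bins])

    return pd.DataFrame(
        {"bin_start_s": origin_s + bins * bin_s, "vo2_lpm": vo2, "vco2_lpm": vco2}
    )


def criterion_ee(
    breaths: pd.DataFrame,
    ree: RestingEE | None = None,
    bin_s: float = 10.0,
    ma_s: float = 60.0,
    origin_s: float | None = None,
    span_s: float | None = None,
    centred: bool = True,
) -> pd.DataFrame:
    """Full criterion series: smoothed gas exchange converted to kcal/min.

    Returns columns ``bin_start_s``, ``ee_kcal_min`` and, when ``ree`` is
    given, ``met``.
    """
    gas = smooth_gas(breaths, bin_s=bin_s, ma_s=ma_s, origin_s=origin_s,
                     span_s=span_s, centred=centred)
    out = pd.DataFrame(
        {
            "bin_start_s": gas["bin_start_s"],
            "ee_kcal_min": weir_ee(gas["vo2_lpm"].to_numpy(), gas["vco2_lpm"].to_numpy()),
        }
    )
    if ree is not None:
        out["met"] = to_mets(out["ee_kcal_min"].to_numpy(), ree)
    return out
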