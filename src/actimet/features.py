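"""Per-window feature extraction from raw tri-axial acceleration.

The raw signal is converted to a vector magnitude (VM), segmented into
non-overlapping 10-s windows, and a fixed catalog of time- and
frequency-domain features is computed per axis and VM, plus cross-axis
correlations and mean orientation angles.  Feature tables are synchronised
with the calorimetry criterion series by window start time.

Operational definitions (the literature names these features but rarely
defines them; the definitions below are locked by oracle tests):

- ``sd``/``variance`` are sample statistics (ddof=1); ``cv`` = sd/|mean|*100
  (0 when the mean is 0); skewness/kurtosis use biased central moments,
  kurtosis is Pearson's (no -3); ``mad`` = mean |x - mean|;
  ``power`` = mean of squared raw samples; ``sum`` over raw samples;
  ``log_energy`` = sum log(x^2 + 1e-10) over raw samples.
- ``zero_crossings`` counts sign changes of the mean-centred signal,
  ``median_crossings`` of the median-centred signal; exact zeros carry the
  previous sign (leading zeros are ignored).
- ``lag1_autocorr`` is the Pearson correlation of (x[:-1], x[1:]); any
  correlation-type, standardized-moment or crossing feature of a
  zero-variance (max == min) signal is 0 (sentinel).
- activation features are computed on the mean-removed, rectified signal
  filtered with a zero-phase 4th-order Butterworth 5 Hz lowpass:
  ``active_samples`` counts samples strictly above the threshold
  (default 0.01 g); activations are maximal contiguous supra-threshold
  runs; interval duration variability is the sample SD of run durations
  (0 with fewer than two runs).
- dominant frequency/magnitude: untapered magnitude spectrum of the
  mean-removed window, bins restricted to [0.25, 5.0] Hz inclusive,
  argmax with ties to the lower frequency; all-zero windows report (0, 0).
- orientation: tilt = arccos(mz/|m|), roll = atan2(my, mz),
  pitch = atan2(-mx, sqrt(my^2+mz^2)) from the per-axis means, in degrees;
  a zero-norm mean vector reports 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import RawTriaxialRecording

AXES = ("x", "y", "z", "vm")

_PER_AXIS_STATS = (
    "mean", "sd", "cv",
    "p10", "p25", "p50", "p75", "p90",
    "skewness", "kurtosis", "max", "min", "p2p",
    "median_crossings", "zero_crossings",
    "sum", "mad", "power", "lag1_autocorr", "log_energy",
    "iqr", "variance",
    "active_samples", "n_activations",
    "mean_activation_interval", "activation_interval_variability",
    "dominant_frequency", "dominant_magnitude",
)
_CROSS = ("corr_xy", "corr_xz", "corr_yz")
_ORIENTATION = ("tilt", "roll", "pitch")

LOG_ENERGY_EPS = 1e-10
DEFAULT_ACTIVATION_THRESHOLD_G = 0.01
DEFAULT_BAND_HZ = (0.25, 5.0)


def feature_catalog() -> list[str]:
    """Ordered names of every extracted feature (the mRMR tie-break order)."""
    names = [f"{stat}_{axis}" for axis in AXES for stat in _PER_AXIS_STATS]
    names.extend(_CROSS)
    names.extend(_ORIENTATION)
    return names


def vector_magnitude(x, y, z) -> np.ndarray:
    """Element-wise Euclidean norm of the three axes."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("axis arrays must have equal shapes")
    return np.sqrt(x * x + y * y + z * z)


def segment_windows(
    recording: RawTriaxialRecording, window_s: float = 10.0
) -> np.ndarray:
    """Segment a recording into complete non-overlapping windows.

    Returns an array of shape (n_windows, window_len, 3); the trailing
    partial window is discarded, so n_windows = floor(n / (rate * window)).
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    wlen = int(round(recording.sampling_rate * window_s))
    n_win = recording.n_samples // wlen
    return recording.samples[: n_win * wlen].reshape(n_win, wlen, 3)


def window_count(n_samples: int, sampling_rate: float = 100.0, window_s: float = 10.0) -> int:
    """Number of complete windows obtainable from ``n_samples`` samples."""
    return int(n_samples // int(round(sampling_rate * window_s)))


# ---------------------------------------------------------------------------
# vectorised per-window statistics (rows = windows)

def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row; 0 where either row has zero variance.

    Zero variance is detected as max == min: the mean of a constant row can
    round, leaving a spuriously tiny but nonzero centred sum of squares.
    """
    const = (np.ptp(a, axis=1) == 0) | (np.ptp(b, axis=1) == 0)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.where(const, 0.0, r)


def _crossings(rows: np.ndarray, centre: np.ndarray) -> np.ndarray:
    """Sign changes of the centred signal, zeros carrying the previous sign."""
    s = np.sign(rows - centre[:, None])
    # forward-fill zeros with the previous sign
    filled = s.copy()
    for j in range(1, filled.shape[1]):
        col = filled[:, j]
        prev = filled[:, j - 1]
        col[col == 0] = prev[col == 0]
    changes = (filled[:, 1:] * filled[:, :-1]) < 0
    return changes.sum(axis=1).astype(float)


def _run_stats(active: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_runs, mean run duration s, sample SD of run durations) per row."""
    n_win = active.shape[0]
    n_runs = np.zeros(n_win)
    mean_dur = np.zeros(n_win)
    sd_dur = np.zeros(n_win)
    for i in range(n_win):
        a = active[i]
        starts = np.flatnonzero(np.diff(np.concatenate(([0], a.view(np.int8)))) == 1)
        ends = np.flatnonzero(np.diff(np.concatenate((a.view(np.int8), [0]))) == -1)
        if starts.size == 0:
            continue
        durations = (ends - starts + 1) / rate
        n_runs[i] = starts.size
        mean_dur[i] = durations.mean()
        sd_dur[i] = durations.std(ddof=1) if durations.size >= 2 else 0.0
    return n_runs, mean_dur, sd_dur


def _spectral(rows: np.ndarray, rate: float, band: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    centred = rows - rows.mean(axis=1, keepdims=True)
    mag = np.abs(np.fft.rfft(centred, axis=1))
    freqs = np.fft.rfftfreq(rows.shape[1], d=1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("no spectral bins inside the requested band")
    band_freqs = freqs[mask]
    band_mag = mag[:, mask]
    idx = band_mag.argmax(axis=1)  # first max -> lower-frequency tie-break
    dom_f = band_freqs[idx]
    dom_m = band_mag[np.arange(rows.shape[0]), idx]
    silent = np.all(rows == rows[:, :1], axis=1)
    dom_f = np.where(silent, 0.0, dom_f)
    dom_m = np.where(silent, 0.0, dom_m)
    return dom_f, dom_m


def _axis_features(
    rows: np.ndarray,
    rate: float,
    band: tuple[float, float],
    threshold_g: float,
    sos: np.ndarray,
) -> dict[str, np.ndarray]:
    mean = rows.mean(axis=1)
    const = np.ptp(rows, axis=1) == 0  # guards ratio features against fp-rounded means
    sd = np.where(const, 0.0, rows.std(axis=1, ddof=1))
    var = sd**2
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean) * 100.0, 0.0)
    p10, p25, p50, p75, p90 = np.percentile(rows, [10, 25, 50, 75, 90], axis=1)
    centred = rows - mean[:, None]
    m2 = (centred**2).mean(axis=1)
    m3 = (centred**3).mean(axis=1)
    m4 = (centred**4).mean(axis=1)
    ok = (m2 > 0) & ~const
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(ok, m3 / np.where(ok, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(ok, m4 / np.where(ok, m2, 1.0) ** 2, 0.0)
    mx = rows.max(axis=1)
    mn = rows.min(axis=1)

    rect = np.abs(centred)
    filtered = sps.sosfiltfilt(sos, rect, axis=1)
    active = filtered > threshold_g
    n_runs, mean_dur, sd_dur = _run_stats(active, rate)

    dom_f, dom_m = _spectral(rows, rate, band)

    return {
        "mean": mean,
        "sd": sd,
        "cv": cv,
        "p10": p10, "p25": p25, "p50": p50, "p75": p75, "p90": p90,
        "skewness": skew,
        "kurtosis": kurt,
        "max": mx,
        "min": mn,
        "p2p": mx - mn,
        "median_crossings": np.where(const, 0.0, _crossings(rows, p50)),
        "zero_crossings": np.where(const, 0.0, _crossings(rows, mean)),
        "sum": rows.sum(axis=1),
        "mad": rect.mean(axis=1),
        "power": (rows**2).mean(axis=1),
        "lag1_autocorr": _rowwise_pearson(rows[:, :-1], rows[:, 1:]),
        "log_energy": np.log(rows**2 + LOG_ENERGY_EPS).sum(axis=1),
        "iqr": p75 - p25,
        "variance": var,
        "active_samples": active.sum(axis=1).astype(float),
        "n_activations": n_runs,
        "mean_activation_interval": mean_dur,
        "activation_interval_variability": sd_dur,
        "dominant_frequency": dom_f,
        "dominant_magnitude": dom_m,
    }


def orientation_angles(x_mean, y_mean, z_mean) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(tilt, roll, pitch) in degrees from the window-mean gravity vector."""
    mx = np.asarray(x_mean, dtype=float)
    my = np.asarray(y_mean, dtype=float)
    mz = np.asarray(z_mean, dtype=float)
    norm = np.sqrt(mx**2 + my**2 + mz**2)
    ok = norm > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        tilt = np.where(ok, np.degrees(np.arccos(np.clip(mz / np.where(ok, norm, 1.0), -1, 1))), 0.0)
    roll = np.where(ok, np.degrees(np.arctan2(my, mz)), 0.0)
    pitch = np.where(ok, np.degrees(np.arctan2(-mx, np.sqrt(my**2 + mz**2))), 0.0)
    return tilt, roll, pitch


def extract_features(
    recording: RawTriaxialRecording,
    window_s: float = 10.0,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    activation_threshold_g: float = DEFAULT_ACTIVATION_THRESHOLD_G,
) -> pd.DataFrame:
    """Feature table for all complete windows of a recording.

    One row per window; columns ``window_start_s`` followed by the full
    feature catalog.
    """
    windows = segment_windows(recording, window_s)
    if windows.shape[0] == 0:
        return pd.DataFrame(columns=["window_start_s", *feature_catalog()])
    rate = recording.sampling_rate
    sos = sps.butter(4, 5.0, btype="low", fs=rate, output="sos")

    cols: dict[str, np.ndarray] = {
        "window_start_s": np.arange(windows.shape[0]) * window_s
    }
    axis_rows = {
        "x": windows[:, :, 0],
        "y": windows[:, :, 1],
        "z": windows[:, :, 2],
    }
    axis_rows["vm"] = vector_magnitude(axis_rows["x"], axis_rows["y"], axis_rows["z"])
    for axis in AXES:
        stats = _axis_features(axis_rows[axis], rate, band, activation_threshold_g, sos)
        for stat in _PER_AXIS_STATS:
            cols[f"{stat}_{axis}"] = stats[stat]

    cols["corr_xy"] = _rowwise_pearson(axis_rows["x"], axis_rows["y"])
    cols["corr_xz"] = _rowwise_pearson(axis_rows["x"], axis_rows["z"])
    cols["corr_yz"] = _rowwise_pearson(axis_rows["y"], axis_rows["z"])
    tilt, roll, pitch = orientation_angles(
        axis_rows["x"].mean(axis=1), axis_rows["y"].mean(axis=1), axis_rows["z"].mean(axis=1)
    )
    cols["tilt"], cols["roll"], cols["pitch"] = tilt, roll, pitch
    return pd.DataFrame(cols)


def extract_window_features(
    window: np.ndarray,
    sampling_rate: float = 100.0,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    activation_threshold_g: float = DEFAULT_ACTIVATION_THRESHOLD_G,
) -> dict[str, float]:
    """Feature map for a single (n, 3) window (convenience wrapper)."""
    rec = RawTriaxialRecording(
        site="hip", sampling_rate=sampling_rate,
        start_time=pd.Timestamp("2000-01-01"), samples=np.asarray(window, dtype=float),
    )
    table = extract_features(rec, window_s=rec.duration_s, band=band,
                             activation_threshold_g=activation_threshold_g)
    row = table.iloc[0].drop("window_start_s")
    return {k: float(v) for k, v in row.items()}


def synchronize(
    features: pd.DataFrame,
    ee: pd.DataFrame,
    tolerance_s: float = 0.0,
) -> tuple[pd.DataFrame, int]:
    """Label feature windows with the EE criterion by start-time alignment.

    Exact matching by default; with ``tolerance_s`` > 0 each window takes
    the nearest EE bin within the tolerance.  Returns the labelled table
    and the number of windows dropped for lack of a match.
    """
    if len(features) == 0 or len(ee) == 0:
        raise ValueError("cannot synchronize empty tables")
    f = features.sort_values("window_start_s").reset_index(drop=True)
    e = ee.sort_values("bin_start_s").reset_index(drop=True)
    lo = max(f["window_start_s"].min(), e["bin_start_s"].min())
    hi = min(f["window_start_s"].max(), e["bin_start_s"].max())
    if lo - hi > tolerance_s:
        raise ValueError("feature and EE time ranges do not overlap")
    if tolerance_s <= 0:
        merged = f.merge(e, left_on="window_start_s", right_on="bin_start_s", how="inner")
    else:
        merged = pd.merge_asof(
            f, e, left_on="window_start_s", right_on="bin_start_s",
            direction="nearest", tolerance=tolerance_s,
        ).dropna(subset=["bin_start_s"])
    merged = merged.drop(columns=["bin_start_s"])
    return merged.reset_index(drop=True), len(f) - len(merged)
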