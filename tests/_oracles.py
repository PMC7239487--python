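"""Independent brute-force oracles for per-window features.

Every statistic here is computed with a deliberately naive, per-window
code path (explicit loops, scipy.stats reference functions) that shares no
code with ``actimet.features``.  The zero-phase Butterworth filter itself
comes from scipy in both places — it is standard infrastructure, not the
feature logic under test; thresholding, run counting and all statistics
are re-derived independently.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy import stats


def oracle_axis_features(w: np.ndarray, rate: float = 100.0,
                         band=(0.25, 5.0), threshold: float = 0.01) -> dict:
    w = np.asarray(w, dtype=float)
    n = len(w)
    constant = max(w) == min(w)  # the documented zero-variance sentinel condition
    out = {}
    mean = sum(w) / n
    out["mean"] = mean
    sd = 0.0 if constant else np.std(w, ddof=1)
    out["sd"] = sd
    out["variance"] = sd * sd
    out["cv"] = sd / abs(mean) * 100.0 if mean != 0 else 0.0
    for q in (10, 25, 50, 75, 90):
        out[f"p{q}"] = np.percentile(w, q)
    out["iqr"] = out["p75"] - out["p25"]
    if not constant:
        out["skewness"] = stats.skew(w, bias=True)
        out["kurtosis"] = stats.kurtosis(w, fisher=False, bias=True)
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    out["max"] = max(w)
    out["min"] = min(w)
    out["p2p"] = max(w) - min(w)
    out["sum"] = sum(w)
    out["mad"] = sum(abs(v - mean) for v in w) / n
    out["power"] = sum(v * v for v in w) / n
    out["log_energy"] = sum(np.log(v * v + 1e-10) for v in w)
    if not constant and np.ptp(w[:-1]) > 0 and np.ptp(w[1:]) > 0:
        out["lag1_autocorr"] = stats.pearsonr(w[:-1], w[1:]).statistic
    else:
        out["lag1_autocorr"] = 0.0

    out["median_crossings"] = 0.0 if constant else _count_crossings(w - np.median(w))
    out["zero_crossings"] = 0.0 if constant else _count_crossings(w - mean)

    # activation features on the rectified, lowpass-filtered signal
    sos = sps.butter(4, 5.0, btype="low", fs=rate, output="sos")
    filtered = sps.sosfiltfilt(sos, np.abs(w - mean))
    runs = _runs_above(filtered, threshold)
    out["active_samples"] = float(sum(len(r) for r in runs))
    out["n_activations"] = float(len(runs))
    durations = [len(r) / rate for r in runs]
    out["mean_activation_interval"] = float(np.mean(durations)) if runs else 0.0
    out["activation_interval_variability"] = (
        float(np.std(durations, ddof=1)) if len(durations) >= 2 else 0.0
    )

    # spectral: untapered DFT of the mean-removed window, band-restricted
    if np.all(w == w[0]):
        out["dominant_frequency"] = 0.0
        out["dominant_magnitude"] = 0.0
    else:
        spectrum = np.fft.rfft(w - mean)
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)
        best_f, best_m = None, -1.0
        for f, c in zip(freqs, spectrum):
            if band[0] <= f <= band[1]:
                m = abs(c)
                if m > best_m:  # strict: ties keep the lower frequency
                    best_f, best_m = f, m
        out["dominant_frequency"] = best_f
        out["dominant_magnitude"] = best_m
    return out


def _count_crossings(centred: np.ndarray) -> float:
    count = 0
    prev = 0.0
    for v in centred:
        s = 0.0 if v == 0 else (1.0 if v > 0 else -1.0)
        if s == 0.0:
            continue  # zeros carry the previous sign: no change recorded
        if prev != 0.0 and s != prev:
            count += 1
        prev = s
    return float(count)


def _runs_above(values: np.ndarray, threshold: float) -> list[list[int]]:
    runs, current = [], []
    for i, v in enumerate(values):
        if v > threshold:
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def oracle_cross_and_orientation(win3: np.ndarray) -> dict:
    x, y, z = win3[:, 0], win3[:, 1], win3[:, 2]
    out = {}
    for name, (a, b) in {
        "corr_xy": (x, y), "corr_xz": (x, z), "corr_yz": (y, z)
    }.items():
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            out[name] = stats.pearsonr(a, b).statistic
        else:
            out[name] = 0.0
    mx, my, mz = x.mean(), y.mean(), z.mean()
    norm = np.sqrt(mx**2 + my**2 + mz**2)
    if norm == 0:
        out["tilt"] = out["roll"] = out["pitch"] = 0.0
    else:
        out["tilt"] = np.degrees(np.arccos(mz / norm))
        out["roll"] = np.degrees(np.arctan2(my, mz))
        out["pitch"] = np.degrees(np.arctan2(-mx, np.hypot(my, mz)))
    return out


def random_windows(n_windows: int, seed: int, n_samples: int = 1000,
                   rate: float = 100.0) -> np.ndarray:
    """Realistic random windows: gravity + oscillation + noise, plus edge cases."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / rate
    wins = []
    for i in range(n_windows):
        kind = i % 10
        if kind == 0:
            w = np.tile(rng.normal(0, 1, 3), (n_samples, 1))  # constant window
        elif kind == 1:
            w = rng.normal(0, 0.02, (n_samples, 3))  # near-still sensor noise
        else:
            g = rng.normal(0, 1, 3)
            g /= np.linalg.norm(g)
            amp = rng.uniform(0.02, 1.5)
            f = rng.uniform(0.3, 4.8)
            phases = rng.uniform(0, 2 * np.pi, 3)
            w = np.outer(np.ones(n_samples), g)
            for ax in range(3):
                w[:, ax] += amp * rng.uniform(0.2, 1.0) * np.sin(
                    2 * np.pi * f * t + phases[ax]
                )
            w += rng.normal(0, 0.05, (n_samples, 3))
        wins.append(w)
    return np.asarray(wins)
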