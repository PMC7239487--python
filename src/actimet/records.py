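"""Core domain records shared across the pipeline.

Times are kept as float seconds relative to a session start; the session
start itself is an ISO-8601 wall-clock timestamp used only at the CSV
boundary (see :mod:`actimet.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: device dynamic range of the emulated tri-axial monitor, in g
DYNAMIC_RANGE_G = 8.0

#: default raw sampling frequency, Hz
SAMPLING_RATE_HZ = 100.0

VALID_SITES = ("hip", "wrist")
VALID_SEXES = ("male", "female")
ACTIVITY_LABELS = ("seated", "walking", "running", "energetic_play", "other")


@dataclass(frozen=True)
class Participant:
    """Demographics needed for resting-EE prediction and bookkeeping."""

    id: str
    age: int
    sex: str
    height_m: float
    mass_kg: float

    def __post_init__(self) -> None:
        if not 3 <= self.age <= 5:
            raise ValueError(f"age must be in 3..5 years, got {self.age}")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if self.height_m <= 0 or self.mass_kg <= 0:
            raise ValueError("height and mass must be positive")


@dataclass(frozen=True)
class Bout:
    """One contiguous activity bout of a play session."""

    activity: str
    duration_s: float
    target_met: float

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_LABELS:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.duration_s <= 0:
            raise ValueError("bout duration must be positive")
        if self.target_met <= 0:
            raise ValueError("target MET must be positive")


@dataclass(frozen=True)
class ActivitySchedule:
    """Ordered bouts covering a whole session."""

    bouts: tuple[Bout, ...]

    @property
    def total_duration_s(self) -> float:
        return float(sum(b.duration_s for b in self.bouts))

    def boundaries(self) -> np.ndarray:
        """Cumulative bout end times (seconds from session start)."""
        return np.cumsum([b.duration_s for b in self.bouts])

    def at(self, t: float) -> Bout:
        """Bout active at time ``t`` seconds (right-open intervals)."""
        ends = self.boundaries()
        i = int(np.searchsorted(ends, t, side="right"))
        i = min(i, len(self.bouts) - 1)
        return self.bouts[i]

    def step_series(self, dt: float = 1.0) -> pd.DataFrame:
        """Activity/MET step functions sampled every ``dt`` seconds."""
        t = np.arange(0.0, self.total_duration_s, dt)
        ends = self.boundaries()
        idx = np.minimum(np.searchsorted(ends, t, side="right"), len(self.bouts) - 1)
        return pd.DataFrame(
            {
                "t": t,
                "activity": [self.bouts[i].activity for i in idx],
                "target_met": [self.bouts[i].target_met for i in idx],
            }
        )


@dataclass
class RawTriaxialRecording:
    """Raw tri-axial acceleration for one wear site of one session.

    ``samples`` is an (n, 3) float array in g, equally spaced at
    ``sampling_rate`` Hz starting at ``start_time``.
    """

    site: str
    sampling_rate: float
    start_time: pd.Timestamp
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.site not in VALID_SITES:
            raise ValueError(f"site must be one of {VALID_SITES}, got {self.site!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def x(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.samples[:, 2]


def make_breath_table(
    time_s: Sequence[float],
    vo2_lpm: Sequence[float],
    vco2_lpm: Sequence[float],
    rr: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Assemble a validated breath-by-breath gas-exchange table.

    Columns: ``time_s`` (seconds from session start, strictly increasing),
    ``vo2_lpm``, ``vco2_lpm`` (L/min, non-negative) and optional ``rr``
    (breaths/min).
    """
    df = pd.DataFrame(
        {
            "time_s": np.asarray(time_s, dtype=float),
            "vo2_lpm": np.asarray(vo2_lpm, dtype=float),
            "vco2_lpm": np.asarray(vco2_lpm, dtype=float),
        }
    )
    if rr is not None:
        df["rr"] = np.asarray(rr, dtype=float)
    if len(df) == 0:
        raise ValueError("breath table must contain at least one breath")
    if (df["vo2_lpm"] < 0).any() or (df["vco2_lpm"] < 0).any():
        raise ValueError("VO2 and VCO2 must be non-negative")
    dt = np.diff(df["time_s"].to_numpy())
    if (dt <= 0).any():
        bad = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"breath timestamps must be strictly increasing (row {bad})")
    return df


@dataclass
class SyntheticSession:
    """One simulated free-play session with its generator ground truth.

    ``truth`` is a 10-s-slot table with columns ``slot_start_s``,
    ``activity``, ``target_met``, ``ee_det`` (deterministic EE after
    on-kinetics, kcal/min) and ``ee_truth`` (``ee_det`` times the lognormal
    slot noise — the noiseless-breath target).
    """

    participant: Participant
    schedule: ActivitySchedule
    hip: RawTriaxialRecording
    wrist: RawTriaxialRecording
    breaths: pd.DataFrame
    truth: pd.DataFrame
    ree_kcal_min: float
    start_time: pd.Timestamp
    seed: int
    extras: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.schedule.total_duration_s

    def recording(self, site: str) -> RawTriaxialRecording:
        if site == "hip":
            return self.hip
        if site == "wrist":
            return self.wrist
        raise ValueError(f"unknown site {site!r}")
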