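"""Seeded synthetic free-play cohorts: accelerometry + calorimetry + truth.

No public dataset of preschool free-play accelerometry with concurrent
indirect calorimetry exists, so the pipeline is validated on a generative
stand-in with known ground truth.  A session is built in three layers:

1. an activity schedule of seated / walking / running / energetic-play
   bouts whose expected per-session totals match observed free-play
   behaviour in 3-5-year-olds (energetic play 11.7 min, walking 2.8 min,
   running 2.4 min, seated 4.3 min in a 20-min session);
2. an energy-expenditure path: each activity has a target MET level,
   steady-state EE = Schofield resting EE x MET follows bout transitions
   with first-order on-kinetics (tau = 30 s), and each 10-s slot receives
   multiplicative lognormal noise (sigma = 0.10, mean-one).  Breath-by-
   breath VO2/VCO2 are obtained by inverting the Weir equation at a fixed
   RER (0.85) with per-breath noise;
3. tri-axial acceleration per wear site: a site-specific gravity
   orientation plus a band-limited oscillation whose amplitude and
   dominant frequency increase monotonically with the target MET, plus
   white sensor noise.  Movement switches instantly at bout boundaries
   (muscles move before oxygen uptake catches up), which is what makes the
   kinetic lag irreducible to any single-window model.

Every output is a pure function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calorimetry import WEIR_VCO2, WEIR_VO2, schofield_ree
from .records import (
    ActivitySchedule,
    Bout,
    DYNAMIC_RANGE_G,
    Participant,
    RawTriaxialRecording,
    SyntheticSession,
    make_breath_table,
)

#: target MET level per activity (artifact defaults, exposed in config)
DEFAULT_MET_TARGETS = {
    "seated": 1.3,
    "walking": 3.7,
    "running": 6.0,
    "energetic_play": 4.5,
}

#: per-session activity totals, minutes: mean and SD in a 20-min session
ACTIVITY_TOTALS_MIN = {
    "energetic_play": (11.7, 4.0),
    "walking": (2.8, 1.9),
    "running": (2.4, 1.1),
    "seated": (4.3, 2.3),
}
REFERENCE_SESSION_S = 1200.0

#: age- and sex-conditional anthropometry: {(age, sex): (height_m, mass_kg)}
#: means near growth-reference medians for 3-5-y-olds; SDs below
ANTHROPOMETRY_MEANS = {
    (3, "male"): (0.96, 14.3), (3, "female"): (0.95, 13.9),
    (4, "male"): (1.03, 16.3), (4, "female"): (1.02, 15.9),
    (5, "male"): (1.10, 18.4), (5, "female"): (1.09, 17.9),
}
HEIGHT_SD_M = 0.04
MASS_SD_KG = 1.5

DEFAULT_AGE_MIX = (0.36, 0.28, 0.36)  # ages 3, 4, 5
DEFAULT_P_MALE = 0.8  # the study cohort: 20 boys, 5 girls

#: site-specific signal parameters
SITE_PARAMS = {
    # gravity unit vector (device frame), oscillation amplitude per (MET-1)
    # in g, axis weights for the oscillation
    "hip": {"gravity": (0.10, 0.05, 0.99), "amp_per_met": 0.15,
            "axis_weights": (0.45, 0.35, 1.00)},
    "wrist": {"gravity": (0.66, 0.21, 0.72), "amp_per_met": 0.25,
              "axis_weights": (1.00, 0.60, 0.50)},
}
#: dominant oscillation frequency, Hz: F0 + F_SLOPE * (MET - 1)
OSC_F0_HZ = 0.6
OSC_F_SLOPE = 0.35
SENSOR_NOISE_G = 0.012
BOUT_AMP_JITTER_SD = 0.10


@dataclass(frozen=True)
class SessionParams:
    """Tunable knobs of the generative model (defaults are the stated world)."""

    ee_noise_sigma: float = 0.10     # lognormal slot-noise sigma on EE
    tau_s: float = 30.0              # first-order EE on-kinetics time constant
    rer: float = 0.85                # respiratory exchange ratio for Weir inversion
    breath_noise_cv: float = 0.05    # per-breath multiplicative noise CV
    slot_s: float = 10.0             # truth-EE slot width
    sampling_rate_hz: float = 100.0
    met_targets: dict = field(default_factory=lambda: dict(DEFAULT_MET_TARGETS))

    def noiseless(self) -> "SessionParams":
        return replace(self, ee_noise_sigma=0.0, breath_noise_cv=0.0)


def make_cohort(
    n: int,
    seed: int,
    age_mix: tuple[float, float, float] = DEFAULT_AGE_MIX,
    p_male: float = DEFAULT_P_MALE,
    id_prefix: str = "P",
) -> list[Participant]:
    """Draw ``n`` participants with age/sex-conditional anthropometrics."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(age_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-6 or (mix < 0).any():
        raise ValueError("age_mix must be three non-negative proportions summing to 1")
    rng = np.random.default_rng(seed)
    ages = rng.choice([3, 4, 5], size=n, p=mix / mix.sum())
    sexes = np.where(rng.random(n) < p_male, "male", "female")
    out = []
    for i, (age, sex) in enumerate(zip(ages, sexes)):
        h_mu, m_mu = ANTHROPOMETRY_MEANS[(int(age), str(sex))]
        height = max(0.80, rng.normal(h_mu, HEIGHT_SD_M))
        mass = max(10.0, rng.normal(m_mu, MASS_SD_KG))
        out.append(
            Participant(
                id=f"{id_prefix}{i + 1:03d}", age=int(age), sex=str(sex),
                height_m=float(height), mass_kg=float(mass),
            )
        )
    return out


def _split_total(rng: np.random.Generator, total: float, n_parts: int,
                 min_part: float) -> list[float]:
    """Split ``total`` into ``n_parts`` random positive parts >= min_part."""
    if total < n_parts * min_part:
        n_parts = max(1, int(total // min_part))
    for _ in range(20):
        parts = rng.dirichlet(np.full(n_parts, 4.0)) * total
        if (parts >= min_part).all():
            return parts.tolist()
    return [total / n_parts] * n_parts


def default_schedule(
    seed: int,
    session_length_s: float = REFERENCE_SESSION_S,
    met_targets: dict | None = None,
    min_bout_s: float = 20.0,
) -> ActivitySchedule:
    """Randomised bout schedule with realistic expected activity totals.

    Raw per-activity totals are drawn from truncated normals around the
    observed free-play means, rescaled to sum to ``session_length_s``,
    split into bouts, and interleaved in random order with seated
    transitions between active bouts.
    """
    if session_length_s < 6 * min_bout_s:
        raise ValueError("session too short for a seated/active bout structure")
    met_targets = met_targets or DEFAULT_MET_TARGETS
    rng = np.random.default_rng(seed)

    totals = {}
    for act, (mu, sd) in ACTIVITY_TOTALS_MIN.items():
        totals[act] = max(0.5, rng.normal(mu, sd)) * 60.0
    scale = session_length_s / sum(totals.values())
    totals = {a: v * scale for a, v in totals.items()}

    scale_n = session_length_s / REFERENCE_SESSION_S
    n_bouts = {
        "energetic_play": max(1, int(round(3 * scale_n))),
        "walking": max(1, int(round(2 * scale_n))),
        "running": max(1, int(round(2 * scale_n))),
    }
    active: list[Bout] = []
    for act, n_parts in n_bouts.items():
        for dur in _split_total(rng, totals[act], n_parts, min_bout_s):
            active.append(Bout(act, dur, met_targets[act]))
    order = rng.permutation(len(active))
    active = [active[i] for i in order]

    seated_parts = _split_total(rng, totals["seated"], len(active) + 1,
                                min(min_bout_s, totals["seated"] / (len(active) + 1)))
    bouts: list[Bout] = []
    for i, bout in enumerate(active):
        bouts.append(Bout("seated", seated_parts[i], met_targets["seated"]))
        bouts.append(bout)
    bouts.append(Bout("seated", seated_parts[-1], met_targets["seated"]))
    return ActivitySchedule(bouts=tuple(bouts))


def _ee_kinetics(ee_ss: np.ndarray, tau_s: float, dt: float) -> np.ndarray:
    """First-order relaxation of EE toward its steady-state step function."""
    if tau_s <= 0:
        return ee_ss.copy()
    ee = np.empty_like(ee_ss)
    ee[0] = ee_ss[0]
    decay = np.exp(-dt / tau_s)
    for i in range(1, len(ee_ss)):
        ee[i] = ee_ss[i] + (ee[i - 1] - ee_ss[i]) * decay
    return ee


def _synth_site(
    rng: np.random.Generator,
    site: str,
    schedule: ActivitySchedule,
    params: SessionParams,
    start_time: pd.Timestamp,
) -> RawTriaxialRecording:
    rate = params.sampling_rate_hz
    n = int(round(schedule.total_duration_s * rate))
    t = np.arange(n) / rate
    cfg = SITE_PARAMS[site]
    sig = np.tile(np.asarray(cfg["gravity"], dtype=float), (n, 1))

    weights = np.asarray(cfg["axis_weights"], dtype=float)
    start = 0.0
    for bout in schedule.bouts:
        lo = int(round(start * rate))
        hi = min(n, int(round((start + bout.duration_s) * rate)))
        start += bout.duration_s
        if hi <= lo:
            continue
        tt = t[lo:hi]
        amp = cfg["amp_per_met"] * max(bout.target_met - 1.0, 0.05)
        amp *= float(np.exp(rng.normal(0.0, BOUT_AMP_JITTER_SD)))
        freq = OSC_F0_HZ + OSC_F_SLOPE * (bout.target_met - 1.0)
        phases = rng.uniform(0, 2 * np.pi, size=(2, 3))
        for ax in range(3):
            osc = amp * weights[ax] * (
                np.sin(2 * np.pi * freq * tt + phases[0, ax])
                + 0.35 * np.sin(2 * np.pi * 2 * freq * tt + phases[1, ax])
            )
            sig[lo:hi, ax] += osc
    sig += rng.normal(0.0, SENSOR_NOISE_G, size=sig.shape)
    np.clip(sig, -DYNAMIC_RANGE_G, DYNAMIC_RANGE_G, out=sig)
    return RawTriaxialRecording(site=site, sampling_rate=rate,
                                start_time=start_time, samples=sig)


def synthesize_session(
    participant: Participant,
    schedule: ActivitySchedule,
    seed: int,
    params: SessionParams | None = None,
    start_time: pd.Timestamp | str = "2019-06-01T09:00:00",
) -> SyntheticSession:
    """Generate one complete session: truth EE, breaths, and both sites."""
    params = params or SessionParams()
    start_time = pd.Timestamp(start_time)
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF])
    rng_truth, rng_breath, rng_hip, rng_wrist = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    ree = schofield_ree(participant.sex, participant.height_m, participant.mass_kg)
    ree_min = ree.ree_kcal_per_min

    # EE path at 1-s resolution: steady-state step function + on-kinetics
    dt = 1.0
    steps = schedule.step_series(dt)
    ee_ss = ree_min * steps["target_met"].to_numpy()
    ee_det_1s = _ee_kinetics(ee_ss, params.tau_s, dt)

    slot = int(round(params.slot_s))
    n_slots = len(ee_det_1s) // slot
    ee_det = ee_det_1s[: n_slots * slot].reshape(n_slots, slot).mean(axis=1)
    slot_start = np.arange(n_slots) * params.slot_s
    mid = slot_start + params.slot_s / 2.0
    activities = [schedule.at(m).activity for m in mid]
    mets = [schedule.at(m).target_met for m in mid]

    sigma = params.ee_noise_sigma
    if sigma > 0:
        noise = np.exp(rng_truth.normal(-0.5 * sigma**2, sigma, size=n_slots))
    else:
        noise = np.ones(n_slots)
    ee_truth = ee_det * noise

    truth = pd.DataFrame(
        {
            "slot_start_s": slot_start,
            "activity": activities,
            "target_met": mets,
            "ee_det": ee_det,
            "ee_truth": ee_truth,
        }
    )

    # breaths: Weir inversion of slot truth at fixed RER, breath-level noise
    weir_denominator = WEIR_VO2 + WEIR_VCO2 * params.rer
    times, vo2s, vco2s, rrs = [], [], [], []
    t = float(rng_breath.uniform(0.2, 1.5))
    total = schedule.total_duration_s
    while t < total:
        i = min(int(t // params.slot_s), n_slots - 1)
        met_now = mets[i]
        rr = 20.0 + 5.0 * met_now
        ee_b = ee_truth[i]
        if params.breath_noise_cv > 0:
            ee_b *= max(0.0, 1.0 + rng_breath.normal(0.0, params.breath_noise_cv))
        vo2 = ee_b / weir_denominator
        times.append(t)
        vo2s.append(vo2)
        vco2s.append(params.rer * vo2)
        rrs.append(rr)
        gap = 60.0 / rr
        if params.breath_noise_cv > 0:
            gap *= float(np.clip(1.0 + rng_breath.normal(0.0, 0.1), 0.5, 1.5))
        t += gap
    breaths = make_breath_table(times, vo2s, vco2s, rrs)

    hip = _synth_site(rng_hip, "hip", schedule, params, start_time)
    wrist = _synth_site(rng_wrist, "wrist", schedule, params, start_time)

    return SyntheticSession(
        participant=participant, schedule=schedule, hip=hip, wrist=wrist,
        breaths=breaths, truth=truth, ree_kcal_min=ree_min,
        start_time=start_time, seed=seed,
    )


def noise_floor(labelled: pd.DataFrame, target: str = "ee_kcal_min") -> float:
    """Irreducible RMSE of the criterion given (subject, activity).

    The best predictor that knows the subject and the window's true
    activity state predicts the conditional mean of the criterion; the
    residual spread around that mean — slot-level lognormal noise, breath
    noise, and the kinetic lag at bout transitions that no single-window
    model can resolve — is the floor against which model RMSE is judged.
    Computed as the pooled within-(participant, activity) RMSE.
    """
    if "activity" not in labelled.columns:
        raise ValueError("labelled table needs an 'activity' column")
    resid = labelled.groupby(["participant_id", "activity"])[target].transform(
        lambda v: v - v.mean()
    )
    return float(np.sqrt(np.mean(resid.to_numpy() ** 2)))
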