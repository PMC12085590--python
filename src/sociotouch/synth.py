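"""Synthetic sessions with planted ground truth.

Every pipeline stage is testable without real recordings: the generator
emulates one animal/day of the social-touch assay — four blocks of 40 bouts
(social/object x voluntary/forced, 5 s stim / 5 s ISI) — with Poisson units
drawn from four temporal archetypes (transient-excited, sustained-excited,
suppressed, unmodulated) whose stimulus-period rate carries a
context-dependent gain, plus pose-label behavioral traces at 120 FPS with
planted aversive-facial-expression bouts, avoidance-running epochs and
saccades.  The planted parameters (archetype membership, context gains,
behavior-firing couplings, event log) are returned alongside the session so
recovery can be asserted exactly.

A single seed drives everything through independent sub-streams (units,
spikes, behavior), so behavior can be regenerated without changing spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import PoseTraces
from .session import Session
from .timeline import BoutSchedule, TrialWindow, build_bout_schedule

ARCHETYPES = ("transient_excited", "sustained_excited", "suppressed", "unmodulated")
REGIONS = ("vS1", "tSTR", "BLA")

#: Depth intervals (um) used to place synthetic units; half-open [lo, hi).
DEFAULT_REGION_BOUNDARIES = {
    "vS1": (0.0, 1200.0),
    "tSTR": (1800.0, 3000.0),
    "BLA": (3600.0, 4600.0),
}

#: 23 face labels (whisker follicles, nose, mouth, cheek, chin) plus the
#: eye outline and pupil markers used by the eye/pupil features.
FACE_LABELS = (
    [f"whisker_{i}" for i in range(1, 7)]
    + [f"nose_{i}" for i in range(1, 4)]
    + [f"mouth_{i}" for i in range(1, 5)]
    + [f"cheek_{i}" for i in range(1, 6)]
    + [f"chin_{i}" for i in range(1, 6)]
)
EYE_LABELS = [f"eye_{i}" for i in range(1, 7)]
PUPIL_LABELS = [f"pupil_{i}" for i in range(1, 5)]

BLOCKS = (
    ("voluntary", "object"),
    ("voluntary", "social"),
    ("forced", "object"),
    ("forced", "social"),
)


@dataclass(frozen=True)
class UnitGroundTruth:
    """Generative parameters of one synthetic unit."""

    unit_id: int
    region: str
    archetype: str
    baseline_rate: float  # Hz
    social_gain: float = 1.0  # multiplicative, stim period only
    object_gain: float = 1.0
    behavior_betas: Mapping[str, float] = field(default_factory=dict)
    depth: float = 0.0
    peak_to_trough: float = 500.0
    isi_violation: float = 0.02
    amplitude_cutoff: float = 0.02
    median_amplitude: float = 90.0
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if self.social_gain <= 0 or self.object_gain <= 0:
            raise ValueError("context gains must be positive")
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic assay.

    Defaults mirror the assay: 40 bouts per context/choice block, 5 s stim,
    5 s ISI, 120 FPS video.  Aversive-behavior probabilities are higher for
    object than social touch, matching the behavioral asymmetry the assay
    is built to expose.
    """

    n_units: Mapping[str, int] = field(
        default_factory=lambda: {"vS1": 20, "tSTR": 12, "BLA": 12}
    )
    archetype_proportions: Mapping[str, float] = field(
        default_factory=lambda: {a: 0.25 for a in ARCHETYPES}
    )
    n_bouts: int = 40
    stim_dur: float = 5.0
    isi_dur: float = 5.0
    blocks: Sequence[tuple[str, str]] = BLOCKS
    block_gap: float = 30.0  # s between blocks (desk-scale session spacing)
    baseline_rate_range: tuple[float, float] = (5.0, 7.0)
    #: preferred/non-preferred stim-gain ratio for preferring units; the two
    #: gains are 2r/(1+r) and 2/(1+r) so the across-context mean response is
    #: conserved (preference without amplitude inflation)
    context_gain_ratio: float = 4.0
    frac_social_pref: float = 0.25
    frac_object_pref: float = 0.25
    transient_amp: float = 5.0
    transient_tau: float = 0.4  # s
    sustained_amp: float = 1.8
    suppressed_factor: float = 0.4
    behavior_beta_scale: float = 0.0  # log-linear coupling; 0 disables
    coupled_fraction: float = 0.25
    frame_rate: float = 120.0
    behavior_noise: float = 0.5  # px jitter on pose labels
    eye_area_px2: float = 400.0
    orbital_drop: float = 0.4  # fractional eye-area reduction in a bout
    whisker_amp_px: float = 6.0  # forward displacement during protraction
    afe_duration: float = 1.5  # s
    p_afe: Mapping[str, float] = field(
        default_factory=lambda: {"object": 0.5, "social": 0.15}
    )
    p_avoid: Mapping[str, float] = field(
        default_factory=lambda: {"object": 0.5, "social": 0.1}
    )
    saccade_rate: float = 0.15  # Hz
    qc_fail_fraction: float = 0.0
    spike_dt: float = 0.01  # s, Poisson discretization
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_units.values()):
            raise ValueError("unit counts must be non-negative")
        if self.n_bouts < 0:
            raise ValueError("n_bouts must be non-negative")
        total = sum(self.archetype_proportions.values())
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("archetype proportions must sum to 1")


def _streams(config: SyntheticConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(config.rng_seed)
    children = ss.spawn(3)
    return {
        "units": np.random.default_rng(children[0]),
        "spikes": np.random.default_rng(children[1]),
        "behavior": np.random.default_rng(children[2]),
    }


def _allocate(n: int, proportions: Mapping[str, float], keys: Sequence[str]) -> list[str]:
    """Deterministic largest-remainder allocation of n items to categories."""
    props = np.array([proportions.get(k, 0.0) for k in keys], dtype=float)
    if props.sum() == 0:
        props = np.ones(len(keys))
    props = props / props.sum()
    counts = np.floor(props * n).astype(int)
    remainder = props * n - counts
    for i in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for k, c in zip(keys, counts):
        out.extend([k] * int(c))
    return out


def generate_trials(config: SyntheticConfig) -> tuple[pd.DataFrame, list[BoutSchedule]]:
    """Block-structured trial table: one block per (choice, context) pair."""
    rows = []
    schedules = []
    t = 0.0
    trial_id = 0
    for choice, context in config.blocks:
        sched = build_bout_schedule(
            config.n_bouts, config.stim_dur, config.isi_dur,
            t0=t + config.stim_dur + config.isi_dur,
        )
        schedules.append(sched)
        for stop in sched.stop_times:
            rows.append(
                {"trial_id": trial_id, "context": context, "choice": choice,
                 "t_stop_s": float(stop)}
            )
            trial_id += 1
        t += (config.n_bouts + 1) * (config.stim_dur + config.isi_dur) + config.block_gap
    return pd.DataFrame(rows, columns=["trial_id", "context", "choice", "t_stop_s"]), schedules


def generate_units(config: SyntheticConfig) -> list[UnitGroundTruth]:
    """Draw unit ground truth: archetypes, gains, baselines, QC metadata."""
    rng = _streams(config)["units"]
    units: list[UnitGroundTruth] = []
    uid = 0
    regressor_names = ("running", "orbital_area", "whisker_protraction", "saccades")
    for region in REGIONS:
        n = int(config.n_units.get(region, 0))
        archetypes = _allocate(n, config.archetype_proportions, ARCHETYPES)
        # preference planted on modulated units only; deterministic interleave
        modulated = [i for i, a in enumerate(archetypes) if a != "unmodulated"]
        n_soc = int(round(config.frac_social_pref * len(modulated)))
        n_obj = int(round(config.frac_object_pref * len(modulated)))
        r = config.context_gain_ratio
        g_hi, g_lo = 2 * r / (1 + r), 2 / (1 + r)
        pref = {}
        for j, i in enumerate(modulated):
            if j < n_soc:
                pref[i] = ("social", (g_hi, g_lo))
            elif j < n_soc + n_obj:
                pref[i] = ("object", (g_hi, g_lo))
        lo, hi = DEFAULT_REGION_BOUNDARIES[region]
        n_fail = int(round(config.qc_fail_fraction * n))
        for i, arch in enumerate(archetypes):
            social_gain = object_gain = 1.0
            if i in pref:
                side, (gg_hi, gg_lo) = pref[i]
                if side == "social":
                    social_gain, object_gain = gg_hi, gg_lo
                else:
                    social_gain, object_gain = gg_lo, gg_hi
            betas: dict[str, float] = {}
            if config.behavior_beta_scale > 0 and rng.uniform() < config.coupled_fraction:
                name = regressor_names[uid % len(regressor_names)]
                betas[name] = config.behavior_beta_scale * rng.choice([-1.0, 1.0])
            fail = i < n_fail
            units.append(
                UnitGroundTruth(
                    unit_id=uid,
                    region=region,
                    archetype=arch,
                    baseline_rate=float(rng.uniform(*config.baseline_rate_range)),
                    social_gain=social_gain,
                    object_gain=object_gain,
                    behavior_betas=betas,
                    depth=float(rng.uniform(lo, hi)),
                    peak_to_trough=float(
                        rng.uniform(450, 900) if rng.uniform() < 0.8 else rng.uniform(150, 350)
                    ),
                    isi_violation=float(rng.uniform(0.12, 0.3)) if fail else float(rng.uniform(0, 0.08)),
                    amplitude_cutoff=float(rng.uniform(0, 0.08)),
                    median_amplitude=float(rng.uniform(60, 150)),
                    qc_pass=not fail,
                )
            )
            uid += 1
    return units


def archetype_profile(config: SyntheticConfig, archetype: str, t_rel: np.ndarray) -> np.ndarray:
    """Multiplicative rate profile during the stim window; 1 outside it."""
    t_rel = np.asarray(t_rel, dtype=float)
    inside = (t_rel >= 0) & (t_rel < config.stim_dur)
    prof = np.ones_like(t_rel)
    if archetype == "transient_excited":
        prof[inside] = 1.0 + config.transient_amp * np.exp(-t_rel[inside] / config.transient_tau)
    elif archetype == "sustained_excited":
        prof[inside] = config.sustained_amp
    elif archetype == "suppressed":
        prof[inside] = config.suppressed_factor
    elif archetype != "unmodulated":
        raise ValueError(f"unknown archetype {archetype!r}")
    return prof


def rate_trace(
    unit: UnitGroundTruth,
    trials: Sequence[TrialWindow],
    config: SyntheticConfig,
    t: np.ndarray,
    regressors: Mapping[str, np.ndarray] | None = None,
    regressor_time: np.ndarray | None = None,
) -> np.ndarray:
    """Generative firing rate of one unit on the time grid ``t`` (Hz)."""
    rate = np.full_like(t, unit.baseline_rate, dtype=float)
    for tr in trials:
        sel = (t >= tr.t_stop) & (t < tr.t_stop + config.stim_dur)
        if not sel.any():
            continue
        prof = archetype_profile(config, unit.archetype, t[sel] - tr.t_stop)
        gain = unit.social_gain if tr.context == "social" else unit.object_gain
        rate[sel] = unit.baseline_rate * prof * gain
    if unit.behavior_betas and regressors is not None:
        loglin = np.zeros_like(t)
        for name, beta in unit.behavior_betas.items():
            if name not in regressors:
                continue
            z = np.asarray(regressors[name], dtype=float)
            sd = z.std()
            z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
            loglin += beta * np.interp(t, regressor_time, z)
        rate = rate * np.exp(loglin)
    return np.clip(rate, 0.0, None)


def generate_spike_trains(
    units: Sequence[UnitGroundTruth],
    trials: Sequence[TrialWindow],
    config: SyntheticConfig,
    session_end: float | None = None,
    regressors: Mapping[str, np.ndarray] | None = None,
    regressor_time: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Inhomogeneous-Poisson spike table (unit_id, spike_time_s).

    Rates are discretized at ``config.spike_dt``; counts are Poisson per bin
    and spike times uniform within their bin.
    """
    if rng is None:
        rng = _streams(config)["spikes"]
    if session_end is None:
        session_end = max(
            (tr.t_stop + config.stim_dur + config.isi_dur for tr in trials),
            default=config.stim_dur,
        )
    dt = config.spike_dt
    t = np.arange(0.0, session_end, dt)
    frames = []
    for unit in units:
        lam = rate_trace(unit, trials, config, t, regressors, regressor_time) * dt
        counts = rng.poisson(lam)
        nz = np.flatnonzero(counts)
        if nz.size == 0:
            continue
        reps = counts[nz]
        starts = np.repeat(t[nz], reps)
        times = np.sort(starts + rng.uniform(0, dt, size=starts.size))
        frames.append(pd.DataFrame({"unit_id": unit.unit_id, "spike_time_s": times}))
    if not frames:
        return pd.DataFrame(columns=["unit_id", "spike_time_s"])
    return pd.concat(frames, ignore_index=True)


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def generate_behavior_traces(
    trials: Sequence[TrialWindow],
    config: SyntheticConfig,
    session_end: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PoseTraces, pd.DataFrame, dict[str, np.ndarray]]:
    """Pose-label traces with planted events.

    Returns ``(traces, event_log, latents)``.  ``latents`` holds the ground
    truth regressor channels (running, orbital_area, whisker_protraction,
    saccades) on the frame grid; ``event_log`` lists every planted event
    with its trial and time span.
    """
    if rng is None:
        rng = _streams(config)["behavior"]
    if session_end is None:
        session_end = max(
            (tr.t_stop + config.stim_dur + config.isi_dur for tr in trials),
            default=config.stim_dur,
        )
    fps = config.frame_rate
    n = int(np.ceil(session_end * fps))
    time = np.arange(n) / fps
    events: list[dict] = []

    # --- latent channels -------------------------------------------------
    running = np.clip(_smooth(rng.normal(1.0, 0.5, n), int(fps * 0.5)), 0.0, None)
    direction = np.ones(n)
    whisker = _smooth(rng.normal(0.0, 0.15, n), int(fps * 0.25))
    area_factor = np.ones(n)
    sacc_x = np.zeros(n)

    for tr in trials:
        p_afe = config.p_afe.get(tr.context, 0.0)
        p_avoid = config.p_avoid.get(tr.context, 0.0)
        stim0 = tr.t_stop
        # aversive whisker protraction bout
        if rng.uniform() < p_afe:
            start = stim0 + rng.uniform(0, max(config.stim_dur - config.afe_duration, 0.1))
            i0, i1 = int(start * fps), int((start + config.afe_duration) * fps)
            whisker[i0:min(i1, n)] += 1.0
            events.append({"kind": "whisker_protraction", "trial_id": tr.trial_id,
                           "t_start": start, "t_stop": start + config.afe_duration})
        # orbital tightening bout
        if rng.uniform() < p_afe:
            start = stim0 + rng.uniform(0, max(config.stim_dur - config.afe_duration, 0.1))
            i0, i1 = int(start * fps), int((start + config.afe_duration) * fps)
            area_factor[i0:min(i1, n)] = 1.0 - config.orbital_drop
            events.append({"kind": "orbital_tightening", "trial_id": tr.trial_id,
                           "t_start": start, "t_stop": start + config.afe_duration})
        # avoidance running epoch over the first half of the stim
        if rng.uniform() < p_avoid:
            i0, i1 = int(stim0 * fps), int((stim0 + config.stim_dur / 2) * fps)
            direction[i0:min(i1, n)] = -1.0
            events.append({"kind": "avoidance", "trial_id": tr.trial_id,
                           "t_start": stim0, "t_stop": stim0 + config.stim_dur / 2})

    # saccades: homogeneous Poisson events, alternating direction
    n_sacc = rng.poisson(config.saccade_rate * session_end)
    sacc_times = np.sort(rng.uniform(0, session_end, n_sacc))
    sign = 1.0
    for st in sacc_times:
        i = int(st * fps)
        if i + 2 >= n:
            continue
        sacc_x[i:] += sign * 8.0
        events.append({"kind": "saccade", "trial_id": -1, "t_start": st, "t_stop": st,
                       "direction": "temporal" if sign > 0 else "nasal"})
        sign = -sign

    latents = {
        "running": running,
        "orbital_area": area_factor * config.eye_area_px2,
        "whisker_protraction": whisker,
        "saccades": sacc_x,
    }

    # --- render pose labels ----------------------------------------------
    labels: dict[str, np.ndarray] = {}
    jitter = lambda: rng.normal(0.0, config.behavior_noise, size=(n, 2))
    base = {}
    for i, name in enumerate(FACE_LABELS):
        base[name] = np.array([100.0 + 12.0 * i, 200.0 + 7.0 * (i % 5)])
    for name in FACE_LABELS:
        xy = base[name] + jitter()
        if name.startswith("whisker_"):
            xy[:, 0] += config.whisker_amp_px * whisker
        labels[name] = xy
    # eye outline: regular hexagon whose area tracks the orbital latent
    r0 = np.sqrt(config.eye_area_px2 / (1.5 * np.sqrt(3.0)))
    r_t = r0 * np.sqrt(area_factor)
    eye_center = np.array([320.0, 120.0])
    for j, name in enumerate(EYE_LABELS):
        ang = 2 * np.pi * j / len(EYE_LABELS)
        labels[name] = (
            eye_center
            + np.column_stack([r_t * np.cos(ang), r_t * np.sin(ang)])
            + rng.normal(0.0, config.behavior_noise * 0.2, size=(n, 2))
        )
    # pupil markers around a drifting center carrying the saccade channel
    pupil_center = np.column_stack([320.0 + sacc_x, np.full(n, 120.0)])
    for j, name in enumerate(PUPIL_LABELS):
        ang = 2 * np.pi * j / len(PUPIL_LABELS)
        offset = 3.0 * np.array([np.cos(ang), np.sin(ang)])
        labels[name] = pupil_center + offset + rng.normal(
            0.0, config.behavior_noise * 0.2, size=(n, 2)
        )

    traces = PoseTraces(
        time=time,
        labels=labels,
        ball_motion=running,
        ball_direction=direction,
    )
    event_log = pd.DataFrame(
        events, columns=["kind", "trial_id", "t_start", "t_stop", "direction"]
    )
    return traces, event_log, latents


def generate_session(
    config: SyntheticConfig | None = None, include_behavior: bool = True
) -> tuple[Session, dict]:
    """Full synthetic session plus its ground truth.

    Ground truth holds the unit parameter list, the planted behavioral event
    log, the latent regressor channels, and the config.
    """
    config = config or SyntheticConfig()
    streams = _streams(config)
    trials_df, _ = generate_trials(config)
    trial_windows = [
        TrialWindow(int(r.trial_id), r.context, r.choice, float(r.t_stop_s))
        for r in trials_df.itertuples()
    ]
    session_end = (
        float(trials_df.t_stop_s.max()) + config.stim_dur + config.isi_dur
        if len(trials_df)
        else config.stim_dur + config.isi_dur
    )
    units = generate_units(config)

    behavior = None
    event_log = pd.DataFrame(columns=["kind", "trial_id", "t_start", "t_stop", "direction"])
    latents: dict[str, np.ndarray] = {}
    reg_time = None
    if include_behavior:
        behavior, event_log, latents = generate_behavior_traces(
            trial_windows, config, session_end, rng=streams["behavior"]
        )
        reg_time = behavior.time

    spikes = generate_spike_trains(
        units, trial_windows, config, session_end,
        regressors=latents if latents else None,
        regressor_time=reg_time,
        rng=streams["spikes"],
    )
    units_df = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "region": [u.region for u in units],
            "depth_um": [u.depth for u in units],
            "peak_to_trough_us": [u.peak_to_trough for u in units],
            "isi_violation": [u.isi_violation for u in units],
            "amplitude_cutoff": [u.amplitude_cutoff for u in units],
            "median_amplitude_uv": [u.median_amplitude for u in units],
        }
    )
    session = Session(
        trials=trials_df,
        spikes=spikes,
        units=units_df,
        behavior=behavior,
        metadata={
            "animal_id": "synthetic",
            "genotype": "WT",
            "stim_dur": config.stim_dur,
            "isi_dur": config.isi_dur,
            "frame_rate": config.frame_rate,
            "rng_seed": config.rng_seed,
            "session_end": session_end,
        },
    )
    ground_truth = {
        "units": units,
        "events": event_log,
        "latents": latents,
        "config": config,
    }
    return session, ground_truth
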