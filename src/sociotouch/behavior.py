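"""Behavioral feature extraction from pose labels and ball motion.

Inputs are fixed-frame-rate time series of tracked marker coordinates on the
face (whisker follicles, nose, mouth, cheeks, chin), the eye outline, and the
pupil, plus ball motion energy with an optional signed running direction.
Features: per-marker motion energy (two-frame displacement), eye area
(shoelace polygon of the outline markers), temporal-nasal saccades (fast
pupil x displacement), aversive-facial-expression (AFE) bouts of whisker
protraction and orbital tightening, and the avoidance-running fraction.
Frames flagged in the exclusion mask (blinks, grooming, occlusion) never
contribute to any feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

FRAME_RATE = 120.0
AFE_MIN_DURATION = 0.5  # s
AFE_MERGE_GAP = 0.25  # s
ORBITAL_KAPPA = 0.3  # area drop fraction defining orbital tightening


@dataclass
class PoseTraces:
    """Pose-label coordinates and ball motion at a fixed frame rate.

    ``labels`` maps label name -> (n_frames, 2) x/y pixel coordinates.
    Excluded frames are masked out of every downstream feature.
    """

    time: np.ndarray  # seconds, uniform spacing
    labels: dict[str, np.ndarray]
    ball_motion: np.ndarray | None = None
    ball_direction: np.ndarray | None = None  # signed; negative = away from stimulus
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = len(self.time)
        if n > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame spacing must be uniform")
        for name, xy in self.labels.items():
            if np.asarray(xy).shape != (n, 2):
                raise ValueError(f"label {name!r} must have shape (n_frames, 2)")
        if self.exclusion_mask is None:
            self.exclusion_mask = np.zeros(n, dtype=bool)
        else:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if len(self.exclusion_mask) != n:
                raise ValueError("exclusion mask length mismatch")

    @property
    def frame_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    def label_names(self, prefix: str = "") -> list[str]:
        return sorted(k for k in self.labels if k.startswith(prefix))


@dataclass
class BehaviorEvents:
    """Per-trial behavioral summary."""

    trial_id: int
    whisker_protraction_bouts: int = 0
    whisker_protraction_fraction: float = 0.0
    orbital_tightening_bouts: int = 0
    orbital_tightening_fraction: float = 0.0
    running_avoidance_fraction: float = float("nan")
    saccade_count: int = 0
    saccade_net_direction: float = 0.0


def exclude_frames(traces: PoseTraces, mask: np.ndarray) -> PoseTraces:
    """OR-combine ``mask`` into the exclusion mask (returns a new PoseTraces)."""
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(traces.time):
        raise ValueError("mask length does not match traces")
    return replace(traces, exclusion_mask=traces.exclusion_mask | mask)


def label_motion_energy(traces: PoseTraces, label: str) -> np.ndarray:
    """Two-frame displacement magnitude of one marker, per frame.

    energy[t] = ||xy[t] - xy[t-2]||; the first two frames are 0.  Excluded
    frames (or frames whose two-back reference is excluded) are NaN.
    """
    if label not in traces.labels:
        raise KeyError(f"unknown label {label!r}")
    xy = np.asarray(traces.labels[label], dtype=float)
    energy = np.zeros(len(xy))
    if len(xy) > 2:
        energy[2:] = np.linalg.norm(xy[2:] - xy[:-2], axis=1)
    bad = traces.exclusion_mask.copy()
    bad[2:] |= traces.exclusion_mask[:-2]
    energy[bad] = np.nan
    return energy


def eye_area_trace(traces: PoseTraces, eye_prefix: str = "eye_") -> np.ndarray:
    """Shoelace polygon area of the eye-outline markers, per frame (px^2)."""
    names = traces.label_names(eye_prefix)
    if len(names) < 3:
        raise ValueError("eye area needs at least 3 eye-outline labels")
    pts = np.stack([traces.labels[n] for n in names], axis=1)  # frames x pts x 2
    x, y = pts[..., 0], pts[..., 1]
    xr, yr = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
    area = 0.5 * np.abs((x * yr - xr * y).sum(axis=1))
    area[traces.exclusion_mask] = np.nan
    return area


def pupil_center(traces: PoseTraces, pupil_prefix: str = "pupil_") -> np.ndarray:
    names = traces.label_names(pupil_prefix)
    if not names:
        raise ValueError("no pupil labels present")
    return np.stack([traces.labels[n] for n in names], axis=1).mean(axis=1)


def detect_saccades(
    traces: PoseTraces,
    velocity_threshold: float,
    pupil_prefix: str = "pupil_",
) -> pd.DataFrame:
    """Fast temporal-nasal pupil displacements.

    A saccade is a contiguous run of frames where |dx/dt| of the pupil
    centroid x-coordinate exceeds the threshold (px/s); direction is
    ``temporal`` for positive dx, ``nasal`` for negative.  Pure y-axis
    motion never triggers.
    """
    center = pupil_center(traces, pupil_prefix)
    dt = traces.time[1] - traces.time[0] if len(traces.time) > 1 else 1.0
    vx = np.zeros(len(center))
    vx[1:] = np.diff(center[:, 0]) / dt
    bad = traces.exclusion_mask.copy()
    bad[1:] |= traces.exclusion_mask[:-1]
    vx[bad] = 0.0
    fast = np.abs(vx) > velocity_threshold
    events = []
    for start, stop in _runs(fast):
        dx = center[stop - 1, 0] - center[max(start - 1, 0), 0]
        events.append(
            {
                "t_start": traces.time[start],
                "t_stop": traces.time[stop - 1],
                "direction": "temporal" if dx > 0 else "nasal",
                "amplitude_px": float(abs(dx)),
            }
        )
    return pd.DataFrame(events, columns=["t_start", "t_stop", "direction", "amplitude_px"])


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    flags = np.asarray(flags, dtype=bool)
    if not flags.any():
        return []
    d = np.diff(flags.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        stops.append(len(flags))
    return list(zip(starts, stops))


def detect_afe_bouts(
    feature: np.ndarray,
    time: np.ndarray,
    kind: str,
    threshold: float,
    min_duration: float = AFE_MIN_DURATION,
    merge_gap: float = AFE_MERGE_GAP,
) -> pd.DataFrame:
    """Aversive-facial-expression bouts in a feature series.

    ``kind="whisker_protraction"`` marks frames where the feature exceeds
    the threshold; ``kind="orbital_tightening"`` marks frames where it falls
    below (eye area under the tightened-area threshold).  NaN (excluded)
    frames never mark.  Supra-threshold epochs closer than ``merge_gap`` are
    merged; epochs shorter than ``min_duration`` are discarded.
    """
    if kind not in ("whisker_protraction", "orbital_tightening"):
        raise ValueError(f"unknown AFE kind {kind!r}")
    feature = np.asarray(feature, dtype=float)
    time = np.asarray(time, dtype=float)
    with np.errstate(invalid="ignore"):
        above = feature > threshold if kind == "whisker_protraction" else feature < threshold
    above &= np.isfinite(feature)
    runs = _runs(above)
    dt = time[1] - time[0] if len(time) > 1 else 1.0
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and (time[start] - time[merged[-1][1] - 1]) < merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    bouts = [
        {"t_start": time[a], "t_stop": time[b - 1] + dt, "duration": (b - a) * dt}
        for a, b in merged
        if (b - a) * dt >= min_duration
    ]
    return pd.DataFrame(bouts, columns=["t_start", "t_stop", "duration"])


def bout_occupancy(bouts: pd.DataFrame, t_start: float, t_stop: float) -> tuple[int, float]:
    """Count of bouts overlapping [t_start, t_stop) and fraction of time covered."""
    if t_stop <= t_start:
        raise ValueError("empty window")
    count, covered = 0, 0.0
    for _, b in bouts.iterrows():
        lo, hi = max(b.t_start, t_start), min(b.t_stop, t_stop)
        if hi > lo:
            count += 1
            covered += hi - lo
    return count, covered / (t_stop - t_start)


def running_avoidance_fraction(
    ball_motion: np.ndarray,
    ball_direction: np.ndarray,
    time: np.ndarray,
    window: tuple[float, float],
    motion_threshold: float = 0.0,
) -> float:
    """Fraction of running time spent moving away from the stimulus.

    Running frames have ball motion above ``motion_threshold``; avoidance
    frames additionally have negative signed direction.  Returns NaN when
    the animal never runs in the window (0/0).
    """
    time = np.asarray(time, dtype=float)
    sel = (time >= window[0]) & (time < window[1])
    motion = np.asarray(ball_motion, dtype=float)[sel]
    direction = np.asarray(ball_direction, dtype=float)[sel]
    running = np.isfinite(motion) & (motion > motion_threshold)
    if not running.any():
        return float("nan")
    return float((running & (direction < 0)).sum() / running.sum())
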