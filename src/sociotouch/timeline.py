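"""Bout schedule and platform kinematics.

The social-touch assay presents a stimulus (a stranger mouse or an inanimate
object) on a motorized platform in repeated bouts: the platform stops at the
touch position for ``stim_dur`` seconds, then withdraws and returns during an
interstimulus interval (ISI) of ``isi_dur`` seconds.  All trial-aligned
analyses downstream take t = 0 at the moment the platform stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CONTEXTS = ("social", "object")
CHOICES = ("voluntary", "forced")

#: Assay defaults: 5 s stop (touch), 5 s ISI, 1.65 cm/s platform speed,
#: 1 cm withdrawal during the ISI.
STIM_DUR = 5.0
ISI_DUR = 5.0
PLATFORM_SPEED = 1.65
WITHDRAW_DIST = 1.0


@dataclass(frozen=True)
class BoutSchedule:
    """Stop times and kinematic parameters of one presentation block."""

    n_bouts: int
    stim_dur: float
    isi_dur: float
    platform_speed: float
    withdraw_dist: float
    stop_times: np.ndarray  # seconds, one per bout, strictly increasing

    @property
    def cycle(self) -> float:
        """Duration of one full bout (stim + ISI), seconds."""
        return self.stim_dur + self.isi_dur

    @property
    def total_duration(self) -> float:
        return self.n_bouts * self.cycle

    def __post_init__(self) -> None:
        if self.stim_dur <= 0 or self.isi_dur <= 0:
            raise ValueError("stim_dur and isi_dur must be positive")
        stops = np.asarray(self.stop_times, dtype=float)
        object.__setattr__(self, "stop_times", stops)
        if len(stops) != self.n_bouts:
            raise ValueError("n_bouts must equal len(stop_times)")
        if len(stops) > 1 and not np.all(np.diff(stops) > 0):
            raise ValueError("stop_times must be strictly increasing")


@dataclass(frozen=True)
class TrialWindow:
    """One presentation, aligned on the platform stop (t_stop)."""

    trial_id: int
    context: str
    choice: str
    t_stop: float
    analysis_window: tuple[float, float] = (-2.0, 7.0)

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if self.choice not in CHOICES:
            raise ValueError(f"choice must be one of {CHOICES}, got {self.choice!r}")
        lo, hi = self.analysis_window
        if not lo < hi:
            raise ValueError("analysis_window start must precede end")


def build_bout_schedule(
    n_bouts: int,
    stim_dur: float = STIM_DUR,
    isi_dur: float = ISI_DUR,
    t0: float = 0.0,
    platform_speed: float = PLATFORM_SPEED,
    withdraw_dist: float = WITHDRAW_DIST,
) -> BoutSchedule:
    """Regular bout schedule: stop_times[i] = t0 + i * (stim_dur + isi_dur)."""
    if n_bouts < 0:
        raise ValueError("n_bouts must be non-negative")
    if stim_dur <= 0 or isi_dur <= 0:
        raise ValueError("stim_dur and isi_dur must be positive")
    stops = t0 + np.arange(n_bouts) * (stim_dur + isi_dur)
    return BoutSchedule(
        n_bouts=n_bouts,
        stim_dur=stim_dur,
        isi_dur=isi_dur,
        platform_speed=platform_speed,
        withdraw_dist=withdraw_dist,
        stop_times=stops,
    )


def count_bouts_in_session(
    session_dur: float, stim_dur: float = STIM_DUR, isi_dur: float = ISI_DUR
) -> int:
    """Number of complete bouts fitting in a session: floor(dur / cycle).

    A 30-min session at 5 s stim + 5 s ISI holds exactly 180 presentations.
    """
    if session_dur < 0:
        raise ValueError("session_dur must be non-negative")
    if stim_dur <= 0 or isi_dur <= 0:
        raise ValueError("stim_dur and isi_dur must be positive")
    return int(np.floor(session_dur / (stim_dur + isi_dur)))


def travel_time(withdraw_dist: float = WITHDRAW_DIST, speed: float = PLATFORM_SPEED) -> float:
    """Round-trip platform travel time within an ISI: 2 * dist / speed.

    At the assay values (1 cm at 1.65 cm/s) this is the 1.2 s the platform
    spends moving during each 5 s ISI.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if withdraw_dist < 0:
        raise ValueError("withdraw_dist must be non-negative")
    return 2.0 * withdraw_dist / speed


def platform_position_trace(schedule: BoutSchedule, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Platform displacement from the touch position, sampled every ``dt`` s.

    During stim the platform sits at the touch position (0 cm).  During each
    ISI it makes a triangular excursion: away at +speed to ``withdraw_dist``,
    a hold at the far position, and back at -speed so that it stops again at
    the next bout's t_stop.

    Returns ``(t, x)`` with t spanning [first stop - cycle, last stop + stim].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cycle = schedule.cycle
    one_way = schedule.withdraw_dist / schedule.platform_speed
    if 2 * one_way > schedule.isi_dur:
        raise ValueError("withdrawal round trip does not fit in the ISI")
    if schedule.n_bouts == 0:
        return np.empty(0), np.empty(0)
    t_start = schedule.stop_times[0] - cycle
    t_end = schedule.stop_times[-1] + schedule.stim_dur
    t = np.arange(t_start, t_end + dt / 2, dt)
    # phase within the bout cycle, measured from the platform stop
    phase = (t - schedule.stop_times[0]) % cycle
    x = np.zeros_like(t)
    in_isi = phase >= schedule.stim_dur
    u = phase[in_isi] - schedule.stim_dur  # time into the ISI
    away = np.minimum(u, one_way) * schedule.platform_speed
    back = np.maximum(schedule.isi_dur - u, 0.0)
    back = np.minimum(back, one_way) * schedule.platform_speed
    x[in_isi] = np.minimum(away, back)
    return t, x
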