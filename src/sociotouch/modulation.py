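"""Modulation-index family: stimulus-period vs. ISI firing-rate contrast.

MI = (FR_stim - FR_ISI) / (FR_stim + FR_ISI), bounded in [-1, 1], computed
over one of three window variants keyed to a unit's temporal response type:

* ``STIM``       - the full 5 s touch period vs. the following 5 s ISI,
* ``SHORTSTIM``  - the first 3 s of touch vs. the 3 s before touch onset,
* ``PLATFORM``   - [-1, +1] s around the platform stop vs. [-3, -1] s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spikes import window_rates
from .timeline import TrialWindow

MI_VARIANTS = ("STIM", "SHORTSTIM", "PLATFORM")

_WINDOWS = {
    "STIM": ((0.0, 5.0), (5.0, 10.0)),
    "SHORTSTIM": ((0.0, 3.0), (-3.0, 0.0)),
    "PLATFORM": ((-1.0, 1.0), (-3.0, -1.0)),
}


@dataclass(frozen=True)
class ModulationResult:
    unit_id: int
    context: str
    choice: str
    variant: str
    fr_stim: float
    fr_isi: float
    mi: float  # NaN when both rates are zero (degenerate)


def modulation_index(fr_stim: float, fr_isi: float) -> float:
    """(FR_stim - FR_ISI) / (FR_stim + FR_ISI); NaN when both rates are 0."""
    if fr_stim < 0 or fr_isi < 0:
        raise ValueError("firing rates must be non-negative")
    total = fr_stim + fr_isi
    if total == 0:
        return math.nan
    return (fr_stim - fr_isi) / total


def mi_windows(variant: str) -> tuple[tuple[float, float], tuple[float, float]]:
    """(stim_window, isi_window) in seconds relative to the platform stop."""
    try:
        return _WINDOWS[variant]
    except KeyError:
        raise ValueError(f"unknown MI variant {variant!r}; expected one of {MI_VARIANTS}") from None


def unit_modulation(
    spike_times: np.ndarray,
    trials: Sequence[TrialWindow],
    variant: str = "STIM",
    unit_id: int = -1,
) -> ModulationResult:
    """MI of one unit over a set of trials (single context/choice group).

    FR_stim and FR_ISI are the trial-averaged mean rates in the variant's
    windows; the MI is taken of these averages.
    """
    stim_w, isi_w = mi_windows(variant)
    fr_stim = float(np.mean(window_rates(spike_times, trials, stim_w))) if trials else math.nan
    fr_isi = float(np.mean(window_rates(spike_times, trials, isi_w))) if trials else math.nan
    contexts = {t.context for t in trials}
    choices = {t.choice for t in trials}
    return ModulationResult(
        unit_id=unit_id,
        context=contexts.pop() if len(contexts) == 1 else "mixed",
        choice=choices.pop() if len(choices) == 1 else "mixed",
        variant=variant,
        fr_stim=fr_stim,
        fr_isi=fr_isi,
        mi=modulation_index(fr_stim, fr_isi) if trials else math.nan,
    )


def delta_modulation(mi_social: float, mi_object: float) -> float:
    """Context contrast: MI_social - MI_object (NaN propagates)."""
    return mi_social - mi_object


def per_trial_modulation(
    spike_times: np.ndarray, trials: Sequence[TrialWindow], variant: str = "STIM"
) -> np.ndarray:
    """MI of each trial separately (used for the aversion-epoch split)."""
    stim_w, isi_w = mi_windows(variant)
    fr_s = window_rates(spike_times, trials, stim_w)
    fr_i = window_rates(spike_times, trials, isi_w)
    with np.errstate(invalid="ignore"):
        return np.where(fr_s + fr_i > 0, (fr_s - fr_i) / (fr_s + fr_i), np.nan)


def aversion_split_modulation(
    spike_times: np.ndarray,
    trials: Sequence[TrialWindow],
    aversion_flags: Sequence[bool],
    variant: str = "STIM",
) -> tuple[float, float]:
    """MI computed separately over aversive and non-aversive presentations.

    Returns ``(mi_aversive, mi_nonaversive)``; an empty class yields NaN for
    that entry.
    """
    if len(aversion_flags) != len(trials):
        raise ValueError("one aversion flag per trial required")
    flags = np.asarray(aversion_flags, dtype=bool)
    trials = list(trials)
    out = []
    for sel in (flags, ~flags):
        sub = [t for t, keep in zip(trials, sel) if keep]
        if not sub:
            out.append(math.nan)
        else:
            out.append(unit_modulation(spike_times, sub, variant).mi)
    return out[0], out[1]


def variant_for_response(response_class: str, peak_latency: float | None = None) -> str:
    """Window variant keyed to a cluster's temporal response type.

    Onset-transient clusters (peak within 1 s of the stop) use ``PLATFORM``;
    sustained responses use ``STIM``; mixed onset+sustained use ``SHORTSTIM``.
    Weak/unmodulated classes default to ``STIM``.
    """
    if response_class not in ("excited", "suppressed"):
        return "STIM"
    if peak_latency is None:
        return "STIM"
    if peak_latency <= 1.0:
        return "PLATFORM"
    if peak_latency <= 3.0:
        return "SHORTSTIM"
    return "STIM"
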