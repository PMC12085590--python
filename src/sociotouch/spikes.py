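"""Unit quality control, cell-type/region assignment, and z-scored PSTHs.

Firing-rate estimation follows the standard pipeline for trial-based
extracellular recordings: spike counts in 50 ms bins divided by bin width,
a 250 ms centered moving average, alignment on the platform stop over
[-2, +7] s, trial averaging, and a z-score against the pre-touch ISI
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .timeline import TrialWindow

#: Default unit QC thresholds: ISI-violation fraction < 0.10,
#: amplitude-cutoff fraction < 0.10, median spike amplitude > 50 uV.
QC_ISI_VIOLATION_MAX = 0.10
QC_AMP_CUTOFF_MAX = 0.10
QC_MEDIAN_AMPLITUDE_MIN = 50.0

#: Regular-spiking boundary: waveform peak-to-trough >= 400 us (inclusive).
RS_PEAK_TO_TROUGH_US = 400.0

BIN_WIDTH = 0.050  # s
SMOOTH_WINDOW = 0.250  # s
ALIGN_WINDOW = (-2.0, 7.0)  # s relative to platform stop


@dataclass(frozen=True)
class UnitMeta:
    """Spike-sorting metadata for one isolated unit."""

    unit_id: int
    depth: float  # um below pia
    peak_to_trough: float | None = None  # us
    isi_violation: float | None = None  # fraction in [0, 1]
    amplitude_cutoff: float | None = None  # fraction in [0, 1]
    median_amplitude: float | None = None  # uV


@dataclass
class PSTHMatrix:
    """Trial-averaged, z-scored responses: one row per unit.

    ``values`` has shape (n_units, n_bins); ``time_bins`` holds bin-center
    times in seconds relative to the platform stop.
    """

    unit_ids: np.ndarray
    time_bins: np.ndarray
    values: np.ndarray
    window: tuple[float, float] = ALIGN_WINDOW
    normalization: str = "ISI-baseline"
    flagged_units: list = field(default_factory=list)


def qc_filter_units(
    units: Iterable[UnitMeta],
    thresholds: tuple[float, float, float] = (
        QC_ISI_VIOLATION_MAX,
        QC_AMP_CUTOFF_MAX,
        QC_MEDIAN_AMPLITUDE_MIN,
    ),
) -> tuple[list[UnitMeta], dict[int, list[str]]]:
    """Keep units passing all three QC criteria; report reasons for the rest.

    A unit is kept iff isi_violation < thresholds[0], amplitude_cutoff <
    thresholds[1], and median_amplitude > thresholds[2].  A missing metric
    rejects the unit with reason ``"missing:<metric>"``.
    """
    isi_max, amp_max, med_min = thresholds
    kept: list[UnitMeta] = []
    rejected: dict[int, list[str]] = {}
    for u in units:
        reasons = []
        for name, value in (
            ("isi_violation", u.isi_violation),
            ("amplitude_cutoff", u.amplitude_cutoff),
            ("median_amplitude", u.median_amplitude),
        ):
            if value is None or not np.isfinite(value):
                reasons.append(f"missing:{name}")
        if not reasons:
            if not u.isi_violation < isi_max:
                reasons.append("isi_violation")
            if not u.amplitude_cutoff < amp_max:
                reasons.append("amplitude_cutoff")
            if not u.median_amplitude > med_min:
                reasons.append("median_amplitude")
        if reasons:
            rejected[u.unit_id] = reasons
        else:
            kept.append(u)
    return kept, rejected


def classify_unit_types(units: Iterable[UnitMeta]) -> dict[int, str]:
    """Regular-spiking (RS) iff peak-to-trough >= 400 us; else ``other``."""
    out = {}
    for u in units:
        if u.peak_to_trough is None:
            raise ValueError(f"unit {u.unit_id}: peak_to_trough missing")
        out[u.unit_id] = "RS" if u.peak_to_trough >= RS_PEAK_TO_TROUGH_US else "other"
    return out


def assign_regions_by_depth(
    units: Iterable[UnitMeta], boundaries: Mapping[str, tuple[float, float]]
) -> dict[int, str]:
    """Assign each unit to a region by half-open depth interval [min, max).

    ``boundaries`` maps region name -> (min_depth, max_depth) in um, ordered
    dorsal to ventral; intervals must not overlap.  Depths outside every
    interval map to ``"unassigned"``.
    """
    ivals = sorted(boundaries.items(), key=lambda kv: kv[1][0])
    for (ra, (a0, a1)), (rb, (b0, b1)) in zip(ivals, ivals[1:]):
        if a1 > b0:
            raise ValueError(f"overlapping depth boundaries: {ra} and {rb}")
    out = {}
    for u in units:
        region = "unassigned"
        for name, (lo, hi) in ivals:
            if lo <= u.depth < hi:
                region = name
                break
        out[u.unit_id] = region
    return out


def bin_firing_rates(
    spike_times: Sequence[float],
    bin_width: float = BIN_WIDTH,
    t_start: float = 0.0,
    t_end: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned firing-rate estimate: counts in half-open bins [t, t+dt) / dt.

    Returns ``(bin_centers, rates_hz)``.  Conservation holds exactly:
    sum(rates) * bin_width equals the number of spikes in [t_start, t_end).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    spikes = np.asarray(spike_times, dtype=float)
    if t_end is None:
        t_end = float(spikes.max()) + bin_width if spikes.size else t_start + bin_width
    n_bins = int(np.ceil((t_end - t_start) / bin_width))
    edges = t_start + np.arange(n_bins + 1) * bin_width
    # np.histogram closes the last bin on the right; drop edge spikes first so
    # every bin is half-open [t, t+dt)
    spikes = spikes[(spikes >= edges[0]) & (spikes < edges[-1])]
    counts, _ = np.histogram(spikes, bins=edges)
    centers = edges[:-1] + bin_width / 2
    return centers, counts / bin_width


def smooth_rates(rates: np.ndarray, window: float = SMOOTH_WINDOW, bin_width: float = BIN_WIDTH) -> np.ndarray:
    """Centered moving average over ``window`` seconds.

    The window must be a positive multiple of the bin width.  Edges use a
    shrinking window (no padding), so a constant input is returned unchanged.
    """
    if window < bin_width:
        raise ValueError("smoothing window must be at least one bin wide")
    n = int(round(window / bin_width))
    if abs(n * bin_width - window) > 1e-9:
        raise ValueError("smoothing window must be a multiple of the bin width")
    if n == 1:
        return np.asarray(rates, dtype=float).copy()
    rates = np.asarray(rates, dtype=float)
    kernel = np.ones(n)
    num = np.convolve(rates, kernel, mode="same")
    den = np.convolve(np.ones_like(rates), kernel, mode="same")
    return num / den


def trial_align_psth(
    times: np.ndarray,
    rates: np.ndarray,
    trials: Sequence[TrialWindow],
    window: tuple[float, float] = ALIGN_WINDOW,
    bin_width: float = BIN_WIDTH,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Align a session-long rate series on each trial's platform stop.

    Returns ``(rel_times, per_trial, average, dropped)`` where ``per_trial``
    has shape (n_kept_trials, n_bins), ``average`` is its mean over trials
    and ``dropped`` lists trial_ids extending past the recorded series.
    """
    times = np.asarray(times, dtype=float)
    rates = np.asarray(rates, dtype=float)
    n_bins = int(round((window[1] - window[0]) / bin_width))
    rel_times = window[0] + (np.arange(n_bins) + 0.5) * bin_width
    t0 = times[0] - bin_width / 2  # left edge of the first bin
    rows, dropped = [], []
    for tr in trials:
        start = tr.t_stop + window[0]
        i0 = int(round((start - t0) / bin_width))
        i1 = i0 + n_bins
        if i0 < 0 or i1 > len(rates):
            dropped.append(tr.trial_id)
            continue
        rows.append(rates[i0:i1])
    per_trial = np.asarray(rows) if rows else np.empty((0, n_bins))
    average = per_trial.mean(axis=0) if len(rows) else np.full(n_bins, np.nan)
    return rel_times, per_trial, average, dropped


def zscore_to_isi(
    psth: np.ndarray,
    time_bins: np.ndarray,
    isi_window: tuple[float, float] = (-2.0, 0.0),
    eps: float = 0.1,
) -> tuple[np.ndarray, bool]:
    """Z-score a PSTH against its pre-touch ISI baseline.

    ``psth`` may be 1-D (trial average) or 2-D (trials x bins); the baseline
    mean and SD pool all ISI bins (and trials).  If the baseline SD is zero
    the configured floor ``eps`` is substituted and the unit is flagged.

    Returns ``(z, flagged)``.
    """
    psth = np.asarray(psth, dtype=float)
    time_bins = np.asarray(time_bins, dtype=float)
    if isi_window[1] > 0:
        raise ValueError("ISI baseline window must end at or before t=0")
    mask = (time_bins >= isi_window[0]) & (time_bins < isi_window[1])
    if not mask.any():
        raise ValueError("ISI baseline window contains no bins")
    base = psth[..., mask]
    mu = float(np.nanmean(base))
    sd = float(np.nanstd(base))
    flagged = sd == 0.0
    if flagged:
        sd = eps
    return (psth - mu) / sd, flagged


def unit_psth_matrix(
    spikes_by_unit: Mapping[int, np.ndarray],
    trials: Sequence[TrialWindow],
    session_end: float | None = None,
    bin_width: float = BIN_WIDTH,
    smooth_window: float = SMOOTH_WINDOW,
    window: tuple[float, float] = ALIGN_WINDOW,
    isi_window: tuple[float, float] = (-2.0, 0.0),
) -> PSTHMatrix:
    """Full per-unit pipeline: bin, smooth, align, trial-average, z-score."""
    unit_ids = np.asarray(sorted(spikes_by_unit), dtype=int)
    if session_end is None:
        session_end = max(
            (tr.t_stop + window[1] for tr in trials), default=window[1]
        ) + bin_width
    rows, flagged = [], []
    rel = None
    for uid in unit_ids:
        times, rates = bin_firing_rates(
            spikes_by_unit[uid], bin_width, t_start=0.0, t_end=session_end
        )
        sm = smooth_rates(rates, smooth_window, bin_width)
        rel, _, avg, _ = trial_align_psth(times, sm, trials, window, bin_width)
        z, flag = zscore_to_isi(avg, rel, isi_window)
        rows.append(z)
        if flag:
            flagged.append(int(uid))
    values = np.asarray(rows) if rows else np.empty((0, 0))
    return PSTHMatrix(
        unit_ids=unit_ids,
        time_bins=rel if rel is not None else np.empty(0),
        values=values,
        window=window,
        flagged_units=flagged,
    )


def window_rates(
    spike_times: np.ndarray,
    trials: Sequence[TrialWindow],
    window: tuple[float, float],
) -> np.ndarray:
    """Mean firing rate (Hz) of one unit in ``window`` (relative to t_stop) per trial."""
    spikes = np.asarray(spike_times, dtype=float)
    lo, hi = window
    if not lo < hi:
        raise ValueError("window start must precede end")
    out = np.empty(len(trials))
    for i, tr in enumerate(trials):
        a, b = tr.t_stop + lo, tr.t_stop + hi
        out[i] = np.count_nonzero((spikes >= a) & (spikes < b)) / (b - a)
    return out
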