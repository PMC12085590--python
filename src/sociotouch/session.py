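"""Session container and delimited-text I/O.

A session bundles everything recorded for one animal/day: the trial table
(context, choice, platform-stop times), spike times per unit, unit metadata,
and optional behavioral traces.  On disk a session is a directory of plain
TSV tables (trials.tsv, spikes.tsv, units.tsv, behavior.tsv) plus meta.json.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import PoseTraces
from .timeline import CHOICES, CONTEXTS, TrialWindow

TRIAL_COLUMNS = ["trial_id", "context", "choice", "t_stop_s"]
SPIKE_COLUMNS = ["unit_id", "spike_time_s"]
UNIT_COLUMNS = [
    "unit_id",
    "region",
    "depth_um",
    "peak_to_trough_us",
    "isi_violation",
    "amplitude_cutoff",
    "median_amplitude_uv",
]


@dataclass
class Session:
    trials: pd.DataFrame
    spikes: pd.DataFrame
    units: pd.DataFrame
    behavior: PoseTraces | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def stim_dur(self) -> float:
        return float(self.metadata.get("stim_dur", 5.0))

    @property
    def isi_dur(self) -> float:
        return float(self.metadata.get("isi_dur", 5.0))

    @property
    def duration(self) -> float:
        end = float(self.trials.t_stop_s.max()) + self.stim_dur + self.isi_dur
        if len(self.spikes):
            end = max(end, float(self.spikes.spike_time_s.max()))
        return end

    def trial_windows(
        self, context: str | None = None, choice: str | None = None
    ) -> list[TrialWindow]:
        df = self.trials
        if context is not None:
            df = df[df.context == context]
        if choice is not None:
            df = df[df.choice == choice]
        return [
            TrialWindow(int(r.trial_id), r.context, r.choice, float(r.t_stop_s))
            for r in df.itertuples()
        ]

    def spikes_by_unit(self) -> dict[int, np.ndarray]:
        out = {int(u): np.empty(0) for u in self.units.unit_id}
        for uid, grp in self.spikes.groupby("unit_id"):
            out[int(uid)] = np.sort(grp.spike_time_s.to_numpy())
        return out

    def validate(self) -> None:
        for col in TRIAL_COLUMNS:
            if col not in self.trials.columns:
                raise ValueError(f"trials table missing column {col!r}")
        bad_ctx = set(self.trials.context) - set(CONTEXTS)
        if bad_ctx:
            raise ValueError(f"unknown context value(s): {sorted(bad_ctx)}")
        bad_cho = set(self.trials.choice) - set(CHOICES)
        if bad_cho:
            raise ValueError(f"unknown choice value(s): {sorted(bad_cho)}")
        stops = self.trials.t_stop_s.to_numpy()
        if len(stops) > 1 and not np.all(np.diff(stops) > 0):
            raise ValueError("trial t_stop_s must be strictly increasing")
        known = set(self.units.unit_id.astype(int))
        referenced = set(self.spikes.unit_id.astype(int))
        dangling = referenced - known
        if dangling:
            raise ValueError(f"spikes reference unknown unit(s): {sorted(dangling)}")
        if len(self.spikes) and (self.spikes.spike_time_s < 0).any():
            raise ValueError("negative spike times")


def behavior_to_table(traces: PoseTraces) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"time_s": traces.time}
    for name in sorted(traces.labels):
        xy = traces.labels[name]
        cols[f"{name}_x"] = xy[:, 0]
        cols[f"{name}_y"] = xy[:, 1]
    if traces.ball_motion is not None:
        cols["ball_motion"] = traces.ball_motion
    if traces.ball_direction is not None:
        cols["ball_direction"] = traces.ball_direction
    cols["excluded"] = traces.exclusion_mask.astype(int)
    return pd.DataFrame(cols)


def behavior_from_table(df: pd.DataFrame) -> PoseTraces:
    labels = {}
    for col in df.columns:
        if col.endswith("_x"):
            name = col[:-2]
            labels[name] = np.column_stack(
                [df[col].to_numpy(float), df[f"{name}_y"].to_numpy(float)]
            )
    return PoseTraces(
        time=df["time_s"].to_numpy(float),
        labels=labels,
        ball_motion=df["ball_motion"].to_numpy(float) if "ball_motion" in df else None,
        ball_direction=(
            df["ball_direction"].to_numpy(float) if "ball_direction" in df else None
        ),
        exclusion_mask=(
            df["excluded"].to_numpy(int).astype(bool) if "excluded" in df else None
        ),
    )


def save_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(path / "trials.tsv", sep="\t", index=False)
    session.spikes.to_csv(path / "spikes.tsv", sep="\t", index=False)
    session.units.to_csv(path / "units.tsv", sep="\t", index=False)
    if session.behavior is not None:
        behavior_to_table(session.behavior).to_csv(
            path / "behavior.tsv", sep="\t", index=False
        )
    (path / "meta.json").write_text(json.dumps(session.metadata, indent=2, sort_keys=True))
    return path


def load_session(path: str | Path) -> Session:
    path = Path(path)
    for required in ("trials.tsv", "spikes.tsv", "units.tsv"):
        if not (path / required).exists():
            raise FileNotFoundError(f"session at {path} is missing {required}")
    trials = pd.read_csv(path / "trials.tsv", sep="\t")
    spikes = pd.read_csv(path / "spikes.tsv", sep="\t")
    units = pd.read_csv(path / "units.tsv", sep="\t")
    behavior = None
    if (path / "behavior.tsv").exists():
        behavior = behavior_from_table(pd.read_csv(path / "behavior.tsv", sep="\t"))
    metadata = {}
    if (path / "meta.json").exists():
        metadata = json.loads((path / "meta.json").read_text())
    session = Session(
        trials=trials, spikes=spikes, units=units, behavior=behavior, metadata=metadata
    )
    session.validate()
    return session
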