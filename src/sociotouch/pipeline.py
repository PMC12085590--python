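"""End-to-end session pipeline: simulate -> qc -> psth -> cluster -> mi ->
roc -> decode -> encode -> report.

Each stage writes delimited-text/JSON outputs into the results directory;
``run_pipeline`` drives them from a flat configuration mapping whose keys
mirror the CLI flags.  All randomness flows from the single ``seed`` entry.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import behavior as beh
from . import clustering, decoding, encoding, modulation, preference, spikes, synth
from .session import Session, save_session
from .timeline import CHOICES, TrialWindow

log = logging.getLogger("sociotouch")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_bouts": 40,
    "n_units_vS1": 20,
    "n_units_tSTR": 12,
    "n_units_BLA": 12,
    "qc_fail_fraction": 0.0,
    "include_behavior": True,
    "n_restarts": 200,
    "k": 4,  # planted archetype count; None selects K by the gap statistic
    "k_max": 8,
    "n_boot": 1000,
    "n_iterations": 100,
    "alpha": 0.05,
    "theta": 0.25,
}


def _config_to_synth(config: Mapping) -> synth.SyntheticConfig:
    return synth.SyntheticConfig(
        n_units={
            "vS1": int(config.get("n_units_vS1", 20)),
            "tSTR": int(config.get("n_units_tSTR", 12)),
            "BLA": int(config.get("n_units_BLA", 12)),
        },
        n_bouts=int(config.get("n_bouts", 40)),
        qc_fail_fraction=float(config.get("qc_fail_fraction", 0.0)),
        rng_seed=int(config.get("seed", 0)),
    )


def session_unit_meta(session: Session) -> list[spikes.UnitMeta]:
    return [
        spikes.UnitMeta(
            unit_id=int(r.unit_id),
            depth=float(r.depth_um),
            peak_to_trough=float(r.peak_to_trough_us),
            isi_violation=float(r.isi_violation),
            amplitude_cutoff=float(r.amplitude_cutoff),
            median_amplitude=float(r.median_amplitude_uv),
        )
        for r in session.units.itertuples()
    ]


def whisker_protraction_feature(traces: beh.PoseTraces) -> np.ndarray:
    """Forward displacement proxy: mean x of the whisker-follicle labels,
    relative to its session median."""
    names = traces.label_names("whisker_")
    if not names:
        raise ValueError("no whisker labels present")
    x = np.mean([traces.labels[n][:, 0] for n in names], axis=0)
    x = x - np.nanmedian(x)
    x[traces.exclusion_mask] = np.nan
    return x


def afe_thresholds(traces: beh.PoseTraces) -> dict[str, float]:
    """Data-driven AFE thresholds.

    Whisker protraction: session median + 4 robust SDs (MAD-based) of the
    forward-displacement proxy.  Orbital tightening: eye area below
    (1 - kappa) times its session median.
    """
    w = whisker_protraction_feature(traces)
    good = np.isfinite(w)
    mad = np.median(np.abs(w[good] - np.median(w[good])))
    area = beh.eye_area_trace(traces)
    return {
        "whisker_protraction": float(np.median(w[good]) + 4 * 1.4826 * mad),
        "orbital_tightening": float(
            (1 - beh.ORBITAL_KAPPA) * np.nanmedian(area)
        ),
    }


def trial_behavior_events(
    session: Session, trials: Sequence[TrialWindow] | None = None
) -> list[beh.BehaviorEvents]:
    """Per-trial AFE bouts, avoidance fraction, and saccade summary."""
    traces = session.behavior
    if traces is None:
        raise ValueError("session has no behavior traces")
    if trials is None:
        trials = session.trial_windows()
    thr = afe_thresholds(traces)
    w = whisker_protraction_feature(traces)
    area = beh.eye_area_trace(traces)
    w_bouts = beh.detect_afe_bouts(w, traces.time, "whisker_protraction",
                                   thr["whisker_protraction"])
    o_bouts = beh.detect_afe_bouts(area, traces.time, "orbital_tightening",
                                   thr["orbital_tightening"])
    saccades = beh.detect_saccades(traces, velocity_threshold=240.0)
    out = []
    for tr in trials:
        win = (tr.t_stop, tr.t_stop + session.stim_dur)
        wc, wf = beh.bout_occupancy(w_bouts, *win)
        oc, of = beh.bout_occupancy(o_bouts, *win)
        run_frac = float("nan")
        if traces.ball_motion is not None and traces.ball_direction is not None:
            run_frac = beh.running_avoidance_fraction(
                traces.ball_motion, traces.ball_direction, traces.time, win
            )
        in_win = saccades[(saccades.t_start >= win[0]) & (saccades.t_start < win[1])]
        net = float(
            (in_win.direction == "temporal").sum() - (in_win.direction == "nasal").sum()
        )
        out.append(
            beh.BehaviorEvents(
                trial_id=tr.trial_id,
                whisker_protraction_bouts=wc,
                whisker_protraction_fraction=wf,
                orbital_tightening_bouts=oc,
                orbital_tightening_fraction=of,
                running_avoidance_fraction=run_frac,
                saccade_count=len(in_win),
                saccade_net_direction=net,
            )
        )
    return out


def _mean_motion(traces: beh.PoseTraces, prefix: str, sel: np.ndarray) -> float:
    energies = [beh.label_motion_energy(traces, n)[sel] for n in traces.label_names(prefix)]
    vals = np.concatenate(energies) if energies else np.array([np.nan])
    good = np.isfinite(vals)
    return float(vals[good].mean()) if good.any() else 0.0


def session_regressors(
    session: Session, trials: Sequence[TrialWindow]
) -> dict[str, np.ndarray]:
    """The 13 per-trial regressors of the encoding design matrix.

    Each value is the trial mean over the 5 s presentation; binary
    regressors are 0/1 indicators.
    """
    traces = session.behavior
    if traces is None:
        raise ValueError("session has no behavior traces")
    events = trial_behavior_events(session, trials)
    area = beh.eye_area_trace(traces)
    pupil_names = traces.label_names("pupil_")
    pupil_pts = np.stack([traces.labels[n] for n in pupil_names], axis=1)
    # pupil size: mean marker distance from the pupil centroid
    pupil_size = np.linalg.norm(
        pupil_pts - pupil_pts.mean(axis=1, keepdims=True), axis=2
    ).mean(axis=1)
    run_median = (
        float(np.nanmedian(traces.ball_motion)) if traces.ball_motion is not None else 0.0
    )
    reg: dict[str, list[float]] = {name: [] for name in encoding.REGRESSOR_NAMES}
    for tr, ev in zip(trials, events):
        win = (tr.t_stop, tr.t_stop + session.stim_dur)
        sel = (traces.time >= win[0]) & (traces.time < win[1])
        reg["context"].append(1.0 if tr.context == "social" else 0.0)
        frac = ev.running_avoidance_fraction
        reg["running_avoidance"].append(1.0 if np.isfinite(frac) and frac > 0.25 else 0.0)
        reg["orbital_area"].append(float(np.nanmean(area[sel])))
        reg["whisker_protraction"].append(1.0 if ev.whisker_protraction_bouts > 0 else 0.0)
        reg["whisker_motion"].append(_mean_motion(traces, "whisker_", sel))
        reg["eye_motion"].append(_mean_motion(traces, "eye_", sel))
        reg["pupil_motion"].append(_mean_motion(traces, "pupil_", sel))
        reg["mouth_motion"].append(_mean_motion(traces, "mouth_", sel))
        reg["nose_motion"].append(_mean_motion(traces, "nose_", sel))
        reg["pupil_size"].append(float(np.nanmean(pupil_size[sel])))
        motion = traces.ball_motion[sel] if traces.ball_motion is not None else np.array([0.0])
        reg["running_motion"].append(float(np.nanmean(motion)))
        reg["saccades"].append(ev.saccade_net_direction)
        reg["locomotion"].append(1.0 if np.nanmean(motion) > run_median else 0.0)
    return {k: np.asarray(v) for k, v in reg.items()}


def build_design_matrix(
    session: Session, trials: Sequence[TrialWindow] | None = None
) -> encoding.DesignMatrix:
    """Design matrix over the forced-touch trials (object + social)."""
    if trials is None:
        trials = session.trial_windows(choice="forced")
    return encoding.build_design_matrix(
        session_regressors(session, trials), trial_ids=[t.trial_id for t in trials]
    )


def run_pipeline(config: Mapping | None = None, outdir: str | Path = "results") -> Path:
    """Execute every stage on a synthetic session; write csv/json results."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")

    def stage(name):
        log.info("stage %s", name)

    # --- simulate --------------------------------------------------------
    stage("simulate")
    scfg = _config_to_synth(cfg)
    session, truth = synth.generate_session(
        scfg, include_behavior=bool(cfg.get("include_behavior", True))
    )
    save_session(session, outdir / "session")

    # --- qc --------------------------------------------------------------
    stage("qc")
    metas = session_unit_meta(session)
    kept, rejected = spikes.qc_filter_units(metas)
    types = spikes.classify_unit_types(kept)
    regions = dict(zip(session.units.unit_id.astype(int), session.units.region))
    (outdir / "qc.json").write_text(
        json.dumps({"kept": [u.unit_id for u in kept],
                    "rejected": rejected, "types": types}, indent=2, default=str)
    )
    kept_ids = [u.unit_id for u in kept]
    spk = {u: t for u, t in session.spikes_by_unit().items() if u in kept_ids}

    # --- psth / cluster / mi / roc per choice condition -------------------
    results_mod, results_pref, cluster_rows = [], [], []
    psth_by_choice = {}
    for choice in CHOICES:
        trials = session.trial_windows(choice=choice)
        if not trials:
            continue
        stage(f"psth:{choice}")
        mat = spikes.unit_psth_matrix(spk, trials, session_end=session.duration)
        psth_by_choice[choice] = mat
        pd.DataFrame(mat.values, index=mat.unit_ids, columns=mat.time_bins).to_csv(
            outdir / f"psth_{choice}.csv"
        )
        stage(f"cluster:{choice}")
        clusterer = clustering.ResponseClusterer(
            n_restarts=int(cfg["n_restarts"]),
            k=None if cfg.get("k") is None else int(cfg["k"]),
            k_range=range(1, int(cfg["k_max"]) + 1),
            theta=float(cfg["theta"]),
            random_state=int(rng.integers(2**31)),
        ).fit(mat.values, time_bins=mat.time_bins)
        classes = {
            int(uid): clusterer.response_classes_[lab]
            for uid, lab in zip(mat.unit_ids, clusterer.labels_)
        }
        for uid, lab in zip(mat.unit_ids, clusterer.labels_):
            cluster_rows.append(
                {"unit_id": int(uid), "region": regions[int(uid)], "condition": choice,
                 "cluster": int(lab), "response_class": clusterer.response_classes_[lab]}
            )
        stage(f"mi:{choice}")
        for uid in mat.unit_ids:
            for context in ("social", "object"):
                sub = [t for t in trials if t.context == context]
                res = modulation.unit_modulation(spk[int(uid)], sub, "STIM", int(uid))
                results_mod.append(
                    {"unit_id": int(uid), "region": regions[int(uid)],
                     "response_class": classes[int(uid)], "context": context,
                     "choice": choice, "variant": "STIM", "mi": res.mi}
                )
        stage(f"roc:{choice}")
        soc = [t for t in trials if t.context == "social"]
        obj = [t for t in trials if t.context == "object"]
        for uid in mat.unit_ids:
            rc = classes[int(uid)]
            if rc == "weak":
                continue
            rs = spikes.window_rates(spk[int(uid)], soc, (0, session.stim_dur))
            ro = spikes.window_rates(spk[int(uid)], obj, (0, session.stim_dur))
            res = preference.preference_result(
                int(uid), rs, ro, rc, n_boot=int(cfg["n_boot"]),
                seed=int(rng.integers(2**31)),
            )
            results_pref.append(
                {"unit_id": int(uid), "region": regions[int(uid)], "condition": choice,
                 "auroc": res.auroc, "p_boot": res.p_boot, "label": res.label}
            )
    pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.csv", index=False)
    pd.DataFrame(results_mod).to_csv(outdir / "modulation.csv", index=False)
    pd.DataFrame(results_pref).to_csv(outdir / "preference.csv", index=False)

    # --- decode -----------------------------------------------------------
    stage("decode")
    decode_rows = []
    for choice in CHOICES:
        trials = session.trial_windows(choice=choice)
        if not trials or not spk:
            continue
        X, labels, _ = decoding.make_feature_matrix(
            "neural", spk, trials, window=(0, session.stim_dur)
        )
        res = decoding.decode_context(
            X, labels, n_iterations=int(cfg["n_iterations"]),
            seed=int(rng.integers(2**31)),
        )
        shuf = decoding.shuffle_controls(
            X, labels, "test_labels", n_iterations=int(cfg["n_iterations"]),
            seed=int(rng.integers(2**31)),
        )
        decode_rows.append(
            {"source": "neural", "condition": choice, "n_units": X.shape[1],
             "accuracy_mean": res.accuracy_mean, "accuracy_se": res.accuracy_se,
             "shuffled_accuracy_mean": shuf.accuracy_mean}
        )
    pd.DataFrame(decode_rows).to_csv(outdir / "decoding.csv", index=False)

    # --- encode -----------------------------------------------------------
    encode_rows = []
    if session.behavior is not None:
        stage("encode")
        forced = session.trial_windows(choice="forced")
        if forced and spk:
            design = build_design_matrix(session, forced)
            rates = {u: spikes.window_rates(t, forced, (0, session.stim_dur))
                     for u, t in spk.items()}
            fits = encoding.fit_ridge_cv(design, rates, random_state=seed)
            for f in fits:
                row = {"unit_id": f.unit_id, "region": regions[f.unit_id],
                       "lambda": f.lam, "cv_r2": f.cv_r2, "included": f.included}
                for name, b, bn in zip(f.regressor_names, f.beta, f.beta_norm):
                    row[f"beta_{name}"] = b
                    row[f"beta_norm_{name}"] = bn
                encode_rows.append(row)
            pd.DataFrame(
                design.values, index=design.regressor_names,
                columns=design.trial_ids,
            ).to_csv(outdir / "design_matrix.csv")
    pd.DataFrame(encode_rows).to_csv(outdir / "encoding.csv", index=False)

    # --- report -----------------------------------------------------------
    stage("report")
    pref_df = pd.DataFrame(results_pref)
    cls_df = pd.DataFrame(cluster_rows)
    report = {
        "seed": seed,
        "n_units_total": int(len(session.units)),
        "n_units_kept": len(kept_ids),
        "n_trials": int(len(session.trials)),
        "response_class_counts": (
            cls_df.groupby("response_class").unit_id.nunique().to_dict()
            if len(cls_df) else {}
        ),
        "preference_counts": (
            pref_df.groupby("label").unit_id.nunique().to_dict() if len(pref_df) else {}
        ),
        "decoding": decode_rows,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return outdir
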