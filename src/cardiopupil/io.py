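"""Plain-text session-directory layout.

A session directory holds::

    ecg.csv       time_s, voltage          (raw ECG, 1 kHz)
    pupil.csv     time_s, area, valid      (+ area_smooth after conditioning)
    trials.csv    trial_id, stimulus, onset_s, first_lick_s, outcome, rt_s
    session.json  manifest: seed, config, rates, ground-truth parameters
    beats.csv     r_time_s                 (detected R peaks)
    cardiac.csv   t_s, hr_bpm, hrv_ms, n_ibi
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .behavior import TrialRecord
from .ecg import BeatSeries, CardiacSeries, EcgTrace
from .pupil import PupilTrace


def write_ecg(path: str, trace: EcgTrace) -> None:
    df = pd.DataFrame({"time_s": trace.t, "voltage": trace.v})
    df.to_csv(path, index=False)


def read_ecg(path: str) -> EcgTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return EcgTrace(fs_hz=round(fs, 6), v=df["voltage"].to_numpy(), t0_s=float(t[0]))


def write_pupil(path: str, trace: PupilTrace, smooth: PupilTrace = None) -> None:
    df = pd.DataFrame({"time_s": trace.t, "area": trace.area,
                       "valid": trace.valid.astype(int)})
    if smooth is not None:
        df["area_smooth"] = smooth.area
    df.to_csv(path, index=False)


def read_pupil(path: str) -> PupilTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return PupilTrace(fs_hz=round(fs, 6), area=df["area"].to_numpy(),
                      valid=df["valid"].to_numpy().astype(bool), t0_s=float(t[0]))


def write_trials(path: str, trials) -> None:
    rows = [{
        "trial_id": tr.trial_id, "stimulus": tr.stimulus, "onset_s": tr.onset_s,
        "first_lick_s": tr.first_lick_s if tr.first_lick_s is not None else "",
        "outcome": tr.outcome, "rt_s": tr.rt_s if tr.rt_s is not None else "",
        "window_s": tr.window_s,
    } for tr in trials]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials(path: str):
    df = pd.read_csv(path)
    trials = []
    for _, r in df.iterrows():
        lick = r["first_lick_s"]
        rt = r["rt_s"]
        trials.append(TrialRecord(
            trial_id=int(r["trial_id"]), stimulus=str(r["stimulus"]),
            onset_s=float(r["onset_s"]),
            first_lick_s=None if pd.isna(lick) else float(lick),
            window_s=float(r["window_s"]),
            outcome=str(r["outcome"]),
            rt_s=None if pd.isna(rt) else float(rt)))
    return trials


def write_beats(path: str, beats: BeatSeries) -> None:
    pd.DataFrame({"r_time_s": beats.r_times_s}).to_csv(path, index=False)


def read_beats(path: str) -> BeatSeries:
    return BeatSeries(r_times_s=pd.read_csv(path)["r_time_s"].to_numpy())


def write_cardiac(path: str, series: CardiacSeries) -> None:
    pd.DataFrame({"t_s": series.t_s, "hr_bpm": series.hr_bpm,
                  "hrv_ms": series.hrv_ms, "n_ibi": series.n_ibi}).to_csv(path, index=False)


def read_cardiac(path: str) -> CardiacSeries:
    df = pd.read_csv(path)
    return CardiacSeries(t_s=df["t_s"].to_numpy(), hr_bpm=df["hr_bpm"].to_numpy(),
                         hrv_ms=df["hrv_ms"].to_numpy(),
                         n_ibi=df["n_ibi"].to_numpy().astype(int))


def write_manifest(path: str, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_session_dir(out_dir: str, session, include_ecg: bool = True) -> None:
    """Write the generator's view of a session (raw traces + ground truth)."""
    os.makedirs(out_dir, exist_ok=True)
    if include_ecg and session.ecg is not None:
        write_ecg(os.path.join(out_dir, "ecg.csv"), session.ecg)
    write_pupil(os.path.join(out_dir, "pupil.csv"), session.pupil)
    write_trials(os.path.join(out_dir, "trials.csv"), session.trials)
    from .behavior import response_rates
    hit, fa = response_rates(session.trials)
    manifest = {
        "seed": session.seed,
        "config": session.config.to_dict(),
        "hit_rate": hit,
        "fa_rate": fa,
        "n_trials": len(session.trials),
        "ground_truth": {
            "n_beats": len(session.beats_truth.beat_times),
            "beat_times_first_s": float(session.beats_truth.beat_times[0]),
            "beat_times_last_s": float(session.beats_truth.beat_times[-1]),
        },
    }
    write_manifest(os.path.join(out_dir, "session.json"), manifest)
    # ground-truth beats always available for validation
    pd.DataFrame({"beat_time_s": session.beats_truth.beat_times}).to_csv(
        os.path.join(out_dir, "beats_truth.csv"), index=False)
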