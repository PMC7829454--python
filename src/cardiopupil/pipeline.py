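"""Multi-session study orchestration: simulate → detect → metrics → tuning →
decode, with a reproducible report.

A study is a set of sessions generated (or loaded) independently; session k
derives its seed from the master seed by a fixed counter
(``SeedSequence(master, spawn_key=(k,))``), so any session is reproducible
in isolation. ``run_study`` executes every stage per session, writes the
per-stage CSV outputs into per-session directories, and aggregates
session-level metrics (mean ± SEM across retained sessions) in
``report.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from ._util import sem
from . import io as sio
from .behavior import (apply_exclusions, extract_baselines, loglinear_sdt,
                       response_rates)
from .decoder import loocv_evaluate, overlap_metrics
from .ecg import (BeatSeries, cardiac_series, detect_r_peaks, fluctuation_index,
                  hr_hrv_relation, optimize_threshold, preprocess_ecg,
                  scan_prominence)
from .pupil import interpolate_blinks, smooth_pupil
from .synth import SessionConfig, simulate_session
from .tuning import (baseline_correlations, outcome_conditioned_baselines,
                     quadratic_regression, task_evoked_dynamics, tuning_curve)

log = logging.getLogger(__name__)

PREDICTOR_SETS = (("pa",), ("hr",), ("hrv",), ("pa", "hr"))


@dataclasses.dataclass
class StudyConfig:
    n_sessions: int = 3
    master_seed: int = 0
    session: SessionConfig = dataclasses.field(default_factory=SessionConfig)
    with_ecg: bool = True
    scan_step: float = None        # None → max prominence / 200
    tuning_bins: int = 20
    decoder_bins: int = 15
    n_warmup: int = 20

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "session" in d and isinstance(d["session"], dict):
            d["session"] = SessionConfig.from_dict(d["session"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def session_seed(master_seed: int, k: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(k,))


def detect_beats_from_ecg(ecg, scan_step=None):
    """preprocess → prominence scan → threshold optimization → peak pick."""
    proc = preprocess_ecg(ecg)
    curve = scan_prominence(proc, step=scan_step)
    threshold = optimize_threshold(curve)
    beats = detect_r_peaks(proc, threshold)
    return beats, threshold, curve


def analyze_session(session, cfg: StudyConfig) -> dict:
    """Run every analysis stage on one simulated session.

    Returns a dict of intermediate products and session-level metrics; the
    session is marked excluded (key ``excluded``) when the study-level rules
    remove it.
    """
    out = {}
    # --- cardiac
    if cfg.with_ecg and session.ecg is not None:
        beats, threshold, curve = detect_beats_from_ecg(session.ecg, cfg.scan_step)
        out["threshold"] = threshold
    else:
        beats = BeatSeries(r_times_s=session.beats_truth.beat_times.copy())
        out["threshold"] = None
    cardiac = cardiac_series(beats)
    out["beats"], out["cardiac"] = beats, cardiac
    hr_ok = cardiac.hr_bpm[np.isfinite(cardiac.hr_bpm)]
    hrv_ok = cardiac.hrv_ms[np.isfinite(cardiac.hrv_ms)]
    out["fi_hr"] = fluctuation_index(hr_ok)
    out["fi_hrv"] = fluctuation_index(hrv_ok)
    out["hr_hrv_slope_2s"], out["hr_hrv_pcc_2s"] = hr_hrv_relation(cardiac, 2.0)
    out["hr_hrv_slope_5s"], out["hr_hrv_pcc_5s"] = hr_hrv_relation(cardiac, 5.0)

    # --- pupil
    pupil_s = smooth_pupil(interpolate_blinks(session.pupil))
    out["pupil_smooth"] = pupil_s

    # --- behavior + exclusions
    kept, excl_report = apply_exclusions({"s": session.trials}, cfg.n_warmup)
    out["exclusion"] = excl_report["s"]
    if "s" not in kept:
        out["excluded"] = excl_report["s"]["excluded"]
        return out
    trials = kept["s"]
    hit, fa = response_rates(trials)
    n_go = sum(1 for t in trials if t.stimulus == "go")
    n_nogo = len(trials) - n_go
    n_hit = sum(1 for t in trials if t.outcome == "hit")
    n_fa = sum(1 for t in trials if t.outcome == "fa")
    s = loglinear_sdt(n_hit, n_go, n_fa, n_nogo)
    rts = [t.rt_s for t in trials if t.rt_s is not None]
    out["metrics"] = {
        "n_trials": len(trials), "hit_rate": hit, "fa_rate": fa,
        "dprime": s.dprime, "criterion": s.criterion,
        "mean_rt_s": float(np.mean(rts)) if rts else None,
    }

    # --- baselines, tuning, correlations, evoked
    baselines = extract_baselines(trials, cardiac, pupil_s)
    out["baselines"] = baselines
    curves, fits = {}, {}
    for var in ("pa", "hr", "hrv"):
        if var not in baselines.columns:
            continue
        tc = tuning_curve(baselines, var, cfg.tuning_bins)
        curves[var] = tc
        for target, y in (("dprime", tc.dprime), ("criterion", tc.criterion),
                          ("rt", tc.rt)):
            try:
                fits[(var, target)] = quadratic_regression(tc.bin_centers, y)
            except ValueError:
                fits[(var, target)] = None
    out["tuning_curves"], out["fits"] = curves, fits
    out["correlations"] = baseline_correlations(baselines)
    out["outcome_baselines"] = outcome_conditioned_baselines(baselines)
    out["evoked_hr"] = task_evoked_dynamics(
        trials, cardiac.t_s, cardiac.hr_bpm, dt_s=0.5)
    out["evoked_pupil"] = task_evoked_dynamics(
        trials, pupil_s.t, pupil_s.area)

    # --- decoding
    responded = baselines["responded"].to_numpy()
    decode = {}
    for preds in PREDICTOR_SETS:
        if all(p in baselines.columns for p in preds):
            decode[preds] = loocv_evaluate(baselines, responded, preds,
                                           n_bins=cfg.decoder_bins)
    out["decode"] = decode
    if ("pa",) in decode and ("hr",) in decode:
        out["overlap_pa_hr"] = overlap_metrics(
            decode[("pa",)].correct_idx, decode[("hr",)].correct_idx,
            decode[("pa",)].accuracy, decode[("hr",)].accuracy)
    return out


def _write_session_outputs(d: str, res: dict) -> None:
    sio.write_beats(os.path.join(d, "beats.csv"), res["beats"])
    sio.write_cardiac(os.path.join(d, "cardiac.csv"), res["cardiac"])
    if res.get("excluded"):
        return
    res["baselines"].to_csv(os.path.join(d, "baselines.csv"), index=False)
    with open(os.path.join(d, "session_metrics.json"), "w") as fh:
        json.dump(res["metrics"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    rows = []
    for var, tc in res["tuning_curves"].items():
        for i in range(len(tc.bin_centers)):
            rows.append({"variable": var, "bin": i + 1,
                         "bin_center_pct": tc.bin_centers[i],
                         "n": int(tc.n_trials[i]), "dprime": tc.dprime[i],
                         "criterion": tc.criterion[i], "rt": tc.rt[i]})
    pd.DataFrame(rows).to_csv(os.path.join(d, "tuning_curves.csv"), index=False)
    rows = []
    for (var, target), fit in res["fits"].items():
        if fit is not None:
            rows.append({"variable": var, "target": target, "beta0": fit.beta0,
                         "beta1": fit.beta1, "beta2": fit.beta2})
    pd.DataFrame(rows).to_csv(os.path.join(d, "fits.csv"), index=False)
    corr = {k: v for k, v in res["correlations"].items()
            if k != "pcc_hr_hrv_by_outcome"}
    for oc, v in res["correlations"]["pcc_hr_hrv_by_outcome"].items():
        corr[f"pcc_hr_hrv_{oc}"] = v
    pd.DataFrame([corr]).to_csv(os.path.join(d, "correlations.csv"), index=False)
    rows = []
    for signal in ("evoked_hr", "evoked_pupil"):
        for oc, (rel, trace, n) in res[signal].items():
            for j in range(len(rel)):
                rows.append({"signal": signal.replace("evoked_", ""),
                             "outcome": oc, "rel_t_s": rel[j],
                             "pct_change": trace[j], "n": n})
    pd.DataFrame(rows).to_csv(os.path.join(d, "evoked.csv"), index=False)
    rows, pred_rows = [], []
    for preds, r in res["decode"].items():
        name = "+".join(preds)
        rows.append({"predictor_set": name, "accuracy": r.accuracy,
                     "chance": r.chance, "above_chance": r.above_chance})
        for i in range(len(r.posterior)):
            pred_rows.append({"predictor_set": name, "trial_index": i,
                              "posterior_respond": r.posterior[i],
                              "predicted": bool(r.predicted[i]),
                              "true": bool(r.true[i])})
    pd.DataFrame(rows).to_csv(os.path.join(d, "decode_results.csv"), index=False)
    pd.DataFrame(pred_rows).to_csv(os.path.join(d, "predictions.csv"), index=False)
    if "overlap_pa_hr" in res:
        ov = res["overlap_pa_hr"]
        pd.DataFrame([{"pair": "pa+hr", "pct_overlap": ov.pct_overlap,
                       "normalized_overlap": ov.normalized_overlap}]).to_csv(
            os.path.join(d, "overlap.csv"), index=False)


def run_study(config: StudyConfig, out_dir: str) -> dict:
    """Simulate and analyze every session; write outputs and report.json."""
    os.makedirs(out_dir, exist_ok=True)
    config.to_yaml(os.path.join(out_dir, "study_config.yaml"))
    per_session = []
    n_failed = 0
    for k in range(config.n_sessions):
        sdir = os.path.join(out_dir, f"session_{k:03d}")
        try:
            sim = simulate_session(config.session, seed=session_seed(config.master_seed, k),
                                   with_ecg=config.with_ecg)
            sim.seed = None  # SeedSequence not JSON-serializable; record master+k instead
            os.makedirs(sdir, exist_ok=True)
            sio.write_session_dir(sdir, sim, include_ecg=config.with_ecg)
            res = analyze_session(sim, config)
            _write_session_outputs(sdir, res)
        except Exception:
            log.exception("session %d failed; skipping", k)
            n_failed += 1
            per_session.append({"session": k, "failed": True})
            continue
        entry = {"session": k, "failed": False,
                 "excluded": res.get("excluded"),
                 "threshold": res.get("threshold"),
                 "fi_hr": res.get("fi_hr"), "fi_hrv": res.get("fi_hrv"),
                 "hr_hrv_slope_2s": res.get("hr_hrv_slope_2s"),
                 "hr_hrv_slope_5s": res.get("hr_hrv_slope_5s")}
        if not res.get("excluded"):
            entry.update(res["metrics"])
            entry["pcc_pa_hr"] = res["correlations"].get("pcc_pa_hr")
            entry["pcc_pa_hrv"] = res["correlations"].get("pcc_pa_hrv")
            for preds, r in res["decode"].items():
                entry[f"above_chance_{'_'.join(preds)}"] = r.above_chance
                entry[f"accuracy_{'_'.join(preds)}"] = r.accuracy
            if "overlap_pa_hr" in res:
                entry["pct_overlap_pa_hr"] = res["overlap_pa_hr"].pct_overlap
                entry["normalized_overlap_pa_hr"] = res["overlap_pa_hr"].normalized_overlap
            for (var, target), fit in res["fits"].items():
                if fit is not None:
                    entry[f"beta2_{var}_{target}"] = fit.beta2
        per_session.append(entry)
    if n_failed == config.n_sessions:
        raise RuntimeError("all sessions failed")

    analyzed = [e for e in per_session if not e.get("failed") and not e.get("excluded")]
    summary = {}
    if analyzed:
        keys = sorted({k for e in analyzed for k, v in e.items()
                       if isinstance(v, (int, float)) and not isinstance(v, bool)
                       and k != "session"})
        for key in keys:
            vals = np.array([e[key] for e in analyzed if e.get(key) is not None], float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                summary[key] = {"mean": float(vals.mean()), "sem": sem(vals),
                                "n": int(vals.size)}
    report = {"config": config.to_dict(), "sessions": per_session,
              "n_analyzed": len(analyzed), "summary": summary}
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=sio._jsonable)
        fh.write("\n")
    return report
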