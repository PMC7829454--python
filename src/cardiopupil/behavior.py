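"""Trial outcomes, signal-detection metrics, baselines, and exclusion rules.

Go/No-go trials are labeled hit / miss / FA (false alarm) / CR (correct
rejection) from the stimulus identity and the first lick time relative to
the response window. Session performance is summarized in the
equal-variance signal-detection frame:

    d' = Psi^-1(hit rate) - Psi^-1(FA rate)
    c  = -(Psi^-1(hit rate) + Psi^-1(FA rate)) / 2

with Psi^-1 the standard normal quantile. The loglinear correction (add 0.5
to hit/FA counts and 1 to Go/No-go counts) keeps both finite when a rate
saturates at 0 or 1.

Pre-stimulus baselines (pupil area, HR, HRV) are means over the 1 s window
ending at stimulus onset, half-open [onset-1, onset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

log = logging.getLogger(__name__)

OUTCOMES = ("hit", "miss", "fa", "cr")
RESPONDED = ("hit", "fa")

__all__ = [
    "TrialRecord",
    "SdtMetrics",
    "label_outcome",
    "response_rates",
    "sdt_metrics",
    "loglinear_sdt",
    "reaction_time",
    "extract_baselines",
    "apply_exclusions",
    "OUTCOMES",
    "RESPONDED",
]


@dataclass
class TrialRecord:
    trial_id: int
    stimulus: str                     # "go" | "nogo"
    onset_s: float
    first_lick_s: Optional[float]
    window_s: float
    outcome: Optional[str] = None     # "hit" | "miss" | "fa" | "cr"
    rt_s: Optional[float] = None


@dataclass
class SdtMetrics:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float


def label_outcome(stimulus: str, first_lick_s, onset_s: float, window_s: float) -> str:
    """Label a trial from its stimulus and first lick time.

    A lick in (onset, onset + window] is a response: hit on Go, FA on
    No-go. No lick (or a lick after the window) yields miss / CR. A lick
    strictly before stimulus onset is rejected: premature licks delay the
    stimulus at acquisition time and must never reach labeling.
    """
    if stimulus not in ("go", "nogo"):
        raise ValueError(f"unknown stimulus {stimulus!r}")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    responded = False
    if first_lick_s is not None:
        if first_lick_s < onset_s:
            raise ValueError(f"lick at {first_lick_s} precedes stimulus onset {onset_s}")
        responded = onset_s < first_lick_s <= onset_s + window_s
    if stimulus == "go":
        return "hit" if responded else "miss"
    return "fa" if responded else "cr"


def response_rates(trials) -> tuple:
    """(hit rate, FA rate) = hits/Go-trials, FAs/No-go-trials."""
    n_go = sum(1 for t in trials if t.stimulus == "go")
    n_nogo = sum(1 for t in trials if t.stimulus == "nogo")
    if n_go == 0 or n_nogo == 0:
        raise ValueError("need at least one Go and one No-go trial")
    n_hit = sum(1 for t in trials if t.outcome == "hit")
    n_fa = sum(1 for t in trials if t.outcome == "fa")
    return n_hit / n_go, n_fa / n_nogo


def sdt_metrics(hit_rate: float, fa_rate: float) -> SdtMetrics:
    """d' and criterion from raw rates; rates must lie strictly in (0, 1)."""
    for name, r in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not (0.0 < r < 1.0):
            raise ValueError(
                f"{name}={r} is degenerate; use loglinear_sdt on the raw counts")
    zh = norm.ppf(hit_rate)
    zf = norm.ppf(fa_rate)
    return SdtMetrics(hit_rate=hit_rate, fa_rate=fa_rate,
                      dprime=float(zh - zf), criterion=float(-(zh + zf) / 2.0))


def loglinear_sdt(n_hit: int, n_go: int, n_fa: int, n_nogo: int) -> SdtMetrics:
    """SDT metrics with the loglinear correction applied to the counts."""
    if min(n_hit, n_go, n_fa, n_nogo) < 0:
        raise ValueError("counts must be non-negative")
    hit_rate = (n_hit + 0.5) / (n_go + 1.0)
    fa_rate = (n_fa + 0.5) / (n_nogo + 1.0)
    return sdt_metrics(hit_rate, fa_rate)


def reaction_time(trial: TrialRecord):
    """First lick latency from stimulus onset on responded trials, else None."""
    if trial.outcome in RESPONDED and trial.first_lick_s is not None:
        return trial.first_lick_s - trial.onset_s
    return None


def _window_mean(t: np.ndarray, x: np.ndarray, lo: float, hi: float):
    """Mean of x over half-open [lo, hi); NaN unless the window is covered.

    Coverage requires the trace span (padded by one sample step) to contain
    the whole window, so edge trials with partial windows are rejected.
    """
    if len(t) < 2:
        return np.nan
    step = np.median(np.diff(t))
    if lo < t[0] - step or hi > t[-1] + step:
        return np.nan
    m = (t >= lo) & (t < hi)
    if not m.any():
        return np.nan
    seg = x[m]
    seg = seg[np.isfinite(seg)]
    return seg.mean() if seg.size else np.nan


def extract_baselines(trials, cardiac=None, pupil=None, baseline_s: float = 1.0,
                      beats=None, from_grid: bool = True) -> pd.DataFrame:
    """Per-trial pre-stimulus baselines as a tidy table.

    Columns: trial_id, stimulus, outcome, responded, rt, and whichever of
    pa / hr / hrv the supplied traces permit. HR/HRV baselines average the
    0.5-s cardiac grid values whose times fall in [onset-1, onset); with
    ``from_grid=False`` and ``beats`` given they are instead recomputed from
    the raw IBIs whose midpoints fall in the window. Trials without coverage
    are dropped (logged).
    """
    rows = []
    if beats is not None and not from_grid:
        r = np.asarray(beats.r_times_s, float)
        ibi = np.diff(r) * 1000.0
        mid = (r[:-1] + r[1:]) / 2.0
    for tr in trials:
        lo, hi = tr.onset_s - baseline_s, tr.onset_s
        row = {
            "trial_id": tr.trial_id, "stimulus": tr.stimulus,
            "outcome": tr.outcome, "responded": tr.outcome in RESPONDED,
            "rt": reaction_time(tr),
        }
        if cardiac is not None:
            if from_grid or beats is None:
                row["hr"] = _window_mean(cardiac.t_s, cardiac.hr_bpm, lo, hi)
                row["hrv"] = _window_mean(cardiac.t_s, cardiac.hrv_ms, lo, hi)
            else:
                m = (mid >= lo) & (mid < hi)
                seg = ibi[m]
                row["hr"] = 60000.0 / seg.mean() if seg.size else np.nan
                row["hrv"] = seg.std(ddof=1) if seg.size >= 2 else np.nan
        if pupil is not None:
            row["pa"] = _window_mean(pupil.t, np.asarray(pupil.area, float), lo, hi)
        signal_cols = [k for k in ("hr", "hrv", "pa") if k in row]
        if any(not np.isfinite(row[k]) for k in signal_cols):
            log.info("trial %s dropped: baseline window [%0.2f, %0.2f) lacks coverage",
                     tr.trial_id, lo, hi)
            continue
        rows.append(row)
    return pd.DataFrame(rows)


def apply_exclusions(sessions: dict, n_warmup: int = 20) -> tuple:
    """Study-level exclusion rules.

    For each session the first ``n_warmup`` trials are dropped (camera
    adjustment period); sessions left with no analyzable trials, or whose FA
    rate exceeds their hit rate, are excluded outright. Returns
    (retained: {session_id: [TrialRecord]}, report: {session_id: dict}).
    """
    retained, report = {}, {}
    for sid, trials in sessions.items():
        entry = {"n_total": len(trials), "n_warmup_dropped": min(n_warmup, len(trials))}
        kept = list(trials)[n_warmup:]
        if not kept:
            entry["excluded"] = "too few trials"
            log.warning("session %s excluded: %d trials <= warmup %d", sid, len(trials), n_warmup)
            report[sid] = entry
            continue
        try:
            hit, fa = response_rates(kept)
        except ValueError as e:
            entry["excluded"] = str(e)
            report[sid] = entry
            continue
        entry.update(hit_rate=hit, fa_rate=fa)
        if fa > hit:
            entry["excluded"] = "FA rate exceeds hit rate"
            log.warning("session %s excluded: FA %.3f > hit %.3f", sid, fa, hit)
            report[sid] = entry
            continue
        entry["excluded"] = None
        entry["n_analyzed"] = len(kept)
        retained[sid] = kept
        report[sid] = entry
    return retained, report
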