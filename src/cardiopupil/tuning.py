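"""Arousal–performance tuning: binned SDT metrics, quadratic fits,
baseline correlations, and task-evoked signal dynamics.

Each physiological baseline (pupil area, HR, HRV) is normalized per
session to percent of maximum, split into 20 equal-width bins, and the
loglinear d', criterion, and mean reaction time are computed per bin. A
degree-2 least-squares polynomial on the bin statistics quantifies the
inverted-U (d') and U (criterion) shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .behavior import loglinear_sdt, RESPONDED

__all__ = [
    "TuningCurve",
    "QuadraticFit",
    "percent_of_max",
    "tuning_curve",
    "quadratic_regression",
    "baseline_correlations",
    "outcome_conditioned_baselines",
    "task_evoked_dynamics",
]


@dataclass
class TuningCurve:
    variable: str
    bin_centers: np.ndarray     # % of maximum baseline
    n_trials: np.ndarray
    dprime: np.ndarray
    criterion: np.ndarray
    rt: np.ndarray
    defined: np.ndarray         # bins containing at least one trial


@dataclass
class QuadraticFit:
    beta0: float
    beta1: float
    beta2: float

    def predict(self, x):
        x = np.asarray(x, float)
        return self.beta0 + self.beta1 * x + self.beta2 * x * x


def percent_of_max(values) -> np.ndarray:
    """Min–max normalize to [0, 100]%. Raises on a constant input."""
    v = np.asarray(values, float)
    vmin, vmax = np.min(v), np.max(v)
    if vmax == vmin:
        raise ValueError("constant baseline: percent of maximum undefined")
    return (v - vmin) / (vmax - vmin) * 100.0


def tuning_curve(baselines: pd.DataFrame, variable: str, n_bins: int = 20) -> TuningCurve:
    """Bin trials by % of maximum baseline and compute per-bin behavior.

    Per bin: loglinear d' and criterion from the hit/FA counts, and the mean
    reaction time over responded trials. Bins without trials are flagged
    undefined. The last bin is right-closed so the maximum lands in bin
    ``n_bins``.
    """
    pct = percent_of_max(baselines[variable].to_numpy())
    width = 100.0 / n_bins
    idx = np.minimum((pct / width).astype(int), n_bins - 1)
    centers = (np.arange(n_bins) + 0.5) * width
    n_tr = np.zeros(n_bins, dtype=int)
    dp = np.full(n_bins, np.nan)
    cr = np.full(n_bins, np.nan)
    rt = np.full(n_bins, np.nan)
    outcome = baselines["outcome"].to_numpy()
    rts = baselines["rt"].to_numpy(dtype=float)
    for b in range(n_bins):
        m = idx == b
        n_tr[b] = int(m.sum())
        if n_tr[b] == 0:
            continue
        oc = outcome[m]
        n_hit = int((oc == "hit").sum())
        n_fa = int((oc == "fa").sum())
        n_go = n_hit + int((oc == "miss").sum())
        n_nogo = n_fa + int((oc == "cr").sum())
        s = loglinear_sdt(n_hit, n_go, n_fa, n_nogo)
        dp[b], cr[b] = s.dprime, s.criterion
        resp_rt = rts[m][np.isin(oc, RESPONDED) & np.isfinite(rts[m])]
        if resp_rt.size:
            rt[b] = resp_rt.mean()
    return TuningCurve(variable=variable, bin_centers=centers, n_trials=n_tr,
                       dprime=dp, criterion=cr, rt=rt, defined=n_tr > 0)


def quadratic_regression(x, y) -> QuadraticFit:
    """Least-squares fit of y = b0 + b1*x + b2*x^2 (NaN pairs dropped)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("quadratic regression needs at least 3 defined points")
    X = np.column_stack([np.ones_like(x), x, x * x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return QuadraticFit(beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]))


def _safe_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined (too few points or zero variance)")
        return np.nan
    return float(pearsonr(x, y)[0])


def baseline_correlations(baselines: pd.DataFrame) -> dict:
    """Trial-to-trial Pearson correlations among the baselines.

    Returns pcc_pa_hr, pcc_pa_hrv (when pupil present), pcc_hr_hrv, and
    pcc_hr_hrv_by_outcome (per-outcome stratification).
    """
    out = {}
    has_pa = "pa" in baselines.columns
    if has_pa:
        out["pcc_pa_hr"] = _safe_pearson(baselines["pa"], baselines["hr"])
        out["pcc_pa_hrv"] = _safe_pearson(baselines["pa"], baselines["hrv"])
    out["pcc_hr_hrv"] = _safe_pearson(baselines["hr"], baselines["hrv"])
    by = {}
    for oc, grp in baselines.groupby("outcome"):
        by[oc] = _safe_pearson(grp["hr"], grp["hrv"]) if len(grp) >= 3 else np.nan
    out["pcc_hr_hrv_by_outcome"] = by
    return out


def outcome_conditioned_baselines(baselines: pd.DataFrame) -> pd.DataFrame:
    """Mean baseline per outcome plus responded/withheld groupings."""
    cols = [c for c in ("pa", "hr", "hrv") if c in baselines.columns]
    rows = []
    for oc, grp in baselines.groupby("outcome"):
        rows.append({"group": oc, "n": len(grp), **{c: grp[c].mean() for c in cols}})
    for label, mask in (("responded", baselines["responded"]),
                        ("withheld", ~baselines["responded"])):
        grp = baselines[mask]
        if len(grp):
            rows.append({"group": label, "n": len(grp), **{c: grp[c].mean() for c in cols}})
    return pd.DataFrame(rows)


def task_evoked_dynamics(trials, t, x, pre_s: float = 1.0, post_s: float = 5.0,
                         dt_s: float = None) -> dict:
    """Stimulus-aligned percent change from each trial's own baseline.

    ``t``/``x`` are the signal's time grid and values (e.g. cardiac grid HR,
    or the 20 Hz smoothed pupil). Each trial's trace is interpolated onto a
    relative grid spanning [-pre, post], expressed as 100*(x - baseline)/
    baseline with baseline the mean over [-pre, 0), then averaged within
    outcome. Trials without full coverage or with a non-positive baseline
    are dropped (logged). Returns {outcome: (rel_t, mean_trace, n_trials)}.
    """
    import logging
    log = logging.getLogger(__name__)
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    ok = np.isfinite(x)
    t, x = t[ok], x[ok]
    if dt_s is None:
        dt_s = float(np.median(np.diff(t)))
    rel = np.arange(-pre_s, post_s + dt_s / 2.0, dt_s)
    per_outcome = {}
    for tr in trials:
        if tr.onset_s - pre_s < t[0] or tr.onset_s + post_s > t[-1]:
            log.info("trial %s dropped from evoked average: coverage gap", tr.trial_id)
            continue
        xi = np.interp(tr.onset_s + rel, t, x)
        base = xi[rel < 0].mean()
        if not np.isfinite(base) or base <= 0:
            log.info("trial %s dropped from evoked average: degenerate baseline", tr.trial_id)
            continue
        per_outcome.setdefault(tr.outcome, []).append(100.0 * (xi - base) / base)
    return {oc: (rel, np.mean(traces, axis=0), len(traces))
            for oc, traces in per_outcome.items()}
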