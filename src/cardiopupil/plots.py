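"""Basic diagnostic plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_cardiac_series(series, ax=None):
    """HR and HRV traces on twin axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(series.t_s, series.hr_bpm, lw=0.8, color="C3", label="HR")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("HR (bpm)", color="C3")
    ax2 = ax.twinx()
    ax2.plot(series.t_s, series.hrv_ms, lw=0.8, color="C0", alpha=0.7, label="HRV")
    ax2.set_ylabel("HRV (ms)", color="C0")
    return ax


def plot_tuning_curve(curve, ax=None):
    """d' and criterion against % of maximum baseline."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ok = curve.defined
    ax.plot(curve.bin_centers[ok], curve.dprime[ok], "o-", label="d'")
    ax.plot(curve.bin_centers[ok], curve.criterion[ok], "s-", label="criterion")
    ax.set_xlabel(f"% of maximum {curve.variable.upper()} baseline")
    ax.set_ylabel("signal-detection metric")
    ax.legend(frameon=False)
    return ax


def plot_evoked(evoked, signal_name="HR", ax=None):
    """Outcome-split task-evoked percent change from baseline."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for oc, (rel, trace, n) in sorted(evoked.items()):
        ax.plot(rel, trace, label=f"{oc} (n={n})")
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from stimulus (s)")
    ax.set_ylabel(f"{signal_name} change from baseline (%)")
    ax.legend(frameon=False, fontsize=8)
    return ax
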