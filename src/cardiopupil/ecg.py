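"""R-peak detection and heart-rate / heart-rate-variability estimation.

The detection pipeline mirrors standard rodent telemetry practice: the raw
voltage trace is zero-phase band-limited (8th-order elliptic high-pass at
4 Hz to remove drift, then a Gaussian smoothing kernel whose -3 dB point is
250 Hz), candidate peaks are ranked by topographic prominence, and the
per-session prominence threshold is placed on the plateau of the
threshold→peak-count curve — the regime where the count is insensitive to
the threshold because every R peak, and nothing else, is retained. The
plateau is located by minimizing the magnitude of the smoothed curve's
descending rate with a Nelder–Mead (downhill simplex) refinement.

HR is evaluated every 0.5 s as 60000 / mean(IBI) over a centered 1 s
window; HRV is the sample SD of the same IBIs. An IBI belongs to a window
when its midpoint falls in [t-0.5, t+0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize
from scipy.stats import linregress, pearsonr

__all__ = [
    "EcgTrace",
    "PeakCountCurve",
    "BeatSeries",
    "CardiacSeries",
    "preprocess_ecg",
    "scan_prominence",
    "optimize_threshold",
    "detect_r_peaks",
    "cardiac_series",
    "fluctuation_index",
    "hr_hrv_relation",
]

REFRACTORY_S = 0.05  # ~1200 bpm physiological ceiling


@dataclass
class EcgTrace:
    fs_hz: float
    v: np.ndarray
    t0_s: float = 0.0

    @property
    def t(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.v)) / self.fs_hz


@dataclass
class PeakCountCurve:
    """Number of prominence-thresholded peaks as the threshold rises."""

    thresholds: np.ndarray
    counts: np.ndarray


@dataclass
class BeatSeries:
    r_times_s: np.ndarray

    @property
    def ibi_ms(self) -> np.ndarray:
        return np.diff(self.r_times_s) * 1000.0

    def __len__(self) -> int:
        return len(self.r_times_s)


@dataclass
class CardiacSeries:
    t_s: np.ndarray
    hr_bpm: np.ndarray
    hrv_ms: np.ndarray
    n_ibi: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        """Mask of grid points with at least 2 IBIs (HR and HRV both valid)."""
        return self.n_ibi >= 2


def preprocess_ecg(trace: EcgTrace, hp_hz: float = 4.0, lp_hz: float = 250.0) -> EcgTrace:
    """Zero-phase elliptic high-pass then Gaussian low-pass smoothing.

    The elliptic section is 8th order (0.1 dB ripple, 80 dB stopband) applied
    forward–backward; the Gaussian kernel's SD is chosen so its magnitude
    response is -3 dB at ``lp_hz``.
    """
    if trace.fs_hz < 2 * lp_hz:
        raise ValueError(f"sampling rate {trace.fs_hz} Hz < 2×{lp_hz} Hz low-pass cutoff")
    sos = sps.ellip(8, 0.1, 80.0, hp_hz, btype="highpass", fs=trace.fs_hz, output="sos")
    v = sps.sosfiltfilt(sos, trace.v)
    sigma_s = np.sqrt(np.log(2.0)) / (2.0 * np.pi * lp_hz)
    v = gaussian_filter1d(v, sigma_s * trace.fs_hz, mode="reflect")
    return EcgTrace(fs_hz=trace.fs_hz, v=v, t0_s=trace.t0_s)


def scan_prominence(trace: EcgTrace, step: float = None) -> PeakCountCurve:
    """Count peaks surviving each prominence threshold from 0 to the max.

    ``step`` defaults to max-prominence/200.
    """
    peaks, _ = sps.find_peaks(trace.v)
    if len(peaks) == 0:
        return PeakCountCurve(thresholds=np.array([0.0]), counts=np.array([0]))
    proms = sps.peak_prominences(trace.v, peaks)[0]
    pmax = float(proms.max())
    if pmax <= 0:
        return PeakCountCurve(thresholds=np.array([0.0]), counts=np.array([len(peaks)]))
    if step is None:
        step = pmax / 200.0
    if step <= 0:
        raise ValueError("step must be positive")
    thresholds = np.arange(0.0, pmax + step, step)
    sorted_p = np.sort(proms)
    counts = len(proms) - np.searchsorted(sorted_p, thresholds, side="left")
    return PeakCountCurve(thresholds=thresholds, counts=counts)


def _smooth_counts(counts: np.ndarray, width: int = 5) -> np.ndarray:
    pad = width // 2
    padded = np.pad(counts.astype(float), pad, mode="edge")
    kernel = np.ones(width) / width
    return np.convolve(padded, kernel, mode="valid")


def optimize_threshold(curve: PeakCountCurve, smooth_width: int = 5) -> float:
    """Threshold where the descending rate of the peak count is smallest.

    The count curve is smoothed with a moving average, differentiated, and
    the search is restricted to the interior between the first and last
    descending segments (outside that range the count is trivially flat at
    the total-peak or zero plateau). A Nelder–Mead refinement runs on the
    linearly interpolated |derivative|. If no interior plateau exists a
    warning is issued and the global |derivative| minimum is returned.
    """
    thr = np.asarray(curve.thresholds, float)
    cnt = np.asarray(curve.counts, float)
    if len(thr) < 3:
        raise ValueError("peak-count curve needs at least 3 points")
    smooth = _smooth_counts(cnt, smooth_width)
    deriv = np.gradient(smooth, thr)
    desc = np.where(deriv < 0)[0]
    absd = np.abs(deriv)
    if len(desc) >= 2 and desc[-1] > desc[0] + 1:
        lo, hi = desc[0], desc[-1]
        # a plateau should be nearly flat relative to the descents around it
        if absd[lo:hi + 1].min() > 0.5 * np.median(absd[desc]):
            warnings.warn("no interior plateau in peak-count curve; "
                          "using global |derivative| minimum")
    else:
        warnings.warn("no interior plateau in peak-count curve; "
                      "using global |derivative| minimum")
        lo, hi = 0, len(thr) - 1
    interior = slice(lo, hi + 1)
    i_best = lo + int(np.argmin(absd[interior]))
    x_lo, x_hi = thr[lo], thr[hi]

    def objective(x):
        x = float(np.atleast_1d(x)[0])
        if x < x_lo or x > x_hi:
            return absd.max() + (absd.max() + 1.0)
        return float(np.interp(x, thr, absd))

    res = minimize(objective, x0=[thr[i_best]], method="Nelder-Mead",
                   options={"xatol": (thr[1] - thr[0]) * 1e-3, "fatol": 1e-12})
    x_star = float(np.clip(res.x[0], x_lo, x_hi))
    if objective(x_star) <= absd[i_best]:
        return x_star
    return float(thr[i_best])


def detect_r_peaks(trace: EcgTrace, threshold: float,
                   refractory_s: float = REFRACTORY_S) -> BeatSeries:
    """Local maxima with prominence >= threshold, >= 50 ms apart."""
    distance = max(1, int(round(refractory_s * trace.fs_hz)))
    peaks, _ = sps.find_peaks(trace.v, prominence=threshold, distance=distance)
    return BeatSeries(r_times_s=trace.t0_s + peaks / trace.fs_hz)


def cardiac_series(beats: BeatSeries, step_s: float = 0.5, window_s: float = 1.0) -> CardiacSeries:
    """HR (bpm) and HRV (ms) on a regular grid anchored at the first beat.

    HR = 60000 / mean(IBI) and HRV = sample SD (ddof=1) of the IBIs whose
    midpoints fall in the half-open window [t - w/2, t + w/2). Windows with
    fewer than one IBI leave HR undefined; fewer than two leave HRV
    undefined (NaN), flagged via ``n_ibi``.
    """
    r = np.asarray(beats.r_times_s, float)
    if len(r) < 3:
        raise ValueError("need at least 3 beats for a cardiac series")
    ibi = np.diff(r) * 1000.0
    if np.any(ibi <= 0):
        raise ValueError("beat times must be strictly increasing")
    mid = (r[:-1] + r[1:]) / 2.0
    n_steps = int(np.floor((r[-1] - r[0]) / step_s)) + 1
    t = r[0] + np.arange(n_steps) * step_s
    half = window_s / 2.0
    lo = np.searchsorted(mid, t - half, side="left")
    hi = np.searchsorted(mid, t + half, side="left")
    n = hi - lo
    hr = np.full(n_steps, np.nan)
    hrv = np.full(n_steps, np.nan)
    for i in range(n_steps):
        if n[i] >= 1:
            seg = ibi[lo[i]:hi[i]]
            hr[i] = 60000.0 / seg.mean()
            if n[i] >= 2:
                hrv[i] = seg.std(ddof=1)
    return CardiacSeries(t_s=t, hr_bpm=hr, hrv_ms=hrv, n_ibi=n)


def fluctuation_index(values) -> float:
    """(max - min) / mean × 100 over the finite entries of a series."""
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty series")
    m = x.mean()
    if m == 0:
        raise ValueError("zero-mean series has no fluctuation index")
    return float((x.max() - x.min()) / m * 100.0)


def hr_hrv_relation(series: CardiacSeries, bin_s: float = 2.0):
    """Slope and Pearson r of HRV vs HR, averaged within ``bin_s`` segments.

    Returns (slope in ms/bpm, pcc). Grid samples are grouped into
    consecutive non-overlapping segments; segments with no defined sample
    are dropped. Raises if fewer than 3 segments remain or HR is constant.
    """
    ok = series.defined
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    seg_idx = np.floor((series.t_s - series.t_s[0]) / bin_s).astype(int)
    hr_means, hrv_means = [], []
    for s in np.unique(seg_idx):
        m = ok & (seg_idx == s)
        if m.any():
            hr_means.append(series.hr_bpm[m].mean())
            hrv_means.append(series.hrv_ms[m].mean())
    hr_means = np.asarray(hr_means)
    hrv_means = np.asarray(hrv_means)
    if len(hr_means) < 3:
        raise ValueError("need at least 3 segments with defined HR/HRV")
    if np.ptp(hr_means) == 0:
        raise ValueError("constant HR: slope undefined")
    fit = linregress(hr_means, hrv_means)
    if np.ptp(hrv_means) == 0:
        return float(fit.slope), 0.0
    pcc = pearsonr(hr_means, hrv_means)[0]
    return float(fit.slope), float(pcc)
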