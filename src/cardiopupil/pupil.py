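"""Pupil-area trace conditioning: blink interpolation and low-pass smoothing.

Pupil area is sampled at 20 Hz from a video-based segmentation upstream;
blinks appear as flagged invalid runs. Invalid runs are bridged linearly
between the flanking valid samples and the result is smoothed with a
zero-phase 4th-order Butterworth low-pass at 3.5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["PupilTrace", "interpolate_blinks", "smooth_pupil", "flag_blinks"]


@dataclass
class PupilTrace:
    fs_hz: float
    area: np.ndarray
    valid: np.ndarray
    t0_s: float = 0.0

    @property
    def t(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.area)) / self.fs_hz


def interpolate_blinks(trace: PupilTrace) -> PupilTrace:
    """Bridge invalid runs linearly; edge runs take the nearest valid value.

    Valid samples pass through unchanged; the returned trace is fully valid.
    """
    valid = np.asarray(trace.valid, bool)
    if not valid.any():
        raise ValueError("trace has no valid samples to interpolate from")
    idx = np.arange(len(trace.area))
    area = np.interp(idx, idx[valid], np.asarray(trace.area, float)[valid])
    area[valid] = trace.area[valid]
    return PupilTrace(fs_hz=trace.fs_hz, area=area,
                      valid=np.ones_like(valid), t0_s=trace.t0_s)


def smooth_pupil(trace: PupilTrace, cutoff_hz: float = 3.5, order: int = 4,
                 pad_s: float = 3.0) -> PupilTrace:
    """Zero-phase Butterworth low-pass (forward–backward, reflective padding)."""
    nyq = trace.fs_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=trace.fs_hz, output="sos")
    padlen = min(len(trace.area) - 1, int(round(pad_s * trace.fs_hz)))
    area = sps.sosfiltfilt(sos, np.asarray(trace.area, float),
                           padtype="even", padlen=padlen)
    return PupilTrace(fs_hz=trace.fs_hz, area=area,
                      valid=np.asarray(trace.valid, bool).copy(), t0_s=trace.t0_s)


def flag_blinks(trace: PupilTrace, z: float = 5.0) -> PupilTrace:
    """Heuristic area-outlier blink flagger (synthetic masks normally stand in).

    Flags samples deviating more than ``z`` robust SDs (MAD-based) below the
    median area, plus their immediate neighbors. This is a convenience for
    traces arriving without a validity mask; it is a simple outlier rule, not
    a validated blink detector.
    """
    area = np.asarray(trace.area, float)
    med = np.median(area)
    mad = np.median(np.abs(area - med))
    scale = 1.4826 * mad if mad > 0 else np.std(area)
    if scale == 0:
        return PupilTrace(trace.fs_hz, area.copy(), np.ones(len(area), bool), trace.t0_s)
    bad = area < med - z * scale
    bad = bad | np.roll(bad, 1) | np.roll(bad, -1)
    return PupilTrace(fs_hz=trace.fs_hz, area=area.copy(), valid=~bad, t0_s=trace.t0_s)
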