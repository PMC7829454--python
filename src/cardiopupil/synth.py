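"""Synthetic Go/No-go sessions with latent-arousal ground truth.

A session couples one latent arousal process to three observables:

* cardiac rhythm — mean inter-beat interval (IBI) decreases with arousal
  (heart rate rises), while the beat-to-beat jitter SD decreases with heart
  rate, so heart-rate variability (HRV) is negatively related to HR;
* pupil area — proportional to arousal plus slow intrinsic noise, sampled at
  20 Hz with Poisson blink gaps flagged in a validity mask;
* behavior — trial outcomes drawn from an equal-variance signal-detection
  model whose sensitivity d'(a) is an inverted U and criterion c(a) a U in
  the trial's pre-stimulus arousal baseline a, with reaction times that
  shorten as arousal rises.

Pupil and cardiac channels share a common latent component but each carries
a private component, so the two observables hold partially independent
information about behavior. Every generator is bit-reproducible given
(config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm

from ._util import as_rng
from .behavior import TrialRecord, label_outcome

__all__ = [
    "ArousalParams",
    "ArousalTrajectory",
    "BeatGroundTruth",
    "CardiacCoupling",
    "PupilCoupling",
    "TaskConfig",
    "ChannelMix",
    "EcgParams",
    "SessionConfig",
    "Session",
    "generate_latent_arousal",
    "generate_beats",
    "synthesize_ecg",
    "generate_pupil",
    "generate_trials",
    "simulate_session",
]


# --------------------------------------------------------------------------
# latent arousal
# --------------------------------------------------------------------------

@dataclass
class ArousalParams:
    """Stationary moments and relaxation time of the latent process."""

    mean: float = 0.0
    sd: float = 1.0
    tau_s: float = 30.0


@dataclass
class ArousalTrajectory:
    """Discretized mean-reverting (Ornstein–Uhlenbeck) arousal sample path."""

    t: np.ndarray
    a: np.ndarray
    params: ArousalParams
    seed: object = None

    @property
    def dt_s(self) -> float:
        return float(self.t[1] - self.t[0])

    def at(self, times) -> np.ndarray:
        """Nearest-sample lookup of arousal at arbitrary times."""
        idx = np.clip(
            np.round((np.asarray(times, float) - self.t[0]) / self.dt_s).astype(int),
            0,
            len(self.a) - 1,
        )
        return self.a[idx]


def generate_latent_arousal(duration_s, params=None, dt_s=0.05, seed=0) -> ArousalTrajectory:
    """Sample a stationary Ornstein–Uhlenbeck path on a uniform grid.

    Uses the exact AR(1) discretization: a[k+1] = m + phi*(a[k]-m) + w[k]
    with phi = exp(-dt/tau) and innovation SD sd*sqrt(1-phi^2), so the
    stationary marginal is N(mean, sd^2) at every step.
    """
    params = params or ArousalParams()
    if duration_s <= 0 or dt_s <= 0 or params.tau_s <= 0:
        raise ValueError("duration_s, dt_s and tau_s must all be positive")
    rng = as_rng(seed)
    n = int(round(duration_s / dt_s)) + 1
    t = np.arange(n) * dt_s
    phi = math.exp(-dt_s / params.tau_s)
    if params.sd == 0:
        a = np.full(n, params.mean)
    else:
        w = rng.standard_normal(n) * (params.sd * math.sqrt(1.0 - phi * phi))
        w[0] = rng.standard_normal() * params.sd  # draw x0 from the stationary law
        # AR(1) recursion via an IIR filter (x[k] = phi*x[k-1] + w[k])
        a = params.mean + lfilter([1.0], [1.0, -phi], w)
    return ArousalTrajectory(t=t, a=a, params=params, seed=seed)


# --------------------------------------------------------------------------
# cardiac ground truth
# --------------------------------------------------------------------------

@dataclass
class CardiacCoupling:
    """Arousal → IBI mean and jitter maps.

    ``mean_ibi_ms`` is affine in arousal with a negative slope so heart rate
    rises with arousal; ``jitter_sd_ms`` falls linearly with the implied HR
    (floored), reproducing a negative HRV–HR relation. Defaults put HR in
    the 350–500 bpm range for ±2 SD of unit-variance arousal with HRV near
    3.7 ms at 400 bpm and an HRV-per-HR slope of about −0.013 ms/bpm.
    """

    ibi0_ms: float = 150.0
    ibi_per_arousal_ms: float = -12.0
    jitter0_ms: float = 8.9
    jitter_per_bpm: float = 0.013
    jitter_min_ms: float = 0.5

    def mean_ibi_ms(self, a):
        return self.ibi0_ms + self.ibi_per_arousal_ms * np.asarray(a, float)

    def jitter_sd_ms(self, a):
        hr = 60000.0 / self.mean_ibi_ms(a)
        return np.maximum(self.jitter_min_ms, self.jitter0_ms - self.jitter_per_bpm * hr)


@dataclass
class BeatGroundTruth:
    """True heartbeat times (s); IBIs in ms are the successive differences."""

    beat_times: np.ndarray

    @property
    def ibi_ms(self) -> np.ndarray:
        return np.diff(self.beat_times) * 1000.0


def generate_beats(arousal: ArousalTrajectory, hr_map, hrv_map, seed=0) -> BeatGroundTruth:
    """Generate beat times over the arousal trajectory's support.

    ``hr_map(a)`` must return the mean IBI in ms at arousal a; ``hrv_map(a)``
    the Gaussian jitter SD in ms. A :class:`CardiacCoupling` supplies both as
    bound methods. Each IBI is mean_ibi(a(t)) + N(0, jitter_sd(a(t))) with a
    1 ms physiological floor on the realized interval.
    """
    rng = as_rng(seed)
    t_end = float(arousal.t[-1])
    t0 = float(arousal.t[0])
    dt = arousal.dt_s
    a_arr = arousal.a
    n_grid = len(a_arr)
    times = []
    t = t0
    while t < t_end:
        idx = int(round((t - t0) / dt))
        a = a_arr[min(max(idx, 0), n_grid - 1)]
        mibi = float(hr_map(a))
        if not np.isfinite(mibi) or mibi <= 0:
            raise ValueError(f"hr_map produced non-positive mean IBI {mibi!r} at arousal {a!r}")
        jit = float(hrv_map(a))
        ibi = mibi + (rng.normal(0.0, jit) if jit > 0 else 0.0)
        ibi = max(ibi, 1.0)
        times.append(t)
        t += ibi / 1000.0
    return BeatGroundTruth(beat_times=np.asarray(times))


# --------------------------------------------------------------------------
# ECG trace synthesis
# --------------------------------------------------------------------------

@dataclass
class EcgParams:
    fs_hz: float = 1000.0
    qrs_amplitude: float = 1.0
    noise_sd: float = 0.1
    qrs_sigma_s: float = 0.004


def synthesize_ecg(beats: BeatGroundTruth, fs_hz=1000.0, qrs_amplitude=1.0,
                   noise_sd=0.0, seed=0, qrs_sigma_s=0.004):
    """Stereotyped QRS-like waveform train plus additive white noise.

    Each beat contributes one narrow positive Gaussian deflection centered at
    the true beat time; at zero noise every beat time is a local maximum of
    the trace to within one sample. Sampling below 500 Hz is rejected (the
    downstream low-pass sits at 250 Hz).
    """
    from .ecg import EcgTrace  # local import to avoid a module cycle

    if fs_hz < 500:
        raise ValueError("ECG sampling rate must be at least 500 Hz")
    rng = as_rng(seed)
    t_last = beats.beat_times[-1] if len(beats.beat_times) else 0.0
    t_first = beats.beat_times[0] if len(beats.beat_times) else 0.0
    t0 = t_first - 0.5  # pad so edge beats are interior local maxima
    n = int(round((t_last + 0.5 - t0) * fs_hz)) + 1
    v = np.zeros(n)
    half = int(round(4 * qrs_sigma_s * fs_hz))
    k = np.arange(-half, half + 1)
    for bt in beats.beat_times:
        c = int(round((bt - t0) * fs_hz))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        sel = k[(c + k >= 0) & (c + k < n)]
        # center the bump on the exact beat time, not the rounded sample
        tt = t0 + (c + sel) / fs_hz - bt
        v[lo:hi] += qrs_amplitude * np.exp(-0.5 * (tt / qrs_sigma_s) ** 2)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return EcgTrace(fs_hz=float(fs_hz), v=v, t0_s=float(t0))


# --------------------------------------------------------------------------
# pupil
# --------------------------------------------------------------------------

@dataclass
class PupilCoupling:
    """Arousal → pupil-area map with slow intrinsic noise and blinks."""

    base: float = 10.0
    gain: float = 1.0
    noise_sd: float = 0.55
    noise_tau_s: float = 2.0
    blink_rate_hz: float = 0.05
    blink_dur_range_s: tuple = (0.1, 0.3)


def generate_pupil(arousal: ArousalTrajectory, gain=1.0, noise_sd=0.55,
                   blink_rate_hz=0.05, fs_hz=20.0, seed=0, base=10.0,
                   noise_tau_s=2.0, blink_dur_range_s=(0.1, 0.3)):
    """Pupil area = base + gain*arousal + slow noise, with blink gaps.

    The intrinsic noise is itself an Ornstein–Uhlenbeck process (time
    constant ``noise_tau_s``) so that it survives 1-s baseline averaging,
    as real pupil fluctuations do. Blink onsets are Poisson at
    ``blink_rate_hz``; each blink invalidates a short run of samples in the
    validity mask (values during blinks are left as recorded garbage:
    downstream interpolation is the consumer's job).
    """
    from .pupil import PupilTrace

    if gain <= 0:
        raise ValueError("gain must be positive")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    kids = ss.spawn(2) if hasattr(ss, "spawn") else [seed, seed]
    duration = float(arousal.t[-1] - arousal.t[0])
    n = int(round(duration * fs_hz)) + 1
    t = arousal.t[0] + np.arange(n) / fs_hz
    area = base + gain * arousal.at(t)
    if noise_sd > 0:
        noise = generate_latent_arousal(
            duration, ArousalParams(0.0, noise_sd, noise_tau_s), dt_s=1.0 / fs_hz,
            seed=kids[0])
        area = area + noise.a[:n]
    valid = np.ones(n, dtype=bool)
    rng = as_rng(kids[1])
    n_blinks = rng.poisson(blink_rate_hz * duration) if blink_rate_hz > 0 else 0
    for _ in range(n_blinks):
        onset = rng.uniform(0.0, duration)
        dur = rng.uniform(*blink_dur_range_s)
        i0 = int(onset * fs_hz)
        i1 = min(n, i0 + max(1, int(round(dur * fs_hz))))
        valid[i0:i1] = False
        area[i0:i1] = 0.0  # occluded pupil reads near zero
    return PupilTrace(fs_hz=float(fs_hz), area=area, valid=valid, t0_s=float(arousal.t[0]))


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

@dataclass
class TaskConfig:
    """Go/No-go task structure and arousal→behavior couplings.

    ``dprime_coeffs``/``criterion_coeffs`` are (b0, b1, b2) of a quadratic in
    the trial's pre-stimulus arousal baseline a. Response probabilities are
    the equal-variance SDT inverse: P(lick|Go) = Phi(d'(a)/2 - c(a)),
    P(lick|No-go) = Phi(-d'(a)/2 - c(a)). Defaults give hit/FA rates, d',
    criterion, and inverted-U/U tuning in the ranges observed in trained
    rats (hit ≈ 0.7, FA ≈ 0.45, d' ≈ 0.85, liberal criterion).
    """

    n_trials: int = 307
    p_go: float = 0.5
    wait_range_s: tuple = (1.0, 3.5)
    no_lick_s: float = 1.0
    window_s: float = 1.3
    iti_s: float = 3.0
    dprime_coeffs: tuple = (1.387, 0.0, -0.45)
    criterion_coeffs: tuple = (-0.469, -1.4, 0.2)
    rt0_s: float = 0.35
    rt_slope: float = -0.05
    rt_noise_sd_s: float = 0.08
    rt_min_s: float = 0.05

    def dprime(self, a):
        b0, b1, b2 = self.dprime_coeffs
        return b0 + b1 * a + b2 * a * a

    def criterion(self, a):
        c0, c1, c2 = self.criterion_coeffs
        return c0 + c1 * a + c2 * a * a


def generate_trials(arousal: ArousalTrajectory, task: TaskConfig, seed=0):
    """Draw a trial sequence whose outcomes depend on baseline arousal.

    Stimulus onsets honor the task timing (inter-trial interval, then a
    1–3.5 s uniform wait whose final 1 s is the no-lick period). The arousal
    value entering d'(a)/c(a) is the mean over the 1 s pre-stimulus baseline
    window, i.e. exactly the quantity downstream baseline extraction sees.
    """
    if not (0.0 < task.p_go < 1.0):
        raise ValueError("p_go must be in (0, 1)")
    if task.window_s <= 0:
        raise ValueError("window_s must be positive")
    rng = as_rng(seed)
    trials = []
    t = float(arousal.t[0]) + 2.0
    t_end = float(arousal.t[-1])
    for i in range(task.n_trials):
        wait = rng.uniform(*task.wait_range_s)
        onset = t + wait
        if onset + task.window_s + 1.0 > t_end:
            break
        # baseline arousal over [onset-1, onset)
        dt = arousal.dt_s
        i0 = int(np.ceil((onset - 1.0 - arousal.t[0]) / dt))
        i1 = int(np.ceil((onset - arousal.t[0]) / dt))
        a = float(np.mean(arousal.a[i0:i1]))
        d = task.dprime(a)
        c = task.criterion(a)
        if not (np.isfinite(d) and np.isfinite(c)):
            raise ValueError(f"non-finite d'/criterion at arousal {a!r}")
        is_go = rng.random() < task.p_go
        p_lick = norm.cdf(d / 2.0 - c) if is_go else norm.cdf(-d / 2.0 - c)
        if not (0.0 < p_lick < 1.0):
            raise ValueError(f"response probability {p_lick!r} outside (0,1) at arousal {a!r}")
        first_lick = None
        rt = None
        if rng.random() < p_lick:
            rt = task.rt0_s + task.rt_slope * a + rng.normal(0.0, task.rt_noise_sd_s)
            rt = min(max(rt, task.rt_min_s), task.window_s)
            first_lick = onset + rt
        stim = "go" if is_go else "nogo"
        outcome = label_outcome(stim, first_lick, onset, task.window_s)
        trials.append(TrialRecord(
            trial_id=i, stimulus=stim, onset_s=onset, first_lick_s=first_lick,
            window_s=task.window_s, outcome=outcome,
            rt_s=rt if outcome in ("hit", "fa") else None))
        t = onset + task.window_s + task.iti_s
    return trials


# --------------------------------------------------------------------------
# whole sessions
# --------------------------------------------------------------------------

@dataclass
class ChannelMix:
    """Private-channel weights for the cardiac and pupil arousal drives.

    Each observable channel is (shared + lambda*private)/sqrt(1+lambda^2),
    keeping unit variance; behavior is driven by the normalized sum of the
    two channel arousals. lambda = 0 collapses to a single shared latent.
    """

    lambda_hr: float = 1.4
    lambda_pa: float = 1.4


@dataclass
class SessionConfig:
    arousal: ArousalParams = field(default_factory=ArousalParams)
    cardiac: CardiacCoupling = field(default_factory=CardiacCoupling)
    pupil: PupilCoupling = field(default_factory=PupilCoupling)
    task: TaskConfig = field(default_factory=TaskConfig)
    mix: ChannelMix = field(default_factory=ChannelMix)
    ecg: EcgParams = field(default_factory=EcgParams)
    arousal_dt_s: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        return cls(
            arousal=ArousalParams(**d.get("arousal", {})),
            cardiac=CardiacCoupling(**d.get("cardiac", {})),
            pupil=PupilCoupling(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in d.get("pupil", {}).items()}),
            task=TaskConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in d.get("task", {}).items()}),
            mix=ChannelMix(**d.get("mix", {})),
            ecg=EcgParams(**d.get("ecg", {})),
            arousal_dt_s=d.get("arousal_dt_s", 0.05),
        )


@dataclass
class Session:
    """One simulated session with full ground truth."""

    config: SessionConfig
    seed: int
    trials: list
    arousal_beh: ArousalTrajectory
    arousal_hr: ArousalTrajectory
    arousal_pa: ArousalTrajectory
    beats_truth: BeatGroundTruth
    pupil: object
    ecg: object = None  # EcgTrace when synthesized


def simulate_session(config: SessionConfig = None, seed=0, with_ecg=True) -> Session:
    """Generate a complete session (latents, beats, pupil, trials, ECG).

    ``with_ecg=False`` skips raw-trace synthesis; downstream cardiac series
    can then be computed from the ground-truth beat times directly, which is
    the fast path for large simulation studies.
    """
    config = config or SessionConfig()
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    k_shared, k_phr, k_ppa, k_beats, k_pupil, k_trials, k_ecg = ss.spawn(7)

    task = config.task
    mean_trial = (config.task.iti_s + np.mean(task.wait_range_s)
                  + task.window_s + 1.0)
    duration = task.n_trials * (mean_trial + (task.wait_range_s[1]
                                - np.mean(task.wait_range_s))) + 30.0

    ap = config.arousal
    dt = config.arousal_dt_s
    shared = generate_latent_arousal(duration, ArousalParams(0.0, ap.sd, ap.tau_s), dt, k_shared)
    lam_h, lam_p = config.mix.lambda_hr, config.mix.lambda_pa
    if lam_h > 0:
        ph = generate_latent_arousal(duration, ArousalParams(0.0, ap.sd, ap.tau_s), dt, k_phr)
        a_hr = (shared.a + lam_h * ph.a) / math.sqrt(1 + lam_h ** 2)
    else:
        a_hr = shared.a.copy()
    if lam_p > 0:
        pp = generate_latent_arousal(duration, ArousalParams(0.0, ap.sd, ap.tau_s), dt, k_ppa)
        a_pa = (shared.a + lam_p * pp.a) / math.sqrt(1 + lam_p ** 2)
    else:
        a_pa = shared.a.copy()
    rho = 1.0 / math.sqrt((1 + lam_h ** 2) * (1 + lam_p ** 2))
    a_beh = (a_hr + a_pa) / math.sqrt(2.0 * (1.0 + rho))

    mk = lambda arr: ArousalTrajectory(t=shared.t, a=ap.mean + arr, params=ap)
    tr_beh, tr_hr, tr_pa = mk(a_beh), mk(a_hr), mk(a_pa)

    beats = generate_beats(tr_hr, config.cardiac.mean_ibi_ms, config.cardiac.jitter_sd_ms, k_beats)
    pc = config.pupil
    pupil = generate_pupil(tr_pa, gain=pc.gain, noise_sd=pc.noise_sd,
                           blink_rate_hz=pc.blink_rate_hz, seed=k_pupil,
                           base=pc.base, noise_tau_s=pc.noise_tau_s,
                           blink_dur_range_s=pc.blink_dur_range_s)
    trials = generate_trials(tr_beh, task, k_trials)
    ecg = None
    if with_ecg:
        ep = config.ecg
        ecg = synthesize_ecg(beats, fs_hz=ep.fs_hz, qrs_amplitude=ep.qrs_amplitude,
                             noise_sd=ep.noise_sd, seed=k_ecg, qrs_sigma_s=ep.qrs_sigma_s)
    return Session(config=config, seed=seed if isinstance(seed, int) else None,
                   trials=trials, arousal_beh=tr_beh, arousal_hr=tr_hr,
                   arousal_pa=tr_pa, beats_truth=beats, pupil=pupil, ecg=ecg)
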