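# Methods

This note documents the models, estimators, and numerical choices in
`cardiopupil`, and what the synthetic-session generator does and does not
emulate.

## The analysis problem

In a head-fixed Go/No-go discrimination task, an animal licks to report one
stimulus class and withholds to the other; each trial ends as a hit, miss,
false alarm (FA), or correct rejection (CR). Pupil area (20 Hz) and ECG
(1 kHz) are recorded throughout. The analysis asks how the pre-stimulus
arousal state — indexed by baseline pupil size, heart rate (HR), and
heart-rate variability (HRV) — relates to perceptual sensitivity, decision
criterion, reaction time, and trial outcome, and whether the pupillary and
cardiac indices carry redundant or distinct information about behavior.

## ECG processing

**Filtering.** The raw trace is high-pass filtered with an 8th-order
elliptic filter (4 Hz cutoff, 0.1 dB passband ripple, 80 dB stopband)
applied forward–backward (`sosfiltfilt`) for zero phase, then smoothed with
a Gaussian kernel whose SD is set so the kernel's magnitude response is
−3 dB at 250 Hz (σ = √(ln 2)/(2π·250) s ≈ 0.53 ms). The 80 dB stopband
ensures DC leaks through at below 10⁻⁶ relative amplitude after the double
pass. Sampling below 500 Hz is rejected (the low-pass needs headroom below
Nyquist).

**Adaptive prominence threshold.** All local maxima are ranked by
topographic prominence (height above the higher of the two flanking
minima). Counting the peaks that survive a prominence threshold, as the
threshold rises from 0 to the maximum prominence in steps of max/200,
yields a non-increasing curve with a characteristic plateau: below the
plateau the count includes noise peaks, above it R peaks start being lost.
The per-session threshold is the point where the descending rate of this
curve is smallest — the curve is smoothed with a 5-point moving average,
differentiated, restricted to the interval between its first and last
descending segments, and the |derivative| minimum is refined by Nelder–Mead
(downhill simplex) on a linear interpolant. A curve with no interior
plateau (e.g. pure noise) triggers a warning and falls back to the global
|derivative| minimum. Scan step, smoothing width, and the simplex objective
are free choices of this implementation.

**Peak pick and cardiac series.** R peaks are local maxima with prominence
above the threshold, separated by at least 50 ms (a ~1200 bpm physiological
ceiling). Inter-beat intervals (IBIs, ms) are successive differences of the
peak times. On a 0.5 s grid anchored at the first beat, HR = 60000 /
mean(IBI) and HRV = sample SD (ddof = 1) of the IBIs whose *midpoints* fall
in the half-open window [t − 0.5, t + 0.5); windows with fewer than two
IBIs are flagged undefined. Anchoring the grid at the first beat makes the
series invariant to a global time shift. The fluctuation index of a series
is (max − min)/mean × 100. The HRV-vs-HR relation is summarized by the
least-squares slope and Pearson r after averaging both series within
consecutive 2 s (or 5 s) segments.

## Pupil processing

Invalid (blink) runs are bridged by linear interpolation between the
flanking valid samples; leading/trailing invalid runs take the nearest
valid value. The full-valid trace is then low-pass filtered with a
4th-order Butterworth at 3.5 Hz, forward–backward with reflective padding
of 3 s, preserving length and phase. Butterworth (maximally flat) is the
family choice; only order and cutoff are externally constrained. A
convenience outlier-based blink flagger exists for traces arriving without
a validity mask; it is a simple robust-z rule on area dropouts, not a
validated blink detector.

## Behavior metrics

A lick in (onset, onset + window] is a response; windows of 0.8 or 1.3 s
are both in use. Rates are hit/Go and FA/No-go counts;
d' = Ψ⁻¹(hit rate) − Ψ⁻¹(FA rate) and c = −(Ψ⁻¹(hit) + Ψ⁻¹(FA))/2 with Ψ⁻¹
the standard normal quantile (scipy's `ndtri`-backed implementation,
accurate well below 1e−9; equal rates give exactly d' = 0). When a rate
saturates, the loglinear correction (add 0.5 to hit/FA counts, 1 to Go/No-go
counts) keeps both finite. Baselines are means over the half-open window
[onset − 1 s, onset); HR/HRV baselines average the 0.5 s grid values whose
times fall in the window (an alternative that recomputes from the raw IBIs
in the window is available via `extract_baselines(..., from_grid=False)`).
Trials whose baseline window is not fully covered by the trace are dropped
and logged. Study-level exclusions: the first 20 trials of each session
(apparatus-adjustment period), and any session whose FA rate exceeds its
hit rate.

## Arousal tuning

Per session and per variable (PA, HR, HRV), baselines are normalized to
percent of maximum, (x − min)/(max − min) × 100, and split into 20
equal-width bins with the last bin right-closed. Per bin: loglinear
d'/criterion from the bin's outcome counts and the mean reaction time over
responded trials. A degree-2 polynomial is fitted by least squares to the
bin centers vs bin statistics (undefined bins dropped; bins unweighted by
trial count — the weighting convention is a free choice, flagged here).
The second-degree weight quantifies the inverted-U (d', β₂ < 0) and
U-shaped (criterion, β₂ > 0) relations. Task-evoked dynamics are per-trial
percent change from that trial's own pre-stimulus baseline, interpolated
onto a stimulus-aligned grid and averaged within outcome.

## Bayesian decoder

Baselines are discretized into 15 equal-width bins per session (edges from
the full session's range; values outside supplied edges clamp to the
extreme bins). The posterior over the binary outcome R uses chain-rule
factorizations whose first predictor is the target and the rest condition
it:

    P(R|X)     ∝ P(X|R) P(R)
    P(R|X,Y)   ∝ P(X|Y,R) P(R|Y)
    P(R|X,Y,Z) ∝ P(X|Y,Z,R) P(R|Y,Z)

with every term estimated by add-one smoothing
P̂(A|B) = (D_{B,A} + 1)/(D_B + N_A). N_A is the number of possible values of
the *predicted* variable (2 for R, 15 for a baseline-bin axis): this is the
only reading under which each conditional sums to one, so it is the one
implemented. The three-predictor model conditions on the full 15×15 joint
of the secondary predictors, relying on smoothing for the (severe)
sparsity. Prediction is MAP (respond iff posterior > 0.5; an exact tie
falls back to the larger smoothed prior, then to respond). Evaluation is
leave-one-out cross-validation with bin edges fixed from the whole session
(per-fold edges available via `edges_per_fold=True`).

**Chance level.** Two definitions are provided. `chance_method="prior"`
scores the prior-only decoder (per fold, predict the training-set's
smoothed majority class). This is simple but systematically *above* the
binned decoder on uninformative predictors: the decoder's bin-wise votes
deviate from the majority on noise, and each deviation has an expected
cost the prior decoder never pays (measured ≈ 1.5% over 100 null
sessions). `chance_method="permutation"` scores the same decoder on
seeded label shuffles (3 by default, averaged); it shares the decoder's
overfitting behavior and is therefore centred on the decoder's own
null-level accuracy, making above-chance an unbiased zero under
independence. The prior definition remains the default for its
determinism and speed; calibration-sensitive analyses (and the acceptance
script) use the permutation definition.

**Overlap.** For two decoders with correct-trial sets A and B,
pct_overlap = |A∩B| / ((|A| + |B|)/2) × 100, and normalized_overlap =
pct_overlap / (100 × mean accuracy), a dimensionless ratio equal to 1 when
the overlap is exactly what the accuracies alone force.

## Synthetic sessions

The generator provides ground truth for every estimator; its defaults *are*
the study conditions the analyses are validated under.

**Latent arousal.** A discretized Ornstein–Uhlenbeck process (exact AR(1)
transition, dt = 0.05 s, stationary N(mean, sd²)) with relaxation time
τ = 30 s, matching slow within-session arousal drift. Three independent
unit-variance processes — one shared, one cardiac-private, one
pupil-private — combine into channel arousals
a_ch = (shared + λ·private)/√(1+λ²) with λ = 1.4 for both channels
(channel correlation 1/(1+λ²) ≈ 0.34), and the behavioral arousal is the
normalized mean of the two channel signals. Private components are what
make pupil and HR carry partially independent information about behavior;
λ = 0 collapses to a single redundant latent.

**Cardiac coupling.** Mean IBI = 150 − 12·a ms (HR ≈ 333–500 bpm over ±2.5
SD, ~400 bpm at rest, fluctuation index in the 30–55% range); beat-to-beat
jitter SD = max(0.5, 8.9 − 0.013·HR) ms, i.e. ≈ 3.7 ms at 400 bpm with a
−0.013 ms/bpm slope, reproducing the negative HRV–HR relation. Beats are
generated sequentially, each IBI Gaussian around the arousal-dependent
mean.

**ECG trace.** Each beat contributes a narrow positive Gaussian deflection
(σ = 4 ms) at 1 kHz, plus white noise (default SD = 10% of the QRS
amplitude); the trace is padded 0.5 s so edge beats are interior local
maxima. P/T waves and realistic QRS morphology are deliberately out of
scope — the waveform exists to exercise the detector, not to fool a
cardiologist.

**Pupil.** area = base + gain·a_pupil + slow intrinsic noise (an OU process
with τ = 2 s, SD 0.55 in arousal units) sampled at 20 Hz, with Poisson
blink gaps (0.05 Hz, 0.1–0.3 s) zeroed and flagged invalid. The intrinsic
noise is slow on purpose: white noise would be averaged away by the 1 s
baseline window and make the pupil an implausibly clean arousal readout.

**Behavior.** Per trial, the generative sensitivity and criterion are
quadratics in the trial's baseline arousal a (the mean over
[onset − 1, onset), i.e. exactly the quantity downstream estimation sees):
d'(a) = 1.387 − 0.45 a², c(a) = −0.469 − 1.4 a + 0.2 a². Response
probabilities invert the equal-variance SDT model:
P(lick|Go) = Φ(d'/2 − c), P(lick|No-go) = Φ(−d'/2 − c). The intercepts are
calibrated (by Gauss–Hermite quadrature over the stationary arousal law) so
the expected hit and FA rates are 0.71 and 0.45; the curvatures implement
the inverted-U/U shapes at an effect size recoverable from single-session
tuning curves; the strong negative linear criterion term makes responding
rise steeply with arousal, which is what gives the baselines their
paper-scale decodability (≈ 14–20% above chance) and responded-vs-withheld
HR differences. Reaction time = clip(0.35 − 0.05·a + N(0, 0.08), 0.05 s,
window). Trial timing: 3 s inter-trial interval, a 1–3.5 s uniform wait
(whose final 1 s is the no-lick period; premature-lick stimulus delays are
represented only as this timing jitter), a 0.8 or 1.3 s response window
(default 1.3), 307 trials per session.

**What the generator does not emulate.** Arousal is Gaussian and
stationary; real sessions drift and fatigue. The pupil–HR coupling
(PCC ≈ 0.2–0.3 at these settings) is somewhat stronger than the weak
correlations typical of real recordings — weakening it to that level would
starve the pupil decoder, and the calibration favors paper-scale decoder
accuracy over paper-scale PCC; both cannot hold simultaneously under a
jointly Gaussian latent model. HRV's fluctuation index (~200–250%) is
large but below the extreme values real windowed-SD estimates produce.
Passing tests therefore certify the *estimators* (detection, windowing,
binning, smoothing, cross-validation) against known ground truth, not the
generator's fidelity to any particular animal.

## Problem sizes and runtime choices

Simulation studies in the test suite use 100 sessions of 307 trials for
calibration/coupling/tuning properties (the natural session scale), 20–40
sessions for directional unit checks, and 35–80-trial sessions wherever a
raw 1 kHz ECG trace is synthesized. The acceptance script uses 30 fast-path
sessions plus one fully synthesized ECG session; these sizes keep every
quantity's Monte-Carlo error well inside the margins being tested.

## Known limitations

* The three-predictor decoder's 15³×2 count tensor is almost entirely
  smoothing at 300-trial scale; it is included for completeness and behaves
  sensibly (no better than pupil+HR), but its absolute accuracy is
  smoothing-dominated.
* `optimize_threshold` assumes a unimodal noise/signal prominence split;
  multi-modal amplitude distributions (e.g. electrode artifacts rivaling
  QRS amplitude) would need a multi-plateau treatment.
* Blink detection proper is out of scope; the validity mask is taken as
  given (or crudely inferred by the robust-z flagger).
* Statistical testing across sessions (ANOVA, post-hoc comparisons) is
  delegated to standard libraries by the user; the package computes the
  per-session quantities.
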