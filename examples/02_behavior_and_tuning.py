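"""Signal-detection metrics and arousal tuning curves for one session.

Labels trials, applies the warmup exclusion, extracts 1-s pre-stimulus
baselines, and fits the inverted-U (d') and U (criterion) shapes against
the percent-of-maximum heart-rate baseline.
"""

import numpy as np
from scipy.stats import pearsonr

import cardiopupil as cp

session = cp.simulate_session(seed=7, with_ecg=False)
trials = session.trials[20:]  # warmup exclusion

hit, fa = cp.response_rates(trials)
n_go = sum(t.stimulus == "go" for t in trials)
m = cp.loglinear_sdt(sum(t.outcome == "hit" for t in trials), n_go,
                     sum(t.outcome == "fa" for t in trials), len(trials) - n_go)
print(f"hit rate {hit:.3f}, FA rate {fa:.3f} -> d' = {m.dprime:.3f}, "
      f"criterion = {m.criterion:+.3f} (negative = liberal responding)")

cardiac = cp.cardiac_series(cp.BeatSeries(session.beats_truth.beat_times))
pupil = cp.smooth_pupil(cp.interpolate_blinks(session.pupil))
baselines = cp.extract_baselines(trials, cardiac, pupil)

groups = cp.outcome_conditioned_baselines(baselines).set_index("group")
print(f"baseline HR responded {groups.loc['responded', 'hr']:.1f} bpm vs "
      f"withheld {groups.loc['withheld', 'hr']:.1f} bpm "
      "(higher arousal on responded trials)")

curve = cp.tuning_curve(baselines, "hr", n_bins=20)
fit_d = cp.quadratic_regression(curve.bin_centers, curve.dprime)
fit_c = cp.quadratic_regression(curve.bin_centers, curve.criterion)
print(f"quadratic beta2: d' {fit_d.beta2:+.2e} (inverted U), "
      f"criterion {fit_c.beta2:+.2e} (U-shape)")

ok = np.isfinite(curve.rt)
r = pearsonr(curve.bin_centers[ok], curve.rt[ok])[0]
print(f"bin-wise reaction time vs HR correlation r = {r:+.2f} "
      "(faster responses at higher arousal)")

corr = cp.baseline_correlations(baselines)
print(f"trial-to-trial PCC(pupil, HR) = {corr['pcc_pa_hr']:+.3f}; the positive "
      "coupling reflects the shared arousal drive of both signals")
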