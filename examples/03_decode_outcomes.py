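"""Bayesian decoding of respond/withhold from pre-stimulus physiology.

Runs leave-one-out cross-validated decoders over 15-bin discretized
baselines — pupil alone, HR alone, HRV alone, and pupil+HR — and measures
how much the two informative channels overlap in the trials they predict.
"""

import cardiopupil as cp

session = cp.simulate_session(seed=3, with_ecg=False)
trials = session.trials[20:]
cardiac = cp.cardiac_series(cp.BeatSeries(session.beats_truth.beat_times))
pupil = cp.smooth_pupil(cp.interpolate_blinks(session.pupil))
baselines = cp.extract_baselines(trials, cardiac, pupil)
responded = baselines["responded"].to_numpy()

results = {}
for preds in (("pa",), ("hr",), ("hrv",), ("pa", "hr")):
    res = cp.loocv_evaluate(baselines, responded, preds,
                            chance_method="permutation", seed=0)
    results[preds] = res
    print(f"{'+'.join(preds):6s} accuracy {res.accuracy:.3f} "
          f"(chance {res.chance:.3f}, above-chance {100 * res.above_chance:+.1f}%)")

ov = cp.overlap_metrics(results[("pa",)].correct_idx,
                        results[("hr",)].correct_idx,
                        results[("pa",)].accuracy, results[("hr",)].accuracy)
print(f"pupil/HR correctly-predicted-trial overlap {ov.pct_overlap:.1f}% "
      f"(normalized {ov.normalized_overlap:.2f}); overlap below what the "
      "accuracies force indicates partially independent arousal channels")
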