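"""Run a small multi-session study end to end and print the report summary.

Equivalent to `cardiopupil run-all --seed 5 --out scratch/study` with a
reduced session count/size so it finishes in seconds. Outputs (per-session
CSVs plus report.json) land under scratch/, which is disposable.
"""

import json

from cardiopupil.pipeline import StudyConfig, run_study
from cardiopupil.synth import SessionConfig, TaskConfig

config = StudyConfig(
    n_sessions=3,
    master_seed=5,
    session=SessionConfig(task=TaskConfig(n_trials=80)),
    with_ecg=True,
)
report = run_study(config, "scratch/study")

print(f"analyzed {report['n_analyzed']}/{config.n_sessions} sessions")
for key in ("hit_rate", "fa_rate", "dprime", "criterion",
            "fi_hr", "hr_hrv_slope_2s", "pcc_pa_hr",
            "above_chance_pa", "above_chance_hr", "above_chance_pa_hr"):
    if key in report["summary"]:
        s = report["summary"][key]
        print(f"  {key:20s} {s['mean']:+.4f} ± {s['sem']:.4f} (n={s['n']})")
print("full report: scratch/study/report.json")
print(json.dumps(report["sessions"][0], indent=2)[:400])
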