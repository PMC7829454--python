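import numpy as np
import pytest

import cardiopupil as cp


@pytest.fixture(scope="session")
def default_session():
    """One default-regime session (fast path, no raw ECG synthesis)."""
    return cp.simulate_session(seed=11, with_ecg=False)


@pytest.fixture(scope="session")
def default_baselines(default_session):
    """Baseline table for the default session after warmup exclusion."""
    s = default_session
    cardiac = cp.cardiac_series(cp.BeatSeries(s.beats_truth.beat_times))
    pupil = cp.smooth_pupil(cp.interpolate_blinks(s.pupil))
    return cp.extract_baselines(s.trials[20:], cardiac, pupil)


@pytest.fixture(scope="session")
def constant_beats():
    """400 bpm constant-rate beats over 60 s (IBI exactly 150 ms)."""
    return cp.BeatGroundTruth(beat_times=np.arange(0.0, 60.0, 0.15))
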