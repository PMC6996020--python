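import numpy as np
import pytest

import tmazephys as tp

FS = 512.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture
def tone():
    def make(freq, duration, amp=1.0, fs=FS, phase=0.0):
        t = np.arange(int(round(duration * fs))) / fs
        return amp * np.cos(2 * np.pi * freq * t + phase)
    return make


@pytest.fixture(scope="session")
def small_session():
    """A short synthetic session reused by io/pipeline tests."""
    cfg = tp.CohortConfig(n_trials=3, habituation_s=20.0,
                          inter_run_interval_s=10.0)
    return tp.generate_session(cfg, animal_id="a0", group="wt", seed=5)


@pytest.fixture(scope="session")
def analyzed_row(small_session):
    """Full per-animal measures for the small session (computed once)."""
    cfg = tp.AnalysisConfig(compute_habituation=False)
    return tp.analyze_session(small_session, cfg)
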