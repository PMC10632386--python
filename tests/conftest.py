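import numpy as np
import pytest

from copgait import synthetic_gait as sg


@pytest.fixture(scope="session")
def baseline_trial():
    """One unperturbed 120 s walking trial (~100 strides), reused widely."""
    subj = sg.draw_subject("s000", "EG", sg.subject_stream(11, 0, 0))
    rng = sg.subject_stream(11, 0, 1)
    return sg.simulate_trial(subj, "GaitBaseline", [], sg.ProtocolConfig(),
                             rng, duration_s=120.0), subj


@pytest.fixture()
def make_trial():
    """Factory for short trials with controlled subject parameters."""
    def _make(seed=0, duration_s=40.0, trial_label="GaitBaseline",
              schedule=(), **param_overrides):
        subj = sg.draw_subject("s000", "EG", sg.subject_stream(seed, 0, 0))
        if param_overrides:
            from dataclasses import replace
            subj = replace(subj, **param_overrides)
        rng = sg.subject_stream(seed, 0, 1)
        rec = sg.simulate_trial(subj, trial_label, list(schedule),
                                sg.ProtocolConfig(), rng,
                                duration_s=duration_s)
        return rec, subj
    return _make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250919)
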