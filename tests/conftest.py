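import numpy as np
import pytest

import owlstrike as o


@pytest.fixture(scope="session")
def night_f():
    """One moderate synthetic night for a female owl, with ground truth."""
    cfg = o.SyntheticNightConfig(seed=2, night_duration=4500, n_trips=4)
    meta = o.generate_owl("f-2", "F", np.random.default_rng(2))
    return o.simulate_night(cfg, meta)


@pytest.fixture(scope="session")
def night_m():
    cfg = o.SyntheticNightConfig(seed=4, night_duration=4500, n_trips=4)
    meta = o.generate_owl("m-4", "M", np.random.default_rng(4))
    return o.simulate_night(cfg, meta)


@pytest.fixture(scope="session")
def processed_f(night_f):
    return o.process_synthetic_night(night_f)


@pytest.fixture(scope="session")
def processed_m(night_m):
    return o.process_synthetic_night(night_m)


@pytest.fixture()
def thresholds():
    return o.RuleThresholds()


def make_trace(heave, surge=None, sway=None, t0=0.0):
    """Build a 50 Hz trace from raw arrays (zeros for omitted axes)."""
    heave = np.asarray(heave, dtype=float)
    n = len(heave)
    zeros = np.zeros(n)
    return o.AccelerometerTrace(
        t=t0 + np.arange(n) / 50.0,
        heave=heave,
        surge=zeros if surge is None else np.asarray(surge, dtype=float),
        sway=zeros if sway is None else np.asarray(sway, dtype=float),
    )
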