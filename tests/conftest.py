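import time

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from actisleep import pipeline, synthetic

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """6-day synthetic study at 10 Hz with the default regular schedule."""
    schedule = synthetic.regular_schedule(6, seed=3)
    profile = synthetic.SimProfile(seed=3)
    raw = synthetic.simulate_study(schedule, profile)
    result = pipeline.run_study(raw)
    return schedule, profile, raw, result


@pytest.fixture(scope="session")
def study30():
    """30-day synthetic study at 10 Hz: regular schedule with arousals,
    naps and non-wear blocks, run through the full pipeline."""
    schedule = synthetic.regular_schedule(30, seed=11)
    profile = synthetic.SimProfile(sampling_rate_hz=10.0, seed=11)
    raw = synthetic.simulate_study(schedule, profile)
    t0 = time.time()
    result = pipeline.run_study(raw)
    elapsed = time.time() - t0
    return schedule, raw, result, elapsed


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
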