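import numpy as np
import pytest

from dyadsync import SimConfig, analyze_session, simulate_session

#: A compact protocol keeping two full-length slices' worth of interaction
#: epochs while staying fast enough for per-test reuse.
SHORT_PLAN = (
    ("BASE", 60.0),
    ("INT1", 240.0),
    ("NEU1", 60.0),
    ("INT2", 240.0),
    ("POST", 60.0),
)


@pytest.fixture(scope="session")
def short_session():
    cfg = SimConfig(seed=11, subsession_plan=SHORT_PLAN)
    bundle, truth = simulate_session(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def analyzed(short_session):
    _, bundle, _ = short_session
    return analyze_session(bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
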