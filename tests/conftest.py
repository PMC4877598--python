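import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160524)


@pytest.fixture
def step_track():
    """200-bin log2-ratio track with a -1 step over bins 81-120 (1-based)
    and N(0, 0.1^2) noise: the shape of a heterozygous deletion at 250 bp
    bins."""
    from promdel import RatioTrack

    noise = np.random.default_rng(7).normal(0.0, 0.1, 200)
    values = noise.copy()
    values[80:120] -= 1.0
    starts = np.arange(200, dtype=np.int64) * 250 + 1
    return RatioTrack("chrT", starts, starts + 249, values)
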