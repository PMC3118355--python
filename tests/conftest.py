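import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def small_log2_matrix(rng):
    """100 probes × 4 arrays, log2 scale, mild array offsets."""
    from kdnorm import LOG2, ExpressionMatrix

    base = rng.normal(8, 2, size=100)
    shifts = np.array([0.0, 0.3, -0.2, 0.1])
    values = base[:, None] + shifts[None, :] + rng.normal(0, 0.2, size=(100, 4))
    return ExpressionMatrix(
        values=values,
        probe_ids=[f"p{i}" for i in range(100)],
        array_ids=["a1", "a2", "a3", "a4"],
        scale=LOG2,
    )
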