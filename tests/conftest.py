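import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230217)


@pytest.fixture
def toy_weight_table():
    from morbistate import DiseaseWeightTable

    return DiseaseWeightTable({"A": 1.5, "B": 2.0, "C": 4.0})


@pytest.fixture
def illness_death_space():
    """S1 (healthy) -> S2 (ill) -> S3 (dead), death from both living states."""
    from morbistate import StateSpace

    return StateSpace(
        living=("S1", "S2"),
        death="S3",
        allowed=frozenset({("S1", "S2"), ("S1", "S3"), ("S2", "S3")}),
    )
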