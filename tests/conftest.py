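import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=20,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# loose-but-fast solver settings for tests that only need qualitative accuracy
FAST = dict(rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="session")
def fast_kwargs():
    return dict(FAST)


@pytest.fixture(scope="session")
def bimolecular_network():
    """A + B -> C, irreversible; closed form C(t) = k t / (1 + k t) for A0=B0=1."""
    from necrosim.network import Reaction, ReactionNetwork

    return ReactionNetwork(
        species=["A", "B", "C"],
        reactions=[Reaction("bind", {"A": 1, "B": 1}, {"C": 1}, "k", "association")],
        parameters={"k": 1.0},
        parameter_classes={"k": "kinetic"},
    )


@pytest.fixture(scope="session")
def reference_truth():
    """Reference ground truth for synthetic-data and calibration tests."""
    from necrosim.synth import GroundTruth

    return GroundTruth()
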