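import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design_d3_len4():
    """Small designed set: length 4, minimum edit distance 3, default filters."""
    from tagkit.design import DesignSpec, design

    return design(DesignSpec(length=4, min_distance=3))


@pytest.fixture(scope="session")
def design_d3_len5():
    from tagkit.design import DesignSpec, design

    return design(DesignSpec(length=5, min_distance=3))


@pytest.fixture(scope="session")
def design_d5_len6():
    """Length-6 set at minimum edit distance 5 (small, for round-trip checks)."""
    from tagkit.design import DesignSpec, design

    return design(DesignSpec(length=6, min_distance=5))
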