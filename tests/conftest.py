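import pytest

from agpsuite.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_fixture():
    """One default-condition synthetic dataset shared across tests."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def clean_fixture():
    """Error-free maps and annotations: every stage should recover truth."""
    return simulate(SimConfig(seed=7, map_error_rate=0.0, missing_rate=0.0,
                              chimera_rate=0.0, split_rate=0.0,
                              curated_fraction=0.0))
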