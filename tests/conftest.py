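import numpy as np
import pytest

from wpdinm import (
    FixtureConfig,
    ProteinNetwork,
    generate_fixture_bundle,
    run_pipeline,
)


@pytest.fixture(scope="session")
def seeded_bundle():
    """The standard desk-scale study bundle: 300 proteins, 60 domains."""
    return generate_fixture_bundle(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def seeded_result(seeded_bundle):
    return run_pipeline(seeded_bundle)


@pytest.fixture()
def k3_network():
    return ProteinNetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture()
def pendant_network():
    """Triangle a-b-c with a pendant d attached to a."""
    return ProteinNetwork.from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "a")]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
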