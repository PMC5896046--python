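import pytest

from psimif import fixtures


@pytest.fixture(scope="session")
def goldens():
    """All eleven golden use-case fixtures with their loss manifests."""
    return [fixtures.golden(c) for c in fixtures.USE_CASES]


@pytest.fixture(scope="session")
def random_docs():
    """A small batch of seeded all-flag random documents."""
    return [
        fixtures.generate_random(
            fixtures.GeneratorSpec(seed=s, feature_flags=fixtures.all_flags()))
        for s in range(8)
    ]
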