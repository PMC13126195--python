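import pytest

from r2gbga.chemcore import canonicalize
from r2gbga.fixtures_io import (
    DEFAULT_MOTIFS,
    FixtureSpec,
    generate_toy_pool,
    toy_reaction_pool,
)


@pytest.fixture(scope="session")
def toy_pool():
    return toy_reaction_pool()


@pytest.fixture(scope="session")
def motifs():
    return [canonicalize(s) for s in DEFAULT_MOTIFS]


@pytest.fixture(scope="session")
def fixture_mols(toy_pool):
    """50 deterministic drug-like fixture molecules."""
    mols, _ = generate_toy_pool(FixtureSpec(n_molecules=50, seed=1), pool=toy_pool)
    return mols


@pytest.fixture(scope="session")
def fixture_corpus(toy_pool):
    """A larger corpus with matching noise-free property values."""
    return generate_toy_pool(
        FixtureSpec(n_molecules=120, seed=7, noise_sigma=0.0), pool=toy_pool
    )
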