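"""Shared fixtures: small synthetic communities generated at test time."""

import numpy as np
import pytest

from gcbin.synthetic import CommunitySpec, generate_community


@pytest.fixture(scope="session")
def desk_community():
    """The standard desk-scale community: 8 genomes x 100 kb, M=3, strong
    compositional bias, low coverage noise, no spurious edges."""
    return generate_community(CommunitySpec(seed=1))


@pytest.fixture(scope="session")
def mini_community():
    """A small community for fast training tests: 4 genomes x 40 kb."""
    return generate_community(
        CommunitySpec(n_genomes=4, genome_length=40_000, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
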