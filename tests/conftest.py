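import numpy as np
import pytest

from catsite import synthetic_fixtures as synth


@pytest.fixture(scope="session")
def toy_protein():
    """One deterministic toy structure with two pockets."""
    spec = synth.FixtureSpec(seed=7, n_residues=40, n_pockets=2,
                             ligand_size=10, structure_id="toyfix")
    return synth.make_toy_protein(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
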