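import numpy as np
import pytest

from caifp import BindingSite, FixtureSpec, GeometryConfig, ResidueKey, make_training_set


@pytest.fixture
def geo():
    return GeometryConfig()


@pytest.fixture
def site44():
    """A 44-residue binding site (the carbonic anhydrase II site size)."""
    return BindingSite(residues=[ResidueKey("A", i + 1, "", "ALA") for i in range(44)])


@pytest.fixture
def small_training_set():
    spec = FixtureSpec(
        seed=11, site_size=6,
        planted_interactions=[
            [(0, "hbond_acceptor"), (2, "hydrophobic"), (3, "pi_pi")],
            [(0, "hbond_acceptor"), (4, "salt_bridge")],
            [(0, "hbond_acceptor"), (3, "pi_pi"), (3, "t_stack")],
            [(2, "hydrophobic"), (4, "salt_bridge")],
            [(5, "hbond_donor"), (3, "cation_pi")],
        ])
    return make_training_set(spec)


def assert_profiles_equal(profile, oracle_flags):
    """Compare a detector InteractionProfile with the oracle's dict output."""
    assert set(profile.residue_flags) == set(oracle_flags)
    for key, flags in oracle_flags.items():
        got = profile.residue_flags[key].tolist()
        assert got == list(flags), f"{key}: detector {got} != oracle {list(flags)}"
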