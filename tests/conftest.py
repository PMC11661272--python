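import numpy as np
import pytest

from protembed.featurize import build_atom_graph, build_residue_graph
from protembed.synthetic import generate_atomic_environment, generate_mini_protein


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def mini_protein():
    """A 15-residue mixed helix/coil chain (session-cached, read-only)."""
    s, seq = generate_mini_protein(15, 0.6, np.random.default_rng(7))
    return s, seq


@pytest.fixture(scope="session")
def residue_graph(mini_protein):
    return build_residue_graph(mini_protein[0])


@pytest.fixture(scope="session")
def charged_environment():
    s, target = generate_atomic_environment(np.random.default_rng(3), n_surround=30)
    return s, target


@pytest.fixture(scope="session")
def atom_graph(charged_environment):
    return build_atom_graph(*charged_environment)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def rigid_transform(structure, R, t):
    """Apply x -> R x + t to every atom in place."""
    for atom in structure.atoms:
        atom.position = R @ atom.position + np.asarray(t, dtype=float)
    return structure
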