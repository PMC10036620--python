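import numpy as np
import pytest

from gpcrdyn.traj_model import ATOMIC_MASSES, AtomRecord, Topology, Trajectory


def make_topology(atom_specs):
    """atom_specs: iterable of (name, element, resname, resid, chain)."""
    atoms = [
        AtomRecord(i + 1, name, element, resname, resid, chain, ATOMIC_MASSES[element])
        for i, (name, element, resname, resid, chain) in enumerate(atom_specs)
    ]
    return Topology(atoms)


def random_trajectory(rng, n_frames=3, n_atoms=5):
    specs = [("CA", "C", "ALA", i + 1, "A") for i in range(n_atoms)]
    coords = rng.uniform(-20, 20, size=(n_frames, n_atoms, 3))
    return Trajectory(make_topology(specs), coords)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-30, 30, size=3)
    return R, t


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
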