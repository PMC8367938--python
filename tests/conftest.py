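import numpy as np
import pytest

from eemcc.core import Atom, Molecule, Topology, Trajectory


def make_trajectory(topology, coordinates, forces, times=None, box_length=1e3):
    coordinates = np.asarray(coordinates, float)
    forces = np.asarray(forces, float)
    n = coordinates.shape[0]
    if times is None:
        times = np.arange(n, dtype=float)
    box = np.tile(np.eye(3) * box_length, (n, 1, 1))
    return Trajectory(topology, coordinates, forces, times, box)


@pytest.fixture
def water_topology():
    atoms = [Atom(0, "O", "O", 15.999), Atom(1, "H1", "H", 1.008), Atom(2, "H2", "H", 1.008)]
    return Topology(atoms, [(0, 1), (0, 2)],
                    [Molecule("SOL_1", "water", (0, 1, 2), 1)])


@pytest.fixture
def water_coords():
    return np.array([[0.0, 0.0, 0.0], [0.7572, 0.0, -0.5865], [-0.7572, 0.0, -0.5865]])


@pytest.fixture
def methanol_topology():
    """CH3-OH: one non-linear united atom (C, 3H) and one linear (O, 1H)."""
    atoms = [
        Atom(0, "C", "C", 12.011), Atom(1, "H1", "H", 1.008), Atom(2, "H2", "H", 1.008),
        Atom(3, "H3", "H", 1.008), Atom(4, "O", "O", 15.999), Atom(5, "HO", "H", 1.008),
    ]
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4), (4, 5)]
    return Topology(atoms, bonds, [Molecule("MOH", "guest", tuple(range(6)), 1)])


@pytest.fixture
def butane_like_topology():
    """Four bare heavy atoms in a chain: 4 point united atoms, one
    rotatable heavy-atom dihedral."""
    atoms = [Atom(i, f"C{i}", "C", 12.011) for i in range(4)]
    bonds = [(0, 1), (1, 2), (2, 3)]
    return Topology(atoms, bonds, [Molecule("BUT", "guest", (0, 1, 2, 3), 1)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
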