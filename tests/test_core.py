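import numpy as np
import pytest

from eemcc.core import (
    Atom,
    Config,
    ForcesRequiredError,
    Molecule,
    Topology,
    define_united_atoms,
    principal_frame,
    read_topology,
    read_trajectory,
    write_topology,
    write_trajectory,
    united_atom_axes,
)
from eemcc.synthetic import HarmonicSpec, harmonic_trajectory

from conftest import make_trajectory


class TestTopology:
    def test_atom_in_two_molecules_rejected(self):
        atoms = [Atom(0, "C", "C", 12.0), Atom(1, "C", "C", 12.0)]
        with pytest.raises(ValueError, match="belongs to both"):
            Topology(atoms, [], [Molecule("A", "other", (0, 1)),
                                 Molecule("B", "other", (1,))])

    def test_cross_molecule_bond_rejected(self):
        atoms = [Atom(0, "C", "C", 12.0), Atom(1, "C", "C", 12.0)]
        with pytest.raises(ValueError, match="crosses molecules"):
            Topology(atoms, [(0, 1)], [Molecule("A", "other", (0,)),
                                       Molecule("B", "other", (1,))])

    def test_symmetry_number_must_be_positive_integer(self):
        atoms = [Atom(0, "C", "C", 12.0)]
        with pytest.raises(ValueError, match="symmetry"):
            Topology(atoms, [], [Molecule("A", "other", (0,), 0)])


class TestUnitedAtoms:
    def test_rotational_dof_rules(self, water_topology, methanol_topology):
        # >1 H: non-linear (3); one H: linear (2); no H: point (0)
        (ua_w,) = define_united_atoms(water_topology, "SOL_1")
        assert ua_w.rotational_dof == 3

        ua_c, ua_o = define_united_atoms(methanol_topology, "MOH")
        assert ua_c.heavy == 0 and ua_c.rotational_dof == 3
        assert ua_o.heavy == 4 and ua_o.rotational_dof == 2

        atoms = [Atom(0, "C", "C", 12.0), Atom(1, "O", "O", 16.0)]
        top = Topology(atoms, [(0, 1)], [Molecule("CO", "other", (0, 1))])
        ua_c, ua_o = define_united_atoms(top, "CO")
        assert ua_o.rotational_dof == 0

    def test_partition_covers_molecule_exactly_once(self, methanol_topology):
        uas = define_united_atoms(methanol_topology, "MOH")
        covered = [i for ua in uas for i in ua.atom_indices]
        assert sorted(covered) == list(range(6))

    def test_bridging_hydrogen_rejected(self):
        atoms = [Atom(0, "C", "C", 12.0), Atom(1, "H", "H", 1.0), Atom(2, "C", "C", 12.0)]
        top = Topology(atoms, [(0, 1), (1, 2)], [Molecule("X", "other", (0, 1, 2))])
        with pytest.raises(ValueError, match="2 heavy atoms"):
            define_united_atoms(top, "X")

    def test_free_hydrogen_rejected(self):
        atoms = [Atom(0, "C", "C", 12.0), Atom(1, "H", "H", 1.0)]
        top = Topology(atoms, [], [Molecule("X", "other", (0, 1))])
        with pytest.raises(ValueError, match="free hydrogen"):
            define_united_atoms(top, "X")


class TestPrincipalFrame:
    def test_center_of_mass(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0]])
        rf = principal_frame(coords, np.ones(3))
        assert np.allclose(rf.origin, [0, 1 / 3, 0])

    def test_axes_orthonormal_right_handed(self, rng):
        coords = rng.normal(size=(10, 3))
        rf = principal_frame(coords, rng.uniform(1, 16, size=10))
        assert np.allclose(rf.axes @ rf.axes.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(rf.axes) == pytest.approx(1.0)

    def test_moments_invariant_under_rigid_rotation(self, rng):
        coords = rng.normal(size=(8, 3))
        masses = rng.uniform(1, 16, size=8)
        ref = principal_frame(coords, masses).moments
        for _ in range(5):
            q = rng.normal(size=(3, 3))
            rot, _ = np.linalg.qr(q)
            rotated = coords @ rot.T + rng.normal(size=3)
            mom = principal_frame(rotated, masses).moments
            assert np.allclose(mom, ref, rtol=1e-10)

    def test_inertia_tensor_diagonal_in_returned_axes(self, rng):
        coords = rng.normal(size=(10, 3)) * 3
        masses = rng.uniform(1, 16, size=10)
        rf = principal_frame(coords, masses)
        rel = (coords - rf.origin) @ rf.axes.T
        inertia = np.einsum("a,ai,aj->ij", masses, rel, rel)
        inertia = np.trace(inertia) * np.eye(3) - inertia
        off = inertia - np.diag(np.diagonal(inertia))
        assert np.abs(off).max() < 1e-10 * np.trace(inertia)
        assert np.allclose(np.diagonal(inertia), rf.moments)

    def test_collinear_geometry_rejected(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="linear"):
            principal_frame(coords, np.ones(3))


class TestUnitedAtomAxes:
    def test_z_axis_along_single_bond(self, water_coords):
        from eemcc.core import UnitedAtom
        ua = UnitedAtom(0, (1,))
        axes = united_atom_axes(water_coords, ua)
        bond = water_coords[1] - water_coords[0]
        assert np.allclose(axes[2], bond / np.linalg.norm(bond))
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-12)

    def test_hydrogen_free_unit_uses_fallback(self):
        from eemcc.core import UnitedAtom
        ua = UnitedAtom(0, ())
        fb = np.eye(3)[::-1]
        assert np.array_equal(united_atom_axes(np.zeros((1, 3)), ua, fallback=fb), fb)


class TestIO:
    def test_round_trip_preserves_arrays(self, tmp_path):
        traj = harmonic_trajectory(HarmonicSpec(n_frames=5, seed=7))
        write_topology(traj.topology, tmp_path / "top.json")
        write_trajectory(traj, tmp_path / "trj.npz")
        top = read_topology(tmp_path / "top.json")
        back = read_trajectory(tmp_path / "trj.npz", top)
        assert back.n_frames == 5 and top.n_atoms == 3
        assert np.array_equal(back.coordinates, traj.coordinates)
        assert np.array_equal(back.forces, traj.forces)
        assert [a.mass for a in top.atoms] == [a.mass for a in traj.topology.atoms]

    def test_trr_with_forces_round_trip(self, tmp_path):
        import MDAnalysis as mda
        from eemcc.core import load_system
        traj = harmonic_trajectory(HarmonicSpec(n_frames=4, seed=1))
        u = mda.Universe.empty(3, trajectory=True, forces=True)
        u.add_TopologyAttr("names", ["O", "H1", "H2"])
        u.add_TopologyAttr("masses", [15.999, 1.008, 1.008])
        with mda.Writer(str(tmp_path / "t.trr"), 3) as w:
            for f in range(4):
                u.atoms.positions = traj.coordinates[f]
                u.atoms.forces = traj.forces[f]
                u.dimensions = [30, 30, 30, 90, 90, 90]
                u.trajectory.ts.time = float(f)
                w.write(u.atoms)
        write_topology(traj.topology, tmp_path / "t.json")
        back = load_system(tmp_path / "t.json", tmp_path / "t.trr")
        assert back.n_frames == 4
        # TRR stores single precision
        assert np.allclose(back.coordinates, traj.coordinates, atol=1e-4)
        assert np.allclose(back.forces, traj.forces, atol=1e-3)

    def test_trr_without_forces_rejected(self, tmp_path):
        import MDAnalysis as mda
        from eemcc.core import load_system
        traj = harmonic_trajectory(HarmonicSpec(n_frames=2, seed=1))
        u = mda.Universe.empty(3, trajectory=True)
        u.add_TopologyAttr("masses", [15.999, 1.008, 1.008])
        with mda.Writer(str(tmp_path / "nf.trr"), 3) as w:
            for f in range(2):
                u.atoms.positions = traj.coordinates[f]
                u.dimensions = [30, 30, 30, 90, 90, 90]
                w.write(u.atoms)
        write_topology(traj.topology, tmp_path / "t.json")
        with pytest.raises(ForcesRequiredError, match="forces required"):
            load_system(tmp_path / "t.json", tmp_path / "nf.trr")

    def test_trajectory_without_forces_rejected(self, tmp_path, water_topology):
        np.savez(tmp_path / "bad.npz", coordinates=np.zeros((2, 3, 3)))
        with pytest.raises(ForcesRequiredError, match="forces required"):
            read_trajectory(tmp_path / "bad.npz", water_topology)

    def test_atom_count_mismatch_names_both_counts(self, tmp_path, water_topology):
        np.savez(tmp_path / "bad.npz", coordinates=np.zeros((2, 5, 3)),
                 forces=np.zeros((2, 5, 3)))
        with pytest.raises(ValueError, match="5 atoms.*3"):
            read_trajectory(tmp_path / "bad.npz", water_topology)


class TestConfig:
    def test_defaults_and_validation(self):
        cfg = Config()
        assert cfg.temperature == 300.0
        assert cfg.x_aq_standard == pytest.approx(1 / 55.5)
        with pytest.raises(ValueError):
            Config(temperature=-1)
        with pytest.raises(ValueError):
            Config(halving="thirds")

    def test_from_yaml(self, tmp_path):
        (tmp_path / "c.yaml").write_text(
            "temperature: 298\nstride: 2\n"
            "molecules:\n- {name: CB8, role: host, symmetry_number: 16}\n"
            "- {name: G1, role: guest}\nreplicates: [r1, r2, r3]\n"
        )
        cfg = Config.from_yaml(tmp_path / "c.yaml")
        assert cfg.temperature == 298 and cfg.stride == 2
        assert cfg.roles == {"CB8": "host", "G1": "guest"}
        assert cfg.symmetry_numbers == {"CB8": 16}
        assert cfg.replicates == ("r1", "r2", "r3")
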