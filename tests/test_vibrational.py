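import numpy as np
import pytest

from eemcc.constants import AMU_TO_KG, FORCE_CONSTANT_TO_SI, H, INERTIA_TO_SI, KB, KJMOL_TO_J, R
from eemcc.core import Atom, Config, Molecule, Topology, principal_frame
from eemcc.synthetic import HarmonicSpec, harmonic_trajectory
from eemcc.vibrational import (
    frequencies_from_eigenvalues,
    molecule_vibrational_entropy,
    qho_entropy,
    weighted_force_covariance,
    weighted_torque_covariance,
)

from conftest import make_trajectory

T = 300.0
RAW = Config(halving="raw")
HALVED = Config(halving="halved")


def _static_water_traj(water_topology, water_coords, forces, n_frames=4):
    coords = np.tile(water_coords, (n_frames, 1, 1))
    f = np.tile(np.asarray(forces, float), (n_frames, 1, 1))
    return make_trajectory(water_topology, coords, f)


class TestForceCovariance:
    def test_constant_forces_give_zero_matrix(self, water_topology, water_coords):
        traj = _static_water_traj(water_topology, water_coords,
                                  [[1.0, 2.0, 3.0]] * 3)
        cov = weighted_force_covariance(traj, "SOL_1", "molecule", RAW)
        assert np.allclose(cov.matrix, 0.0)

    def test_single_frame_rejected(self, water_topology, water_coords):
        traj = _static_water_traj(water_topology, water_coords,
                                  np.zeros((3, 3)), n_frames=1)
        with pytest.raises(ValueError, match="two frames"):
            weighted_force_covariance(traj, "SOL_1", "molecule", RAW)

    def test_doubling_masses_halves_entries(self, water_coords, rng):
        def top(scale):
            atoms = [Atom(0, "O", "O", 15.999 * scale),
                     Atom(1, "H1", "H", 1.008 * scale),
                     Atom(2, "H2", "H", 1.008 * scale)]
            return Topology(atoms, [(0, 1), (0, 2)],
                            [Molecule("SOL_1", "water", (0, 1, 2), 1)])

        coords = np.tile(water_coords, (50, 1, 1))
        forces = rng.normal(size=(50, 3, 3))
        c1 = weighted_force_covariance(make_trajectory(top(1), coords, forces),
                                       "SOL_1", "molecule", RAW)
        c2 = weighted_force_covariance(make_trajectory(top(2), coords, forces),
                                       "SOL_1", "molecule", RAW)
        assert np.allclose(c2.matrix, c1.matrix / 2.0)

    def test_harmonic_diagonal_matches_k_kbt_over_4m(self):
        # halving forces divides the variance by 4: diag = k*kB*T/(4M)
        spec = HarmonicSpec(k_trans=(100.0, 300.0, 900.0), n_frames=20_000, seed=11)
        traj = harmonic_trajectory(spec)
        cov = weighted_force_covariance(traj, "SOL_1", "molecule", HALVED)
        m_tot = sum(spec.masses) * AMU_TO_KG
        expected = np.sort(np.array(spec.k_trans) * FORCE_CONSTANT_TO_SI
                           * KB * T / (4.0 * m_tot))
        measured = np.sort(np.linalg.eigvalsh(cov.matrix))
        assert np.allclose(measured, expected, rtol=0.05)

    def test_lab_frame_rotation_leaves_eigenvalues(self, rng):
        spec = HarmonicSpec(n_frames=400, seed=5)
        traj = harmonic_trajectory(spec)
        rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = make_trajectory(traj.topology,
                                  traj.coordinates @ rot.T,
                                  traj.forces @ rot.T)
        for fn in (weighted_force_covariance, weighted_torque_covariance):
            e1 = np.linalg.eigvalsh(fn(traj, "SOL_1", "molecule", RAW).matrix)
            e2 = np.linalg.eigvalsh(fn(rotated, "SOL_1", "molecule", RAW).matrix)
            assert np.allclose(e1, e2, rtol=1e-8)


class TestTorqueCovariance:
    def test_constant_torques_give_zero_matrix(self, water_topology, water_coords):
        traj = _static_water_traj(water_topology, water_coords,
                                  [[0, 1.0, 0], [0, -0.5, 0], [0, -0.5, 0]])
        cov = weighted_torque_covariance(traj, "SOL_1", "molecule", RAW)
        assert np.abs(cov.matrix).max() < 1e-10

    def test_harmonic_rotor_diagonal_matches_kappa_kbt_over_4i(self):
        spec = HarmonicSpec(kappa_rot=(20.0, 60.0, 180.0), n_frames=20_000, seed=12)
        traj = harmonic_trajectory(spec)
        cov = weighted_torque_covariance(traj, "SOL_1", "molecule", HALVED)
        geom = traj.coordinates[0]
        i_si = principal_frame(geom, np.array(spec.masses)).moments * INERTIA_TO_SI
        expected = np.sort(np.array(spec.kappa_rot) * KJMOL_TO_J * KB * T / (4.0 * i_si))
        measured = np.sort(np.linalg.eigvalsh(cov.matrix))
        assert np.allclose(measured, expected, rtol=0.05)

    def test_point_united_atom_contributes_no_rows(self, rng):
        # CH2 group (3 rotational dof) + bare O (0 dof) -> 3x3 matrix
        atoms = [Atom(0, "C", "C", 12.011), Atom(1, "H1", "H", 1.008),
                 Atom(2, "H2", "H", 1.008), Atom(3, "O", "O", 15.999)]
        top = Topology(atoms, [(0, 1), (0, 2), (0, 3)],
                       [Molecule("X", "guest", (0, 1, 2, 3))])
        coords = np.tile(np.array([[0.0, 0, 0], [0.9, 0.3, 0],
                                   [-0.9, 0.3, 0], [0, -1.2, 0.1]]), (20, 1, 1))
        traj = make_trajectory(top, coords, rng.normal(size=(20, 4, 3)))
        cov = weighted_torque_covariance(traj, "X", "united_atom", RAW)
        assert cov.matrix.shape == (3, 3)

    def test_explicit_point_unit_rejected(self, rng):
        from eemcc.core import UnitedAtom, define_united_atoms
        atoms = [Atom(0, "C", "C", 12.011), Atom(1, "O", "O", 15.999)]
        top = Topology(atoms, [(0, 1)], [Molecule("CO", "other", (0, 1))])
        coords = np.tile(np.array([[0.0, 0, 0], [1.2, 0, 0]]), (5, 1, 1))
        traj = make_trajectory(top, coords, rng.normal(size=(5, 2, 3)))
        with pytest.raises(ValueError, match="no rotational"):
            weighted_torque_covariance(traj, "CO", "united_atom", RAW,
                                       units=[UnitedAtom(0, ()), UnitedAtom(1, ())])


class TestSpectrum:
    def test_eigenvalue_to_frequency_inversion(self):
        lam = 4 * np.pi**2 * KB * T * 1.0**2  # nu = 1 Hz
        spec = frequencies_from_eigenvalues(np.diag([lam]), T)
        assert spec.frequencies[0] == pytest.approx(1.0)
        spec4 = frequencies_from_eigenvalues(np.diag([4 * lam]), T)
        assert spec4.frequencies[0] == pytest.approx(2.0)

    def test_degenerate_covariance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            frequencies_from_eigenvalues(np.zeros((3, 3)), T)

    def test_near_null_modes_dropped(self):
        lam = 4 * np.pi**2 * KB * T
        spec = frequencies_from_eigenvalues(np.diag([lam, lam * 1e-15]), T)
        assert spec.n_vib == 1

    def test_ua_translational_mode_count_is_3n_minus_6(self, butane_like_topology, rng):
        n_frames, n_at = 60, 4
        coords = np.tile(np.array([[0.0, 0, 0], [1.5, 0.3, 0],
                                   [3.0, 0, 0.4], [4.5, 0.5, 0.2]]), (n_frames, 1, 1))
        traj = make_trajectory(butane_like_topology, coords,
                               rng.normal(size=(n_frames, n_at, 3)))
        cov = weighted_force_covariance(traj, "BUT", "united_atom", RAW)
        spec = frequencies_from_eigenvalues(cov, T)
        assert spec.n_vib == 3 * n_at
        kept = np.sort(spec.frequencies)[6:]
        assert kept.size == 3 * n_at - 6


class TestQhoEntropy:
    def test_mode_at_thermal_frequency(self):
        nu = KB * T / H  # h nu = kB T
        assert qho_entropy(np.array([nu]), T) == pytest.approx(8.65, abs=0.01)

    def test_frozen_mode_limit(self):
        nu = 1e3 * KB * T / H
        assert qho_entropy(np.array([nu]), T) == pytest.approx(0.0, abs=1e-12)

    def test_additivity_over_identical_modes(self):
        nu = KB * T / H
        single = qho_entropy(np.array([nu]), T)
        assert qho_entropy(np.array([nu, nu]), T) == pytest.approx(2 * single)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            qho_entropy(np.array([-1.0]), T)

    @pytest.mark.parametrize("nu", np.geomspace(1e11, 1e14, 6))
    def test_monotonic_decreasing_in_frequency_increasing_in_temperature(self, nu):
        assert qho_entropy([nu], T) > qho_entropy([nu * 1.3], T)
        assert qho_entropy([nu], T * 1.2) > qho_entropy([nu], T)

    def test_drop_lowest_removes_softest_modes(self):
        nus = np.array([1e12, 2e12, 4e12])
        kept = qho_entropy(nus, T, drop_lowest=1)
        assert kept == pytest.approx(qho_entropy(nus[1:], T))


class TestHalvingConvention:
    def test_halved_entropy_equals_raw_at_half_frequency(self):
        spec = HarmonicSpec(n_frames=4000, seed=3)
        traj = harmonic_trajectory(spec)
        raw = frequencies_from_eigenvalues(
            weighted_force_covariance(traj, "SOL_1", "molecule", RAW).matrix, T)
        halved = frequencies_from_eigenvalues(
            weighted_force_covariance(traj, "SOL_1", "molecule", HALVED).matrix, T)
        assert np.allclose(halved.frequencies, raw.frequencies / 2.0, rtol=1e-10)
        assert qho_entropy(halved, T) == pytest.approx(
            qho_entropy(raw.frequencies / 2.0, T))


def test_molecule_entropy_summary_has_all_four_terms():
    traj = harmonic_trajectory(HarmonicSpec(n_frames=300, seed=9))
    out = molecule_vibrational_entropy(traj, "SOL_1", RAW)
    assert set(out) == {"M_transvib", "M_rovib", "UA_transvib", "UA_rovib"}
    # water is a single united atom: no UA translation survives the
    # six-mode filter, but its three rotational dof remain
    assert out["UA_transvib"] == 0.0
    assert out["UA_rovib"] > 0.0
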