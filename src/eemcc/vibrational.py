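"""Vibrational entropy from force/torque covariance matrices.

Two covariance matrices are built per hierarchy level: one from
mass-weighted net forces (translation, "transvibrational" entropy) and
one from moment-of-inertia-weighted torques (rotation, "rovibrational").
Eigenvalues lambda_i of each matrix map to effective harmonic
frequencies

    nu_i = (1/2 pi) sqrt(lambda_i / (k_B T))

and the entropy is the quantum-harmonic-oscillator sum over modes. In
the mean-field picture of a unit vibrating among weakly correlated
neighbours, instantaneous forces and torques are halved before the
covariance is taken (configurable: ``halving='halved'|'raw'``).

At the molecule level each motion gives a 3x3 matrix (6 modes total).
At the united-atom level translation spans 3N coordinates of which the
six lowest-frequency modes are discarded (they duplicate the rigid-body
molecule modes, leaving 3N-6), and rotation spans the summed rotational
degrees of freedom of the united atoms (3 per non-linear UA, 2 per
single-hydrogen UA, 0 for bare heavy atoms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import AMU_TO_KG, FORCE_TO_SI, H, INERTIA_TO_SI, KB, R, TORQUE_TO_SI
from .core import (
    Config,
    Trajectory,
    UnitedAtom,
    define_united_atoms,
    principal_frame,
    united_atom_axes,
    united_atom_moments,
)

logger = logging.getLogger(__name__)

#: relative floor under which covariance eigenvalues are treated as null
EIGENVALUE_FLOOR = 1e-12

__all__ = [
    "CovarianceMatrix",
    "VibrationalSpectrum",
    "weighted_force_covariance",
    "weighted_torque_covariance",
    "frequencies_from_eigenvalues",
    "qho_entropy",
    "molecule_vibrational_entropy",
]


@dataclass(frozen=True)
class CovarianceMatrix:
    matrix: np.ndarray  # symmetric, SI (per-particle) weighted units
    level: str  # molecule | united_atom
    motion: str  # translation | rotation

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8 * (np.abs(m).max() + 1e-300)):
            raise ValueError("covariance matrix must be symmetric")


@dataclass(frozen=True)
class VibrationalSpectrum:
    eigenvalues: np.ndarray  # ascending, weighted-variance units
    frequencies: np.ndarray  # s^-1, ascending
    n_vib: int


def _covariance(samples: np.ndarray) -> np.ndarray:
    if samples.shape[0] < 2:
        raise ValueError("covariance needs at least two frames")
    x = samples - samples.mean(axis=0)
    return x.T @ x / (samples.shape[0] - 1)


def _halving_factor(config: Config | None) -> float:
    halving = config.halving if config is not None else "halved"
    return 0.5 if halving == "halved" else 1.0


def _resolve_frame_atoms(traj: Trajectory, config: Config | None):
    """Atom set defining the orientation frame for united-atom analysis:
    the molecule itself, or the whole host-guest complex when configured
    (bound-host analysis needs a frame aligned with the guest)."""
    if config is not None and config.frame_source == "complex":
        idx = []
        for mol in traj.topology.molecules:
            if mol.role in ("host", "guest"):
                idx.extend(mol.atom_indices)
        if idx:
            return np.array(idx)
    return None


def weighted_force_covariance(trajectory: Trajectory, molecule: str,
                              level: str = "molecule",
                              config: Config | None = None,
                              units: list[UnitedAtom] | None = None) -> CovarianceMatrix:
    """Covariance of mean-field-halved, mass-weighted net forces.

    level='molecule': one 3-vector per frame — the net force on the whole
    molecule in its principal-axis frame, weighted by 1/sqrt(M).
    level='united_atom': concatenated 3-vectors of every united atom in
    its local bond frame, each weighted by 1/sqrt(m_UA), giving a 3N x 3N
    matrix.
    """
    top = trajectory.topology
    mol = top.molecule(molecule)
    masses = top.masses
    half = _halving_factor(config)
    idx = np.array(mol.atom_indices)
    if masses[idx].sum() <= 0:
        raise ValueError("zero-mass unit")

    if level == "molecule":
        m_si = masses[idx].sum() * AMU_TO_KG
        rows = []
        for f in range(trajectory.n_frames):
            rf = principal_frame(trajectory.coordinates[f, idx], masses[idx])
            net = trajectory.forces[f, idx].sum(axis=0) * FORCE_TO_SI * half
            rows.append(rf.to_local(net) / np.sqrt(m_si))
        return CovarianceMatrix(_covariance(np.array(rows)), level, "translation")

    if level != "united_atom":
        raise ValueError("level must be 'molecule' or 'united_atom'")

    uas = units if units is not None else define_united_atoms(top, mol)
    frame_atoms = _resolve_frame_atoms(trajectory, config)
    rows = []
    for f in range(trajectory.n_frames):
        coords = trajectory.coordinates[f]
        shared_axes = None
        if frame_atoms is not None:
            shared_axes = principal_frame(coords[frame_atoms], masses[frame_atoms]).axes
        vec = []
        for ua in uas:
            ua_idx = list(ua.atom_indices)
            m_si = masses[ua_idx].sum() * AMU_TO_KG
            if m_si <= 0:
                raise ValueError("zero-mass united atom")
            axes = shared_axes if shared_axes is not None else united_atom_axes(coords, ua)
            net = trajectory.forces[f, ua_idx].sum(axis=0) * FORCE_TO_SI * half
            vec.append(axes @ net / np.sqrt(m_si))
        rows.append(np.concatenate(vec))
    return CovarianceMatrix(_covariance(np.array(rows)), level, "translation")


def weighted_torque_covariance(trajectory: Trajectory, molecule: str,
                               level: str = "molecule",
                               config: Config | None = None,
                               units: list[UnitedAtom] | None = None) -> CovarianceMatrix:
    """Covariance of mean-field-halved, inertia-weighted torques.

    Torques are taken about each unit's origin (center of mass for a
    molecule, heavy atom for a united atom), expressed along the unit's
    axes and weighted per axis by 1/sqrt(I_a). United atoms without
    rotational degrees of freedom contribute no rows; passing one
    explicitly in ``units`` is an error.
    """
    top = trajectory.topology
    mol = top.molecule(molecule)
    masses = top.masses
    half = _halving_factor(config)

    if level == "molecule":
        idx = np.array(mol.atom_indices)
        rows = []
        for f in range(trajectory.n_frames):
            coords = trajectory.coordinates[f, idx]
            rf = principal_frame(coords, masses[idx])
            rel = coords - rf.origin
            tau = np.cross(rel, trajectory.forces[f, idx]).sum(axis=0) * TORQUE_TO_SI * half
            i_si = rf.moments * INERTIA_TO_SI
            if np.any(i_si < 1e-12 * i_si.max()):
                raise ValueError("vanishing principal moment: linear unit")
            rows.append(rf.to_local(tau) / np.sqrt(i_si))
        return CovarianceMatrix(_covariance(np.array(rows)), level, "rotation")

    if level != "united_atom":
        raise ValueError("level must be 'molecule' or 'united_atom'")

    uas = units if units is not None else define_united_atoms(top, mol)
    if units is not None:
        for ua in uas:
            if ua.rotational_dof == 0:
                raise ValueError(f"united atom {ua.heavy} has no rotational degrees of freedom")
    uas = [ua for ua in uas if ua.rotational_dof > 0]
    if not uas:
        raise ValueError("no united atoms with rotational degrees of freedom")

    rows = []
    for f in range(trajectory.n_frames):
        coords = trajectory.coordinates[f]
        vec = []
        for ua in uas:
            axes = united_atom_axes(coords, ua)
            ua_idx = list(ua.atom_indices)
            rel = coords[ua_idx] - coords[ua.heavy]
            tau = np.cross(rel, trajectory.forces[f, ua_idx]).sum(axis=0) * TORQUE_TO_SI * half
            tau_local = axes @ tau
            moments = united_atom_moments(coords, masses, ua, axes) * INERTIA_TO_SI
            # dof=2 (one H): rotation about the bond axis (local z) carries no
            # inertia; only the two perpendicular axes enter.
            use = (0, 1) if ua.rotational_dof == 2 else (0, 1, 2)
            for a in use:
                if moments[a] <= 0:
                    raise ValueError(
                        f"vanishing moment of inertia on used axis {a} of united atom {ua.heavy}"
                    )
                vec.append(tau_local[a] / np.sqrt(moments[a]))
        rows.append(np.array(vec))
    return CovarianceMatrix(_covariance(np.array(rows)), level, "rotation")


def frequencies_from_eigenvalues(matrix: CovarianceMatrix | np.ndarray,
                                 temperature: float) -> VibrationalSpectrum:
    """Eigen-decompose a weighted covariance matrix and map eigenvalues to
    harmonic frequencies, nu = sqrt(lambda/(k_B T)) / 2 pi.

    Eigenvalues below ``EIGENVALUE_FLOOR`` relative to the largest are
    numerical nulls and are dropped with a warning.
    """
    m = matrix.matrix if isinstance(matrix, CovarianceMatrix) else np.asarray(matrix)
    if not np.allclose(m, m.T, atol=1e-8 * (np.abs(m).max() + 1e-300)):
        raise ValueError("matrix must be symmetric")
    lam = np.linalg.eigvalsh(m)
    top = lam.max(initial=0.0)
    if top <= 0:
        raise ValueError("degenerate covariance: no positive eigenvalues")
    keep = lam >= EIGENVALUE_FLOOR * top
    if not keep.all():
        logger.warning("dropping %d near-null covariance eigenvalues", (~keep).sum())
    lam = lam[keep]
    if lam.size == 0:
        raise ValueError("degenerate covariance")
    freqs = np.sqrt(lam / (KB * temperature)) / (2.0 * np.pi)
    return VibrationalSpectrum(lam, freqs, int(lam.size))


def qho_entropy(spectrum: VibrationalSpectrum | np.ndarray, temperature: float,
                drop_lowest: int = 0) -> float:
    """Quantum-harmonic-oscillator entropy (J K^-1 mol^-1) of a mode set.

        S = R * sum_i [ x_i/(e^{x_i}-1) - ln(1-e^{-x_i}) ],  x = h nu / k_B T

    ``drop_lowest`` removes that many lowest-frequency modes first (six
    for united-atom translation, which duplicates the molecule-level
    rigid-body modes).
    """
    freqs = spectrum.frequencies if isinstance(spectrum, VibrationalSpectrum) \
        else np.asarray(spectrum, float)
    if freqs.size == 0:
        raise ValueError("empty spectrum")
    if np.any(freqs < 0):
        raise ValueError("negative frequency")
    if drop_lowest > freqs.size:
        drop_lowest = freqs.size
    freqs = np.sort(freqs)[drop_lowest:]
    if freqs.size == 0:
        return 0.0
    x = H * freqs / (KB * temperature)
    with np.errstate(over="ignore"):
        term = np.where(x < 700, x / np.expm1(np.minimum(x, 700)), 0.0)
    term = term - np.log1p(-np.exp(-x))
    return float(R * term.sum())


def molecule_vibrational_entropy(trajectory: Trajectory, molecule: str,
                                 config: Config | None = None) -> dict[str, float]:
    """All four vibrational terms of one molecule (J K^-1 mol^-1).

    Returns ``{'M_transvib', 'M_rovib', 'UA_transvib', 'UA_rovib'}``.
    United-atom translation drops its six lowest modes (3N-6 kept); a
    single-united-atom molecule (e.g. water) keeps none and its UA
    translation is zero.
    """
    temp = config.temperature if config else 300.0
    out = {}
    cov = weighted_force_covariance(trajectory, molecule, "molecule", config)
    out["M_transvib"] = qho_entropy(frequencies_from_eigenvalues(cov, temp), temp)
    cov = weighted_torque_covariance(trajectory, molecule, "molecule", config)
    out["M_rovib"] = qho_entropy(frequencies_from_eigenvalues(cov, temp), temp)

    uas = define_united_atoms(trajectory.topology, molecule)
    cov = weighted_force_covariance(trajectory, molecule, "united_atom", config, units=uas)
    spec = frequencies_from_eigenvalues(cov, temp)
    out["UA_transvib"] = qho_entropy(spec, temp, drop_lowest=6) if spec.n_vib > 6 else 0.0

    if any(ua.rotational_dof > 0 for ua in uas):
        cov = weighted_torque_covariance(trajectory, molecule, "united_atom", config)
        out["UA_rovib"] = qho_entropy(frequencies_from_eigenvalues(cov, temp), temp)
    else:
        out["UA_rovib"] = 0.0
    return out
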