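"""Synthetic fixtures with analytic ground truth.

Every generator here produces inputs whose exact answer is known in
closed form, so the entropy pipeline can be validated end-to-end
without running MD:

* :func:`harmonic_trajectory` — a rigid triatomic unit in a harmonic
  translational trap with harmonic libration about its principal axes,
  sampled i.i.d. from the exact Boltzmann distribution (positions
  ~ N(0, k_B T/k), forces F = -k x). Covariance-based entropies must
  recover the analytic quantum-harmonic-oscillator value.
* :func:`dihedral_fixture` — a wrapped mixture of well-separated
  dihedral wells with known occupation weights; the conformational
  entropy of the series is -k_B sum w ln w.
* :func:`shell_fixture` — a solute with contact waters and farther
  waters that the contacts block by construction; the first shell under
  the relative-angular-distance criterion is exactly the contact set.

Sampling is i.i.d. rather than dynamical: the correlation method uses
only static covariances and histograms, so time correlation is not
needed for these ground truths. All generators are deterministic under
a fixed seed, which is recorded in the emitted metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import (
    AMU_TO_KG,
    ANGSTROM_TO_M,
    FORCE_CONSTANT_TO_SI,
    FORCE_TO_SI,
    INERTIA_TO_SI,
    KB,
    KJMOL_TO_J,
    R,
)
from .core import Atom, Molecule, Topology, Trajectory, principal_frame, write_topology, write_trajectory
from .vibrational import qho_entropy

__all__ = [
    "HarmonicSpec",
    "harmonic_trajectory",
    "analytic_frequencies",
    "analytic_entropy_oracle",
    "dihedral_fixture",
    "shell_fixture",
    "ShellFixture",
    "write_fixture",
]


@dataclass(frozen=True)
class HarmonicSpec:
    """Harmonic trap + libration parameters for the triatomic test unit.

    ``k_trans`` are per-axis translational force constants
    (kJ mol^-1 A^-2), ``kappa_rot`` librational stiffnesses
    (kJ mol^-1 rad^-2). Defaults give frequencies in the far-infrared
    range typical of intermolecular motion at 300 K.
    """

    k_trans: tuple[float, float, float] = (300.0, 300.0, 300.0)
    kappa_rot: tuple[float, float, float] = (50.0, 50.0, 50.0)
    masses: tuple[float, float, float] = (15.999, 1.008, 1.008)  # amu
    temperature: float = 300.0  # K
    n_frames: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if any(k <= 0 for k in self.k_trans) or any(k <= 0 for k in self.kappa_rot):
            raise ValueError("force constants must be positive")
        if any(m <= 0 for m in self.masses):
            raise ValueError("masses must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")

    def metadata(self) -> dict:
        return {
            "k_trans": list(self.k_trans), "kappa_rot": list(self.kappa_rot),
            "masses": list(self.masses), "temperature": self.temperature,
            "n_frames": self.n_frames, "seed": self.seed,
        }


def _equilibrium_geometry(masses) -> np.ndarray:
    """Water-like triatomic geometry re-expressed in its principal frame
    (center of mass at origin, principal axes along x/y/z, moments
    ascending)."""
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.7572, 0.0, -0.5865],
        [-0.7572, 0.0, -0.5865],
    ])
    rf = principal_frame(coords, np.asarray(masses, float))
    return (coords - rf.origin) @ rf.axes.T


def _spec_topology() -> Topology:
    atoms = [Atom(0, "O", "O", 15.999), Atom(1, "H1", "H", 1.008), Atom(2, "H2", "H", 1.008)]
    mol = Molecule("SOL_1", "other", (0, 1, 2), 1)
    return Topology(atoms, [(0, 1), (0, 2)], [mol])


def harmonic_trajectory(spec: HarmonicSpec) -> Trajectory:
    """Sample a Boltzmann-distributed trajectory of the harmonic unit.

    Per frame and translational axis a: displacement x_a ~
    N(0, k_B T/k_a) with restoring force -k_a x_a shared over atoms in
    proportion to mass (zero torque). Librational torques tau_a =
    -kappa_a theta_a, theta_a ~ N(0, k_B T/kappa_a), are realised as
    rigid-rotation force fields m_i (alpha x r_i) with zero net force.
    The orientation itself is held fixed so the principal frame is
    constant; only forces fluctuate, which is all the covariance method
    reads.
    """
    rng = np.random.default_rng(spec.seed)
    masses = np.asarray(spec.masses, float)
    geom = _equilibrium_geometry(masses)
    m_si = masses * AMU_TO_KG
    m_tot = m_si.sum()
    k_si = np.asarray(spec.k_trans, float) * FORCE_CONSTANT_TO_SI
    kap_si = np.asarray(spec.kappa_rot, float) * KJMOL_TO_J
    kbt = KB * spec.temperature

    rf = principal_frame(geom, masses)
    i_si = rf.moments * INERTIA_TO_SI  # geometry is already principal-aligned

    n = spec.n_frames
    x = rng.normal(0.0, np.sqrt(kbt / k_si), size=(n, 3))  # m
    theta = rng.normal(0.0, np.sqrt(kbt / kap_si), size=(n, 3))  # rad
    f_net = -k_si * x  # N
    tau = -kap_si * theta  # J/rad
    alpha = tau / i_si

    rel = geom * ANGSTROM_TO_M  # COM-relative positions, m
    coords = np.empty((n, 3, 3))
    forces_si = np.empty((n, 3, 3))
    for f in range(n):
        coords[f] = geom + x[f] / ANGSTROM_TO_M
        trans_part = f_net[f][None, :] * (m_si / m_tot)[:, None]
        rot_part = m_si[:, None] * np.cross(alpha[f], rel)
        forces_si[f] = trans_part + rot_part

    box = np.tile(np.eye(3) * 1e3, (n, 1, 1))
    times = np.arange(n, dtype=float)
    return Trajectory(_spec_topology(), coords, forces_si / FORCE_TO_SI, times, box)


def analytic_frequencies(spec: HarmonicSpec) -> np.ndarray:
    """The six exact mode frequencies (s^-1): nu = sqrt(k/M)/2pi per
    translational axis and sqrt(kappa/I_a)/2pi per principal axis."""
    masses = np.asarray(spec.masses, float)
    m_tot = (masses * AMU_TO_KG).sum()
    geom = _equilibrium_geometry(masses)
    i_si = principal_frame(geom, masses).moments * INERTIA_TO_SI
    k_si = np.asarray(spec.k_trans, float) * FORCE_CONSTANT_TO_SI
    kap_si = np.asarray(spec.kappa_rot, float) * KJMOL_TO_J
    nu_t = np.sqrt(k_si / m_tot) / (2 * np.pi)
    nu_r = np.sqrt(kap_si / i_si) / (2 * np.pi)
    return np.sort(np.concatenate([nu_t, nu_r]))


def analytic_entropy_oracle(spec: HarmonicSpec) -> float:
    """Exact vibrational entropy (J K^-1 mol^-1) of the spec's six modes
    under the quantum-harmonic-oscillator formula."""
    return qho_entropy(analytic_frequencies(spec), spec.temperature)


def write_fixture(spec: HarmonicSpec, directory: str | Path) -> tuple[Path, Path]:
    """Write the harmonic fixture through the package's own file formats
    (JSON topology + NPZ force trajectory), exercising the I/O path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    traj = harmonic_trajectory(spec)
    top_path = directory / "topology.json"
    trj_path = directory / "trajectory.npz"
    write_topology(traj.topology, top_path)
    write_trajectory(traj, trj_path, metadata=spec.metadata())
    return top_path, trj_path


# ---------------------------------------------------------------------------
# Dihedral mixtures


def dihedral_fixture(well_centers, weights, concentration: float = 200.0,
                     n: int = 10_000, seed: int = 0,
                     bin_width: float = 30.0) -> tuple[np.ndarray, float]:
    """Angles (degrees) drawn from a mixture of von Mises wells, plus the
    exact conformer entropy -k_B sum w ln w (J K^-1 mol^-1).

    Wells must be circularly separated by more than twice the histogram
    bin width or the adaptive binning could not resolve them and the
    ground truth would be undefined.
    """
    centers = np.asarray(well_centers, float) % 360.0
    w = np.asarray(weights, float)
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w <= 0):
        raise ValueError("weights must be positive and sum to 1")
    if centers.size != w.size:
        raise ValueError("one weight per well required")
    for i in range(centers.size):
        for j in range(i + 1, centers.size):
            d = abs(centers[i] - centers[j])
            if min(d, 360.0 - d) <= 2 * bin_width:
                raise ValueError("wells overlap: separation must exceed twice the bin width")
    rng = np.random.default_rng(seed)
    comp = rng.choice(centers.size, size=n, p=w)
    angles = np.degrees(rng.vonmises(np.radians(centers[comp]), concentration)) % 360.0
    true_entropy = float(-R * (w * np.log(w)).sum()) if w.size > 1 else 0.0
    return angles, true_entropy


# ---------------------------------------------------------------------------
# Hydration-shell geometries


@dataclass
class ShellFixture:
    solute: np.ndarray  # (3,)
    waters: np.ndarray  # (n, 3) oxygen positions
    contact_indices: set[int]  # ground-truth first shell
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def to_trajectory(self) -> Trajectory:
        """One-frame trajectory: a carbon-like solute plus oxygen-site
        waters, in a huge box (no periodic wrapping)."""
        atoms = [Atom(0, "C", "C", 12.011)]
        mols = [Molecule("solute", "guest", (0,), 1)]
        for i in range(self.waters.shape[0]):
            atoms.append(Atom(i + 1, "OW", "O", 15.999))
            mols.append(Molecule(f"W{i}", "water", (i + 1,), 1))
        top = Topology(atoms, [], mols)
        coords = np.vstack([self.solute[None], self.waters])[None]
        forces = np.zeros_like(coords)
        box = (np.eye(3) * 1e4)[None]
        return Trajectory(top, coords, forces, np.zeros(1), box)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def shell_fixture(n_contact: int, n_distant: int, seed: int = 0) -> ShellFixture:
    """Solute at the origin with ``n_contact`` first-shell waters at 3 A
    on well-spread directions and ``n_distant`` waters stacked directly
    behind them (blocked by construction). With no contacts, distant
    waters are strung along a far arc where each blocks its neighbour's
    line to the solute, leaving the shell empty.

    Raises when contacts are packed so densely (pairwise separation
    below ~32 degrees) that they would start occluding one another.
    """
    if n_contact < 0 or n_distant < 0:
        raise ValueError("counts must be >= 0")
    if n_contact == 0 and n_distant == 1:
        raise ValueError("a lone distant water cannot be blocked: placement infeasible")
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    contact_r = 3.0

    waters: list[np.ndarray] = []
    if n_contact > 0:
        dirs = _fibonacci_sphere(n_contact) @ rot.T
        if n_contact > 1:
            cosmax = max(float(dirs[i] @ dirs[j])
                         for i in range(n_contact) for j in range(i + 1, n_contact))
            if np.degrees(np.arccos(np.clip(cosmax, -1, 1))) < 32.0:
                raise ValueError("too many contact waters: placement infeasible")
        waters.extend(contact_r * d for d in dirs)
        for j in range(n_distant):  # stack behind contacts, layer by layer
            d = dirs[j % n_contact]
            layer = 1 + j // n_contact
            waters.append((contact_r + 3.2 * layer) * d)
    elif n_distant > 0:
        # far arc: neighbours at ~88 degrees from the solute direction and
        # much closer than the solute, so every water's view is blocked
        arc_r, step = 60.0, 0.1
        for j in range(n_distant):
            a = j * step
            waters.append(arc_r * (rot @ np.array([np.cos(a), np.sin(a), 0.0])))

    return ShellFixture(
        solute=np.zeros(3),
        waters=np.array(waters).reshape(len(waters), 3),
        contact_indices=set(range(n_contact)),
        seed=seed,
        metadata={"n_contact": n_contact, "n_distant": n_distant, "seed": seed},
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
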