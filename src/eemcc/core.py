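"""Data model for force-bearing MD systems.

A :class:`Topology` partitions atoms into named molecules with roles
(host, guest, water, other) and rotational symmetry numbers. A
:class:`Trajectory` binds a topology to frames of coordinates *and*
atomic forces — the entropy machinery is force-based, so trajectories
without forces are rejected at load time.

Sub-molecular "cells" are united atoms: each heavy atom together with
its bonded hydrogens. Local reference frames (molecular principal axes,
united-atom bond-derived axes) live here too.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Molecule",
    "Topology",
    "UnitedAtom",
    "Frame",
    "Trajectory",
    "ReferenceFrame",
    "Config",
    "ForcesRequiredError",
    "define_united_atoms",
    "principal_frame",
    "united_atom_axes",
    "united_atom_moments",
    "load_system",
    "write_topology",
    "read_topology",
    "write_trajectory",
    "read_trajectory",
    "read_energy_series",
]


class ForcesRequiredError(ValueError):
    """Raised when a trajectory source carries no atomic forces."""


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    mass: float  # amu

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass(frozen=True)
class Molecule:
    name: str
    role: str  # host | guest | water | other
    atom_indices: tuple[int, ...]
    symmetry_number: int = 1

    ROLES = ("host", "guest", "water", "other")


@dataclass
class Topology:
    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    molecules: list[Molecule]

    def __post_init__(self) -> None:
        owner: dict[int, str] = {}
        for mol in self.molecules:
            if mol.role not in Molecule.ROLES:
                raise ValueError(f"unknown molecule role {mol.role!r}")
            if not (isinstance(mol.symmetry_number, (int, np.integer)) and mol.symmetry_number >= 1):
                raise ValueError(f"symmetry number of {mol.name!r} must be an integer >= 1")
            for i in mol.atom_indices:
                if i in owner:
                    raise ValueError(f"atom {i} belongs to both {owner[i]!r} and {mol.name!r}")
                owner[i] = mol.name
        for atom in self.atoms:
            if atom.mass <= 0:
                raise ValueError(f"atom {atom.index} has non-positive mass")
            if atom.index not in owner:
                raise ValueError(f"atom {atom.index} belongs to no molecule")
        for a, b in self.bonds:
            if owner.get(a) != owner.get(b):
                raise ValueError(f"bond ({a},{b}) crosses molecules")
        self._owner = owner

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def molecule(self, name: str) -> Molecule:
        for mol in self.molecules:
            if mol.name == name:
                return mol
        raise KeyError(f"no molecule named {name!r}")

    def molecules_with_role(self, role: str) -> list[Molecule]:
        return [m for m in self.molecules if m.role == role]

    def bonded(self, index: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == index:
                out.append(b)
            elif b == index:
                out.append(a)
        return out


@dataclass(frozen=True)
class UnitedAtom:
    """A heavy atom plus its bonded hydrogens — the sub-molecular cell."""

    heavy: int
    hydrogens: tuple[int, ...]

    @property
    def atom_indices(self) -> tuple[int, ...]:
        return (self.heavy, *self.hydrogens)

    @property
    def rotational_dof(self) -> int:
        """3 for non-linear (>1 H), 2 for linear (one H), 0 for a point."""
        n = len(self.hydrogens)
        return 3 if n > 1 else (2 if n == 1 else 0)


@dataclass(frozen=True)
class Frame:
    time: float  # ps
    coordinates: np.ndarray  # (n_atoms, 3) Angstrom
    forces: np.ndarray  # (n_atoms, 3) kJ mol^-1 A^-1
    box: np.ndarray  # (3, 3) Angstrom


@dataclass
class Trajectory:
    """Frames of coordinates + forces bound to a topology."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    forces: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,) ps
    box: np.ndarray  # (n_frames, 3, 3) Angstrom

    def __post_init__(self) -> None:
        n_at = self.topology.n_atoms
        for arr, nm in ((self.coordinates, "coordinates"), (self.forces, "forces")):
            if arr.shape[1:] != (n_at, 3):
                raise ValueError(
                    f"{nm} shape {arr.shape} does not match topology "
                    f"({n_at} atoms vs {arr.shape[1] if arr.ndim == 3 else '?'})"
                )
        if self.coordinates.shape[0] != self.forces.shape[0]:
            raise ValueError("coordinate and force frame counts differ")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), self.coordinates[i], self.forces[i], self.box[i])

    def strided(self, stride: int) -> "Trajectory":
        s = slice(None, None, stride)
        return Trajectory(self.topology, self.coordinates[s], self.forces[s],
                          self.times[s], self.box[s])


@dataclass(frozen=True)
class ReferenceFrame:
    """Origin + orthonormal right-handed axes (rows) + principal moments."""

    origin: np.ndarray  # (3,) Angstrom
    axes: np.ndarray  # (3, 3), rows are unit axes
    moments: np.ndarray  # (3,) amu A^2, ascending

    def to_local(self, vectors: np.ndarray) -> np.ndarray:
        return vectors @ self.axes.T


@dataclass
class Config:
    """Run configuration: temperature, conventions, molecule metadata."""

    temperature: float = 300.0  # K
    x_aq_standard: float = 1.0 / 55.5
    stride: int = 1
    halving: str = "halved"  # mean-field convention: halved | raw
    frame_source: str = "self"  # self | complex (bound-host UA frames)
    water_p_corr: float = 0.25
    replicates: tuple[str, ...] = ()
    roles: dict = field(default_factory=dict)  # molecule name -> role
    symmetry_numbers: dict = field(default_factory=dict)
    experimental: dict = field(default_factory=dict)  # guest -> dG kcal/mol

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.halving not in ("halved", "raw"):
            raise ValueError("halving must be 'halved' or 'raw'")
        if self.frame_source not in ("self", "complex"):
            raise ValueError("frame_source must be 'self' or 'complex'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for key in ("temperature", "x_aq_standard", "stride", "halving",
                    "frame_source", "water_p_corr", "experimental"):
            if key in raw:
                kw[key] = raw[key]
        if "replicates" in raw:
            kw["replicates"] = tuple(raw["replicates"])
        for mol in raw.get("molecules", []):
            kw.setdefault("roles", {})[mol["name"]] = mol.get("role", "other")
            if "symmetry_number" in mol:
                kw.setdefault("symmetry_numbers", {})[mol["name"]] = mol["symmetry_number"]
        return cls(**kw)


# ---------------------------------------------------------------------------
# United atoms


def define_united_atoms(topology: Topology, molecule: str | Molecule) -> list[UnitedAtom]:
    """Partition a molecule into united atoms (heavy atom + bonded H).

    Every heavy atom yields exactly one united atom, ordered by heavy-atom
    index; every hydrogen must be bonded to exactly one heavy atom.
    """
    mol = topology.molecule(molecule) if isinstance(molecule, str) else molecule
    atoms = {i: topology.atoms[i] for i in mol.atom_indices}
    hydrogens = {i for i, a in atoms.items() if a.is_hydrogen}
    heavies = sorted(set(atoms) - hydrogens)

    attached: dict[int, list[int]] = {h: [] for h in heavies}
    for h_idx in sorted(hydrogens):
        heavy_partners = [j for j in topology.bonded(h_idx) if j in atoms and j not in hydrogens]
        if len(heavy_partners) == 0:
            raise ValueError(f"hydrogen {h_idx} is bonded to no heavy atom (free hydrogen)")
        if len(heavy_partners) > 1:
            raise ValueError(
                f"hydrogen {h_idx} is bonded to {len(heavy_partners)} heavy atoms "
                "(ill-formed topology)"
            )
        attached[heavy_partners[0]].append(h_idx)

    return [UnitedAtom(h, tuple(attached[h])) for h in heavies]


# ---------------------------------------------------------------------------
# Reference frames


def _fix_axis_signs(axes: np.ndarray) -> np.ndarray:
    """Deterministic orientation: per axis, the largest-|component| is made
    positive; the third axis is rebuilt as a cross product so the frame is
    right-handed."""
    out = axes.copy()
    for i in range(2):
        j = np.argmax(np.abs(out[i]))
        if out[i, j] < 0:
            out[i] = -out[i]
    out[2] = np.cross(out[0], out[1])
    return out


def principal_frame(coordinates: np.ndarray, masses: np.ndarray) -> ReferenceFrame:
    """Center of mass and principal axes of inertia of a rigid unit.

    Raises for (near-)collinear geometries: linear units are out of scope
    and would have a vanishing principal moment.
    """
    coordinates = np.asarray(coordinates, float)
    masses = np.asarray(masses, float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    origin = masses @ coordinates / total
    rel = coordinates - origin
    inertia = np.einsum("a,ai,aj->ij", masses, rel, rel)
    inertia = np.trace(inertia) * np.eye(3) - inertia
    moments, vecs = np.linalg.eigh(inertia)
    if moments[-1] <= 0 or moments[0] < 1e-10 * moments[-1]:
        raise ValueError("degenerate (collinear) geometry: molecule is linear or a point")
    axes = _fix_axis_signs(vecs.T)
    return ReferenceFrame(origin=origin, axes=axes, moments=moments)


def united_atom_axes(coordinates: np.ndarray, ua: UnitedAtom,
                     fallback: np.ndarray | None = None) -> np.ndarray:
    """Local axes of a united atom from its covalent bonds to hydrogen.

    z lies along the mean heavy->H bond direction; x is the in-plane
    component of the first H bond (for >=2 H) or an arbitrary
    perpendicular (one H). A hydrogen-free united atom has no bond-derived
    orientation: ``fallback`` axes (e.g. the parent molecule's principal
    axes) are used, defaulting to the lab frame.
    """
    if not ua.hydrogens:
        return np.eye(3) if fallback is None else fallback
    r0 = coordinates[ua.heavy]
    bond_dirs = []
    for h in ua.hydrogens:
        d = coordinates[h] - r0
        n = np.linalg.norm(d)
        if n < 1e-10:
            raise ValueError("coincident hydrogen and heavy atom")
        bond_dirs.append(d / n)
    z = np.sum(bond_dirs, axis=0)
    nz = np.linalg.norm(z)
    if nz < 1e-8:  # symmetric opposed hydrogens: fall back to first bond
        z = bond_dirs[0]
        nz = 1.0
    z = z / nz
    if len(bond_dirs) >= 2:
        x = bond_dirs[0] - (bond_dirs[0] @ z) * z
        if np.linalg.norm(x) < 1e-8:
            x = bond_dirs[1] - (bond_dirs[1] @ z) * z
    else:
        e = np.eye(3)[np.argmin(np.abs(z))]
        x = e - (e @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.array([x, y, z])


def united_atom_moments(coordinates: np.ndarray, masses: np.ndarray,
                        ua: UnitedAtom, axes: np.ndarray) -> np.ndarray:
    """Moments of inertia (amu A^2) of a united atom about its heavy-atom
    origin, along the given local axes. The heavy atom sits at the origin
    and contributes nothing; only hydrogens carry angular inertia."""
    r0 = coordinates[ua.heavy]
    idx = list(ua.atom_indices)
    rel = (coordinates[idx] - r0) @ axes.T
    m = masses[idx]
    r2 = np.einsum("ai,ai->a", rel, rel)
    return np.array([m @ (r2 - rel[:, k] ** 2) for k in range(3)])


# ---------------------------------------------------------------------------
# Periodic unwrapping


def unwrap_molecule(coordinates: np.ndarray, atom_indices, bonds, box_lengths) -> np.ndarray:
    """Make a molecule whole across periodic boundaries by walking its bond
    graph from the lowest-index atom and minimum-imaging each step."""
    idx = list(atom_indices)
    pos = {i: coordinates[i].copy() for i in idx}
    adj: dict[int, list[int]] = {i: [] for i in idx}
    for a, b in bonds:
        if a in adj and b in adj:
            adj[a].append(b)
            adj[b].append(a)
    seen = set()
    stack = [idx[0]]
    seen.add(idx[0])
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if j in seen:
                continue
            d = pos[j] - pos[i]
            pos[j] = pos[i] + d - box_lengths * np.round(d / box_lengths)
            seen.add(j)
            stack.append(j)
    out = coordinates.copy()
    for i in idx:
        out[i] = pos[i]
    return out


# ---------------------------------------------------------------------------
# I/O: internal JSON topology + NPZ trajectory, GRO/PDB + TRR via MDAnalysis


def write_topology(topology: Topology, path: str | Path) -> None:
    doc = {
        "atoms": [[a.index, a.name, a.element, a.mass] for a in topology.atoms],
        "bonds": [list(b) for b in topology.bonds],
        "molecules": [
            {"name": m.name, "role": m.role, "atoms": list(m.atom_indices),
             "symmetry_number": int(m.symmetry_number)}
            for m in topology.molecules
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_topology(path: str | Path) -> Topology:
    doc = json.loads(Path(path).read_text())
    atoms = [Atom(int(i), n, e, float(m)) for i, n, e, m in doc["atoms"]]
    bonds = [tuple(b) for b in doc["bonds"]]
    mols = [
        Molecule(m["name"], m["role"], tuple(m["atoms"]), int(m.get("symmetry_number", 1)))
        for m in doc["molecules"]
    ]
    return Topology(atoms, bonds, mols)


def write_trajectory(trajectory: Trajectory, path: str | Path,
                     metadata: dict | None = None) -> None:
    """NPZ archive with arrays: coordinates (F,N,3) A, forces (F,N,3)
    kJ mol^-1 A^-1, times (F,) ps, box (F,3,3) A."""
    extra = {}
    if metadata is not None:
        extra["metadata"] = np.array(json.dumps(metadata))
    np.savez(Path(path), coordinates=trajectory.coordinates, forces=trajectory.forces,
             times=trajectory.times, box=trajectory.box, **extra)


def read_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    with np.load(Path(path)) as arc:
        if "forces" not in arc:
            raise ForcesRequiredError(f"forces required: {path} stores no force arrays")
        coords, forces = arc["coordinates"], arc["forces"]
        times = arc["times"] if "times" in arc else np.arange(coords.shape[0], dtype=float)
        box = arc["box"] if "box" in arc else np.tile(np.eye(3) * 1e6, (coords.shape[0], 1, 1))
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: trajectory has {coords.shape[1]} atoms, "
            f"topology has {topology.n_atoms}"
        )
    return Trajectory(topology, coords, forces, times, box)


def _topology_from_mdanalysis(universe, config: Config | None) -> Topology:
    roles = config.roles if config else {}
    sigmas = config.symmetry_numbers if config else {}
    water_resnames = {"SOL", "WAT", "HOH", "TIP3", "TIP3P", "SPC"}
    atoms = []
    for at in universe.atoms:
        try:
            element = at.element
        except Exception:
            from MDAnalysis.topology.guessers import guess_atom_element
            element = guess_atom_element(at.name)
        atoms.append(Atom(int(at.index), str(at.name), str(element), float(at.mass)))
    if hasattr(universe, "bonds") and len(universe.bonds):
        bonds = [(int(a), int(b)) for a, b in universe.bonds.indices]
    else:
        guessed = universe.atoms.guess_bonds()  # falls back to vdW-distance guessing
        bonds = [(int(a), int(b)) for a, b in universe.atoms.bonds.indices] if guessed is None else []
    mols = []
    for res in universe.residues:
        name = f"{res.resname}_{res.resid}"
        role = roles.get(res.resname, roles.get(name,
                    "water" if res.resname.upper() in water_resnames else "other"))
        mols.append(Molecule(name, role, tuple(int(i) for i in res.atoms.indices),
                             int(sigmas.get(res.resname, sigmas.get(name, 1)))))
    return Topology(atoms, bonds, mols)


def load_system(topology_path: str | Path, trajectory_path: str | Path,
                config: Config | None = None) -> Trajectory:
    """Load a force-bearing trajectory bound to its topology.

    Topology: internal JSON (``.json``) or GRO/PDB (molecules from
    residues, roles/symmetry numbers from ``config``). Trajectory:
    internal NPZ archive or TRR with forces. Trajectories without forces
    are rejected: the covariance formulation needs them.
    """
    topology_path, trajectory_path = Path(topology_path), Path(trajectory_path)
    for p in (topology_path, trajectory_path):
        if not p.exists():
            raise FileNotFoundError(p)

    if topology_path.suffix == ".json":
        topology = read_topology(topology_path)
    else:
        import MDAnalysis as mda
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology_path))
        topology = _topology_from_mdanalysis(u, config)

    if trajectory_path.suffix == ".npz":
        traj = read_trajectory(trajectory_path, topology)
    else:
        import MDAnalysis as mda
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_path.suffix.lower() == ".trr":
                reader = mda.coordinates.TRR.TRRReader(str(trajectory_path))
            else:
                reader = mda.Universe(str(topology_path), str(trajectory_path)).trajectory
        if reader.n_atoms != topology.n_atoms:
            raise ValueError(
                f"atom count mismatch: trajectory has {reader.n_atoms} atoms, "
                f"topology has {topology.n_atoms}"
            )
        coords, forces, times, boxes = [], [], [], []
        for ts in reader:
            if not ts.has_forces:
                raise ForcesRequiredError(
                    f"forces required: {trajectory_path} stores no forces"
                )
            coords.append(ts.positions.copy())
            forces.append(ts.forces.copy())
            times.append(ts.time)
            boxes.append(ts.triclinic_dimensions.copy() if ts.dimensions is not None
                         else np.eye(3) * 1e6)
        traj = Trajectory(topology, np.array(coords), np.array(forces),
                          np.array(times), np.array(boxes))
    stride = config.stride if config else 1
    return traj.strided(stride) if stride > 1 else traj


def read_energy_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column whitespace text: time (ps), energy (kJ mol^-1)."""
    data = np.loadtxt(Path(path), comments=("#", "@"))
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError("energy series needs two columns: time, energy")
    return data[:, 0], data[:, 1]
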