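"""Topographical (minima-counting) entropy terms.

Vibrational entropy covers motion within one energy well; the
topographical terms count the wells themselves:

* positional — where a molecule can sit, S = k_B ln(1/x_aq) at mole
  fraction x_aq (1/55.5 for a 1 M aqueous solute, ~1 for solvent water);
* orientational — how it can point, from the coordination number N_c of
  its first shell, its symmetry number sigma and a hydrogen-bond
  correlation factor p_corr (1 for solutes, 0.25 for water); a guest
  locked inside a host instead counts the host's symmetry-equivalent
  poses, S = k_B ln(sigma_host/sigma_guest);
* conformational — which dihedral wells its heavy-atom torsions occupy,
  a Shannon entropy over the joint distribution of adaptively binned
  dihedral states.

All values are molar, J K^-1 mol^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import R

__all__ = [
    "OrientationalContext",
    "DihedralSeries",
    "ConformerDistribution",
    "positional_entropy",
    "orientational_entropy_solution",
    "orientational_entropy_bound",
    "assign_conformers",
    "conformational_entropy",
    "protonation_correction",
    "dihedral_angles",
]


@dataclass(frozen=True)
class OrientationalContext:
    n_c: float  # coordination number (trajectory mean; fractional allowed)
    sigma: int = 1  # rotational symmetry number
    p_corr: float = 1.0  # orientational correlation factor; 0.25 for water

    def __post_init__(self):
        if self.n_c < 0:
            raise ValueError("coordination number must be >= 0")
        if self.sigma < 1:
            raise ValueError("symmetry number must be >= 1")
        if not (0.0 < self.p_corr <= 1.0):
            raise ValueError("p_corr must lie in (0, 1]")


@dataclass(frozen=True)
class DihedralSeries:
    atoms: tuple[int, int, int, int]
    angles: np.ndarray  # degrees per frame, wrapped to [0, 360)

    def __post_init__(self):
        object.__setattr__(self, "angles", np.asarray(self.angles, float) % 360.0)


@dataclass(frozen=True)
class ConformerDistribution:
    labels: tuple
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, float)
        if np.any(p <= 0):
            raise ValueError("probabilities must be positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def n_conf(self) -> int:
        return len(self.labels)

    @property
    def entropy(self) -> float:
        p = self.probabilities
        return float(-R * (p * np.log(p)).sum())


def positional_entropy(x_aq: float) -> float:
    """S = k_B ln(1/x_aq): entropy of a molecule's positional minima at
    mole fraction x_aq. Zero for solvent water (x ~ 1); R ln 55.5 = 33.4
    J K^-1 mol^-1 for a solute at 1 M."""
    if not (0.0 < x_aq <= 1.0):
        raise ValueError("mole fraction must lie in (0, 1]")
    return float(R * np.log(1.0 / x_aq))


def orientational_entropy_solution(ctx: OrientationalContext | float,
                                   sigma: int = 1, p_corr: float = 1.0) -> float:
    """S = k_B ln( N_c^{3/2} sqrt(pi) p_corr / sigma ) for a molecule in
    solution, with N_c the first-shell coordination number."""
    if not isinstance(ctx, OrientationalContext):
        ctx = OrientationalContext(float(ctx), sigma, p_corr)
    if ctx.n_c == 0:
        raise ValueError("coordination number is zero: no orientational minima defined")
    arg = ctx.n_c ** 1.5 * np.sqrt(np.pi) * ctx.p_corr / ctx.sigma
    return float(R * np.log(arg))


def orientational_entropy_bound(sigma_host: int, sigma_guest: int) -> float:
    """S = k_B ln(sigma_host/sigma_guest) for a guest bound inside a host:
    its orientational minima are the host's symmetry-equivalent poses."""
    if sigma_host < 1 or sigma_guest < 1:
        raise ValueError("symmetry numbers must be >= 1")
    return float(R * np.log(sigma_host / sigma_guest))


# ---------------------------------------------------------------------------
# Conformational entropy: adaptive dihedral binning


def _circular_runs(counts: np.ndarray) -> list[list[int]]:
    """Maximal circular runs of equal histogram counts, as index lists."""
    nb = counts.size
    if np.all(counts == counts[0]):
        return [list(range(nb))]
    # rotate so a boundary between unequal counts sits at position 0
    start = next(i for i in range(nb) if counts[i] != counts[i - 1])
    runs, cur = [], [start]
    order = [(start + k) % nb for k in range(1, nb)]
    for i in order:
        if counts[i] == counts[cur[-1]]:
            cur.append(i)
        else:
            runs.append(cur)
            cur = [i]
    runs.append(cur)
    return runs


def find_peaks_circular(counts: np.ndarray) -> list[int]:
    """Peak bins of a periodic histogram: a run of equal counts whose count
    strictly exceeds both circular neighbours. Plateaus contribute their
    lowest-angle bin; a flat histogram yields the single lowest-angle bin
    of maximal count (bin 0)."""
    counts = np.asarray(counts)
    nb = counts.size
    runs = _circular_runs(counts)
    if len(runs) == 1:
        return [int(np.argmax(counts))]
    peaks = []
    for run in runs:
        left = counts[(run[0] - 1) % nb]
        right = counts[(run[-1] + 1) % nb]
        if counts[run[0]] > left and counts[run[0]] > right:
            peaks.append(min(run))
    if not peaks:  # pathological (e.g. perfectly alternating): take max bin
        peaks = [int(np.argmax(counts))]
    return sorted(peaks)


def assign_conformers(series: DihedralSeries | np.ndarray,
                      bin_width: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """Adaptively bin a dihedral series: histogram at ``bin_width``, find
    circular peaks, assign every frame to its nearest peak by circular
    distance. Returns (per-frame labels, peak centres in degrees)."""
    angles = series.angles if isinstance(series, DihedralSeries) else \
        np.asarray(series, float) % 360.0
    if angles.size == 0:
        raise ValueError("empty dihedral series")
    nb = 360.0 / bin_width
    if abs(nb - round(nb)) > 1e-9:
        raise ValueError("bin width must divide 360 degrees")
    nb = int(round(nb))
    counts, _ = np.histogram(angles, bins=nb, range=(0.0, 360.0))
    peak_bins = find_peaks_circular(counts)
    centers = (np.array(peak_bins) + 0.5) * bin_width
    diff = np.abs(angles[:, None] - centers[None, :])
    circ = np.minimum(diff, 360.0 - diff)
    labels = np.argmin(circ, axis=1)  # ties resolve to the lower-angle peak
    return labels, centers


def conformational_entropy(label_sequences) -> float:
    """Joint conformational entropy, S = -k_B sum_i p_i ln p_i, where a
    conformer is the tuple of per-dihedral peak labels in one frame and
    p_i its empirical frequency. A rigid molecule (no dihedrals or a
    single conformer) has zero conformational entropy."""
    seqs = [np.asarray(s) for s in label_sequences]
    if not seqs:
        return 0.0
    n = seqs[0].size
    if any(s.size != n for s in seqs):
        raise ValueError("dihedral label sequences have mismatched lengths")
    if n == 0:
        raise ValueError("empty label sequences")
    joint = np.stack(seqs, axis=1)
    _, counts = np.unique(joint, axis=0, return_counts=True)
    p = counts / n
    return float(-R * (p * np.log(p)).sum())


def conformer_distribution(label_sequences) -> ConformerDistribution:
    seqs = [np.asarray(s) for s in label_sequences]
    joint = np.stack(seqs, axis=1)
    states, counts = np.unique(joint, axis=0, return_counts=True)
    p = counts / counts.sum()
    return ConformerDistribution(tuple(map(tuple, states)), p)


def protonation_correction(fraction_unbound: float, fraction_bound: float) -> float:
    """Binding-entropy shift for a guest whose protonation state changes on
    binding. The supported case — half protonated free in solution, fully
    protonated when bound — contributes -0.5 k_B ln 2 = -2.88 J K^-1
    mol^-1; unchanged states contribute nothing."""
    for f in (fraction_unbound, fraction_bound):
        if not (0.0 <= f <= 1.0):
            raise ValueError("protonated fractions must lie in [0, 1]")
    if fraction_unbound == fraction_bound:
        return 0.0
    if (fraction_unbound, fraction_bound) == (0.5, 1.0):
        return float(-0.5 * R * np.log(2.0))
    if (fraction_unbound, fraction_bound) == (1.0, 0.5):
        return float(0.5 * R * np.log(2.0))
    raise NotImplementedError(
        "only the half-protonated <-> fully-protonated shift is supported"
    )


# ---------------------------------------------------------------------------
# Dihedral extraction


def dihedral_angles(coordinates: np.ndarray, quad: tuple[int, int, int, int]) -> np.ndarray:
    """Dihedral angle (degrees, [0, 360)) of an atom quadruple over frames.
    ``coordinates`` is (n_frames, n_atoms, 3)."""
    p0, p1, p2, p3 = (coordinates[:, i] for i in quad)
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    v = b0 - np.einsum("ij,ij->i", b0, b1n)[:, None] * b1n
    w = b2 - np.einsum("ij,ij->i", b2, b1n)[:, None] * b1n
    x = np.einsum("ij,ij->i", v, w)
    y = np.einsum("ij,ij->i", np.cross(b1n, v), w)
    return np.degrees(np.arctan2(y, x)) % 360.0


def heavy_atom_dihedrals(topology, molecule: str) -> list[tuple[int, int, int, int]]:
    """All rotatable heavy-atom dihedrals of a molecule: for each bond b-c
    between heavy atoms that both have another heavy neighbour, the
    quadruple (a, b, c, d) with a, d the lowest-index heavy neighbours."""
    mol = topology.molecule(molecule)
    atoms = {i: topology.atoms[i] for i in mol.atom_indices}
    heavy = {i for i, a in atoms.items() if not a.is_hydrogen}
    quads = []
    for b, c in topology.bonds:
        if b not in heavy or c not in heavy:
            continue
        b, c = min(b, c), max(b, c)
        a_nb = sorted(j for j in topology.bonded(b) if j in heavy and j != c)
        d_nb = sorted(j for j in topology.bonded(c) if j in heavy and j != b)
        if a_nb and d_nb:
            quads.append((a_nb[0], b, c, d_nb[0]))
    return quads
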