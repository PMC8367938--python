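"""First-hydration-shell analysis and water bookkeeping.

Shells are identified with the relative angular distance (RAD)
criterion, a parameter-free coordination definition: candidates around
a centre are sorted by distance and a farther candidate j is rejected
whenever some closer accepted neighbour k blocks it,

    (1/r_ij)^2 < (1/r_ik)^2 cos(theta_jik),

with theta_jik the angle at the centre i between j and k. A water
belongs to a solute's first shell when the solute appears in the
water's own RAD neighbour set (sites: water oxygens and solute heavy
atoms).

Binding bookkeeping balances water stoichiometry: the number of waters
released to bulk satisfies  N_WB + N_WS,H-G = N_WS,H + N_WS,G  exactly,
and N_WB splits into host- and guest-released parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ShellAssignment",
    "WaterBookkeeping",
    "rad_neighbors",
    "first_shell_waters",
    "split_complex_shell",
    "water_bookkeeping",
    "water_entropy_by_category",
]


@dataclass
class ShellAssignment:
    solute: str
    per_frame: list[set]  # water molecule names per frame

    @property
    def mean_count(self) -> float:
        if not self.per_frame:
            return 0.0
        return float(np.mean([len(s) for s in self.per_frame]))


@dataclass
class WaterBookkeeping:
    """Mean first-shell counts and the released-to-bulk balance."""

    n_ws_host: float
    n_ws_guest: float
    n_ws_complex_host: float  # complex-shell waters nearer the host
    n_ws_complex_guest: float
    host_released: float = field(init=False)
    guest_released: float = field(init=False)
    n_wb: float = field(init=False)

    def __post_init__(self):
        for v in (self.n_ws_host, self.n_ws_guest,
                  self.n_ws_complex_host, self.n_ws_complex_guest):
            if v < 0:
                raise ValueError("shell counts must be >= 0")
        self.host_released = self.n_ws_host - self.n_ws_complex_host
        self.guest_released = self.n_ws_guest - self.n_ws_complex_guest
        self.n_wb = self.host_released + self.guest_released
        if self.host_released < 0 or self.guest_released < 0:
            logger.warning(
                "negative released-water count (shell grows on binding): "
                "host %.2f, guest %.2f; reports clamp at zero",
                self.host_released, self.guest_released,
            )

    @property
    def n_ws_complex(self) -> float:
        return self.n_ws_complex_host + self.n_ws_complex_guest


def _minimum_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return disp
    lengths = np.diagonal(box) if np.ndim(box) == 2 else np.asarray(box, float)
    return disp - lengths * np.round(disp / lengths)


def rad_neighbors(center: np.ndarray, candidates: np.ndarray,
                  box: np.ndarray | None = None) -> set[int]:
    """RAD neighbour set of a centre among candidate sites.

    Returns indices into ``candidates``. Distance-sorted greedy sweep:
    each candidate is accepted unless blocked by a closer accepted one.
    """
    center = np.asarray(center, float)
    candidates = np.atleast_2d(np.asarray(candidates, float))
    disp = _minimum_image(candidates - center, box)
    r = np.linalg.norm(disp, axis=1)
    if np.any(r < 1e-8):
        raise ValueError("candidate coincides with the centre")
    order = np.argsort(r, kind="stable")
    unit = disp / r[:, None]
    accepted: list[int] = []
    for j in order:
        blocked = False
        for k in accepted:
            cos_t = float(unit[j] @ unit[k])
            if (1.0 / r[j]) ** 2 < (1.0 / r[k]) ** 2 * cos_t:
                blocked = True
                break
        if not blocked:
            accepted.append(int(j))
    return set(accepted)


def _water_oxygen_index(topology, mol) -> int:
    for i in mol.atom_indices:
        if not topology.atoms[i].is_hydrogen:
            return i
    raise ValueError(f"water {mol.name!r} has no heavy atom")


def _solute_heavy_indices(topology, solutes) -> list[int]:
    idx = []
    for mol in solutes:
        idx.extend(i for i in mol.atom_indices if not topology.atoms[i].is_hydrogen)
    return idx


def first_shell_waters(trajectory: Trajectory, solute: str | list[str]) -> ShellAssignment:
    """Per-frame first-shell water sets of a solute (or a solute group,
    e.g. host + guest for the complex) and the trajectory-mean count.

    A water is first-shell when any solute heavy-atom site survives in
    the RAD neighbour set computed from the water's oxygen over all
    water-oxygen and solute-heavy-atom sites.
    """
    top = trajectory.topology
    names = [solute] if isinstance(solute, str) else list(solute)
    solutes = [top.molecule(n) for n in names]
    waters = top.molecules_with_role("water")
    if not waters:
        raise ValueError("no water molecules in the system")
    oxy = {w.name: _water_oxygen_index(top, w) for w in waters}
    solute_sites = _solute_heavy_indices(top, solutes)
    if not solute_sites:
        raise ValueError("solute has no heavy atoms")

    per_frame: list[set] = []
    for f in range(trajectory.n_frames):
        coords = trajectory.coordinates[f]
        box = trajectory.box[f]
        shell = set()
        for w in waters:
            center = coords[oxy[w.name]]
            other_ox = [oxy[v.name] for v in waters if v.name != w.name]
            sites = other_ox + solute_sites
            accepted = rad_neighbors(center, coords[sites], box)
            n_other = len(other_ox)
            if any(a >= n_other for a in accepted):
                shell.add(w.name)
        per_frame.append(shell)
    return ShellAssignment("+".join(names), per_frame)


def split_complex_shell(trajectory: Trajectory, host: str, guest: str) -> tuple[float, float]:
    """Partition the complex's first shell into host- and guest-side parts:
    each shell water goes to the solute owning its nearest heavy atom
    (ties to the host). Returns mean (host part, guest part)."""
    top = trajectory.topology
    assignment = first_shell_waters(trajectory, [host, guest])
    h_idx = _solute_heavy_indices(top, [top.molecule(host)])
    g_idx = _solute_heavy_indices(top, [top.molecule(guest)])
    oxy = {w.name: _water_oxygen_index(top, w)
           for w in top.molecules_with_role("water")}
    host_counts, guest_counts = [], []
    for f, shell in enumerate(assignment.per_frame):
        coords = trajectory.coordinates[f]
        box = trajectory.box[f]
        nh = ng = 0
        for wname in shell:
            center = coords[oxy[wname]]
            dh = np.linalg.norm(_minimum_image(coords[h_idx] - center, box), axis=1).min()
            dg = np.linalg.norm(_minimum_image(coords[g_idx] - center, box), axis=1).min()
            if dh <= dg:
                nh += 1
            else:
                ng += 1
        host_counts.append(nh)
        guest_counts.append(ng)
    return float(np.mean(host_counts)), float(np.mean(guest_counts))


def water_bookkeeping(n_ws_host: float, n_ws_guest: float,
                      shell_hg_host_part: float, shell_hg_guest_part: float) -> WaterBookkeeping:
    """Stoichiometric balance of shell water on binding. The identity
    N_WB + N_WS,H-G = N_WS,H + N_WS,G holds exactly by construction."""
    return WaterBookkeeping(n_ws_host, n_ws_guest, shell_hg_host_part, shell_hg_guest_part)


def water_entropy_by_category(shell_per_water: dict[str, float] | None,
                              bulk_per_water: dict[str, float],
                              n_ws: float, n_wb: float) -> dict[str, float]:
    """Scale per-water entropy components to category totals.

    WS totals use shell-resident per-water components times N_WS; WB
    totals use bulk per-water components (from the pure-water
    simulation) times N_WB. Components are keyed 'transvib', 'rovib',
    'or'.
    """
    if bulk_per_water is None:
        raise ValueError("bulk-water reference components are required")
    out: dict[str, float] = {}
    if n_ws > 0:
        if shell_per_water is None:
            raise ValueError("shell-water components required when N_WS > 0")
        for key, val in shell_per_water.items():
            out[f"WS_{key}"] = val * n_ws
    else:
        for key in bulk_per_water:
            out[f"WS_{key}"] = 0.0
    for key, val in bulk_per_water.items():
        out[f"WB_{key}"] = val * n_wb
    return out
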