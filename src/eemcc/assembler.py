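"""Assembly of system free energies and the binding free energy.

Each of the four simulations (host in water, guest in water, host-guest
complex in water, bulk water) yields G = E - TS from its mean energy
and total multiscale entropy. The standard binding free energy is

    dG_bind = (G_complex + G_water) - (G_host + G_guest)

with the bulk-water leg counting the N_WB released waters so that water
stoichiometry balances exactly. Replicates give SEM = sigma/sqrt(n);
agreement with experiment is summarised as the mean absolute error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .constants import KCAL_TO_J
from .hydration import WaterBookkeeping

__all__ = [
    "EntropyComponent",
    "EntropyLedger",
    "SystemFreeEnergy",
    "BindingResult",
    "total_entropy",
    "binding_free_energy",
    "sem",
    "mae",
    "energy_drift",
    "report",
]


@dataclass(frozen=True)
class EntropyComponent:
    """One S_ij^kl term: species i, level j, motion k, minima class l."""

    species: str  # host | guest | waterWS | waterWB
    level: str  # molecule | united_atom
    motion: str  # translation | rotation
    minima: str  # vibrational | topographical
    value: float  # J K^-1 mol^-1

    @property
    def key(self):
        return (self.species, self.level, self.motion, self.minima)


@dataclass
class EntropyLedger:
    components: list[EntropyComponent] = field(default_factory=list)

    def add(self, component: EntropyComponent) -> "EntropyLedger":
        if component.key in {c.key for c in self.components}:
            raise ValueError(f"duplicate entropy component {component.key}")
        self.components.append(component)
        return self

    def total(self) -> float:
        return float(sum(c.value for c in self.components))

    def subtotal(self, **criteria) -> float:
        out = 0.0
        for c in self.components:
            if all(getattr(c, k) == v for k, v in criteria.items()):
                out += c.value
        return float(out)


def total_entropy(ledger: EntropyLedger) -> float:
    """Plain sum over all entropy components (J K^-1 mol^-1)."""
    return ledger.total()


@dataclass(frozen=True)
class SystemFreeEnergy:
    """One simulation replicate: mean energy E ~ H, total S, G = E - TS."""

    energy: float  # kcal mol^-1
    entropy: float  # J K^-1 mol^-1
    temperature: float  # K
    replicate: str = "r1"

    @property
    def ts(self) -> float:
        """T*S in kcal mol^-1."""
        return self.temperature * self.entropy / KCAL_TO_J

    @property
    def free_energy(self) -> float:
        """G = E - TS, kcal mol^-1 (PV omitted, H ~ E)."""
        return self.energy - self.ts


@dataclass
class BindingResult:
    guest: str
    dg: float  # kcal mol^-1
    dh: float
    tds: float
    dg_sem: float = 0.0
    dh_sem: float = 0.0
    tds_sem: float = 0.0
    dg_expt: float | None = None
    dh_expt: float | None = None
    tds_expt: float | None = None

    def __post_init__(self):
        if abs(self.dg - (self.dh - self.tds)) > 1e-6:
            raise ValueError("dG must equal dH - T dS")


def binding_free_energy(g_complex: SystemFreeEnergy, g_water: SystemFreeEnergy,
                        g_host: SystemFreeEnergy, g_guest: SystemFreeEnergy,
                        bookkeeping: WaterBookkeeping | None = None,
                        stoichiometry_tol: float = 1e-6,
                        guest: str = "guest") -> BindingResult:
    """dG = (G_complex + G_water) - (G_host + G_guest), with dH and TdS
    combined the same way. If a water bookkeeping record is supplied its
    stoichiometric identity is checked before combining."""
    if bookkeeping is not None:
        lhs = bookkeeping.n_wb + bookkeeping.n_ws_complex
        rhs = bookkeeping.n_ws_host + bookkeeping.n_ws_guest
        if abs(lhs - rhs) > stoichiometry_tol:
            raise ValueError(
                f"water stoichiometry violated: N_WB + N_WS,H-G = {lhs:.4f} "
                f"but N_WS,H + N_WS,G = {rhs:.4f}"
            )
    dh = (g_complex.energy + g_water.energy) - (g_host.energy + g_guest.energy)
    tds = (g_complex.ts + g_water.ts) - (g_host.ts + g_guest.ts)
    return BindingResult(guest=guest, dg=dh - tds, dh=dh, tds=tds)


def sem(replicate_values) -> float:
    """Standard error of the mean over replicate simulations,
    sigma/sqrt(n) with the sample (n-1) standard deviation."""
    vals = np.asarray(list(replicate_values), float)
    if vals.size < 2:
        raise ValueError("SEM needs at least two replicates")
    return float(np.std(vals, ddof=1) / np.sqrt(vals.size))


def mae(predicted, experimental) -> float:
    """Mean absolute error of predictions against experiment."""
    p = np.asarray(list(predicted), float)
    e = np.asarray(list(experimental), float)
    if p.shape != e.shape:
        raise ValueError(f"length mismatch: {p.size} predictions vs {e.size} experiments")
    return float(np.mean(np.abs(p - e)))


@dataclass(frozen=True)
class DriftResult:
    slope_per_ns: float  # energy units per ns
    intercept: float
    stderr_per_ns: float


def energy_drift(times_ps: np.ndarray, energies: np.ndarray) -> DriftResult:
    """Ordinary least-squares drift of an energy time series; the slope is
    reported per ns as a convergence diagnostic."""
    t = np.asarray(times_ps, float)
    e = np.asarray(energies, float)
    if t.size < 3:
        raise ValueError("drift check needs at least three points")
    if np.ptp(t) == 0:
        raise ValueError("constant time column")
    fit = stats.linregress(t, e)
    return DriftResult(float(fit.slope * 1e3), float(fit.intercept),
                       float(fit.stderr * 1e3))


# ---------------------------------------------------------------------------
# Reporting

_LEDGER_ROWS = [
    ("S_M^transvib", ("host", "guest"), ("molecule", "translation", "vibrational")),
    ("S_M^rovib", ("host", "guest"), ("molecule", "rotation", "vibrational")),
    ("S^pos", ("host", "guest"), ("molecule", "translation", "topographical")),
    ("S^or", ("host", "guest"), ("molecule", "rotation", "topographical")),
    ("S_UA^transvib", ("host", "guest"), ("united_atom", "translation", "vibrational")),
    ("S_UA^rovib", ("host", "guest"), ("united_atom", "rotation", "vibrational")),
    ("S^conf", ("host", "guest"), ("united_atom", "translation", "topographical")),
]

_WATER_ROWS = [
    ("S_WS^transvib", "waterWS", ("molecule", "translation", "vibrational")),
    ("S_WS^rovib", "waterWS", ("molecule", "rotation", "vibrational")),
    ("S_WS^or", "waterWS", ("molecule", "rotation", "topographical")),
    ("S_WB^transvib", "waterWB", ("molecule", "translation", "vibrational")),
    ("S_WB^rovib", "waterWB", ("molecule", "rotation", "vibrational")),
    ("S_WB^or", "waterWB", ("molecule", "rotation", "topographical")),
]


def report(binding_results: list[BindingResult],
           ledgers: dict[str, EntropyLedger] | None = None,
           bookkeeping: dict[str, WaterBookkeeping] | None = None,
           outdir: str | Path = ".") -> dict[str, Path]:
    """Write delimited summary tables.

    ``binding.tsv`` — dG/dH/TdS with SEM and experiment (one decimal,
    kcal mol^-1), plus MAE rows when experimental values are present;
    ``entropy_components.tsv`` — per-system component ledgers (integer
    J K^-1 mol^-1); ``water_bookkeeping.tsv`` — shell and released
    counts (negative released counts are clamped to zero and flagged
    upstream). Returns the written paths.
    """
    if not binding_results:
        raise ValueError("no binding results to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    rows = []
    for r in binding_results:
        rows.append({
            "guest": r.guest,
            "dG": round(r.dg, 1), "dG_sem": round(r.dg_sem, 1),
            "dG_expt": None if r.dg_expt is None else round(r.dg_expt, 1),
            "dH": round(r.dh, 1), "dH_sem": round(r.dh_sem, 1),
            "dH_expt": None if r.dh_expt is None else round(r.dh_expt, 1),
            "TdS": round(r.tds, 1), "TdS_sem": round(r.tds_sem, 1),
            "TdS_expt": None if r.tds_expt is None else round(r.tds_expt, 1),
        })
    df = pd.DataFrame(rows)
    if all(r.dg_expt is not None for r in binding_results):
        df.loc[len(df)] = {
            "guest": "MAE",
            "dG": round(mae([r.dg for r in binding_results],
                            [r.dg_expt for r in binding_results]), 1),
        }
    path = outdir / "binding.tsv"
    df.to_csv(path, sep="\t", index=False)
    written["binding"] = path

    if ledgers:
        recs = []
        for system, ledger in ledgers.items():
            for label, species_opts, (level, motion, minima) in _LEDGER_ROWS:
                for sp in species_opts:
                    v = ledger.subtotal(species=sp, level=level, motion=motion, minima=minima)
                    if any(c.key == (sp, level, motion, minima) for c in ledger.components):
                        recs.append({"system": system, "species": sp,
                                     "component": label, "value": int(round(v))})
            for label, sp, (level, motion, minima) in _WATER_ROWS:
                if any(c.key == (sp, level, motion, minima) for c in ledger.components):
                    v = ledger.subtotal(species=sp, level=level, motion=motion, minima=minima)
                    recs.append({"system": system, "species": sp,
                                 "component": label, "value": int(round(v))})
        path = outdir / "entropy_components.tsv"
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False)
        written["entropy_components"] = path

    if bookkeeping:
        recs = []
        for guest, bk in bookkeeping.items():
            recs.append({
                "guest": guest,
                "N_WS_host": round(bk.n_ws_host, 1),
                "N_WS_guest": round(bk.n_ws_guest, 1),
                "N_WS_complex": round(bk.n_ws_complex, 1),
                "N_WB": round(max(bk.n_wb, 0.0), 1),
                "host_released": round(max(bk.host_released, 0.0), 1),
                "guest_released": round(max(bk.guest_released, 0.0), 1),
            })
        path = outdir / "water_bookkeeping.tsv"
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False)
        written["water_bookkeeping"] = path

    return written
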