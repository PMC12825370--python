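"""Monolayer composition from fitted slab parameters via electron balances.

Each fitted slab carries an areal electron density rho·d (e⁻/Å²).  Assigning
molecular fragments to slabs (hydrocarbon tails to the air-proximal slab,
headgroups and hydration water to the aqueous-side slabs) turns the fitted
profile into per-slab electron balances::

    rho_i · d_i = sum_species  n_s · e_(s,i)  +  n_(W,i) · 10

with n_s the molecules of species s per Å², e_(s,i) the electrons of the
fragment of s assigned to slab i, and 10 electrons per water.  Solving the
balances yields the area per molecule A_s = 1/n_s, the surface excesses
Gamma (mg/m²) and the hydration number N_W per headgroup.  A molar-volume
balance is reported as a consistency residual, not enforced: the electron
balances alone determine the composition.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .constants import A2_TO_M2, N_A, WATER_ELECTRONS, WATER_MOLAR_MASS
from .slab_model import Slab

__all__ = [
    "SpeciesFragments",
    "MonolayerComposition",
    "BalanceSolution",
    "electrons_from_formula",
    "area_per_molecule",
    "waters_per_headgroup",
    "surface_excess",
    "area_from_excess",
    "waters_from_excesses",
    "molar_surface_ratio",
    "mixed_layer_composition",
    "volume_balance_residual",
    "OLEIC_ACID",
    "POLYSORBATE_80",
    "WATER",
]

_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


def electrons_from_formula(formula: str) -> int:
    """Electron count of a neutral molecule from its chemical formula."""
    tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
    total = 0
    matched = ""
    for el, num in tokens:
        if not el:
            continue
        if el not in _Z:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        total += _Z[el] * (int(num) if num else 1)
        matched += el + num
    if matched != formula or not formula:
        raise ValueError(f"could not parse formula {formula!r}")
    return total


@dataclass(frozen=True)
class SpeciesFragments:
    """Per-molecule electron (and optional volume) bookkeeping for one species.

    ``electrons_tail`` is the fragment assigned to the air-proximal slab;
    ``electrons_head`` the remainder, assigned to the hydrated slab(s).
    """

    name: str
    molar_mass: float
    electrons_total: float
    electrons_tail: float
    electrons_head: float
    volume_tail: float | None = None   # Å³, optional, for the volume check
    volume_head: float | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0 or self.electrons_total <= 0:
            raise ValueError("molar mass and electron count must be > 0")
        if self.electrons_tail < 0 or self.electrons_head < 0:
            raise ValueError("fragment electron counts must be >= 0")
        if not np.isclose(self.electrons_tail + self.electrons_head,
                          self.electrons_total):
            raise ValueError(
                f"{self.name}: tail + head electrons must equal the total "
                f"({self.electrons_tail} + {self.electrons_head} != {self.electrons_total})"
            )


# Oleic acid C18H34O2: oleyl tail C17H33 (135 e⁻) + carboxyl head CO2H (23 e⁻).
OLEIC_ACID = SpeciesFragments(
    name="OA",
    molar_mass=282.46,
    electrons_total=float(electrons_from_formula("C18H34O2")),
    electrons_tail=float(electrons_from_formula("C17H33")),
    electrons_head=float(electrons_from_formula("CO2H")),
)

# Polysorbate 80 average monooleate composition C64H124O26 (M ≈ 1310 g/mol);
# oleate tail C17H33, the sorbitan/polyoxyethylene head carries the rest.
_PS80_TOTAL = float(electrons_from_formula("C64H124O26"))
_PS80_TAIL = float(electrons_from_formula("C17H33"))
POLYSORBATE_80 = SpeciesFragments(
    name="PS80",
    molar_mass=1310.0,
    electrons_total=_PS80_TOTAL,
    electrons_tail=_PS80_TAIL,
    electrons_head=_PS80_TOTAL - _PS80_TAIL,
)

WATER = SpeciesFragments(
    name="W",
    molar_mass=WATER_MOLAR_MASS,
    electrons_total=WATER_ELECTRONS,
    electrons_tail=0.0,
    electrons_head=WATER_ELECTRONS,
)


@dataclass(frozen=True)
class MonolayerComposition:
    """Composition of the interfacial film, with optional standard deviations.

    ``area_per_molecule`` refers to the reference species (the surfactant
    whose headgroup hydration N_W describes).
    """

    area_per_molecule: float               # Å²/molecule
    gamma: dict[str, float]                # species -> mg/m²
    gamma_water: float                     # mg/m²
    waters_per_headgroup: float
    reference_species: str
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area_per_molecule < 0 or self.gamma_water < 0:
            raise ValueError("composition values must be >= 0")
        if any(g < 0 for g in self.gamma.values()):
            raise ValueError("surface excesses must be >= 0")


def area_per_molecule(tail_slab: Slab, tail_electrons: float) -> float:
    """Area per molecule from the tail-slab electron balance, A = n/(rho d).

    The air-proximal slab contains only the hydrophobic tails, so its areal
    electron density rho·d divided into the tail fragment's electron count
    gives the molecular footprint.
    """
    if tail_slab.rho <= 0:
        raise ValueError("tail slab needs rho > 0")
    if tail_electrons <= 0:
        raise ValueError("tail electron count must be > 0")
    return tail_electrons / (tail_slab.rho * tail_slab.thickness)


def waters_per_headgroup(head_slab: Slab, area: float, head_electrons: float) -> float:
    """Hydration number from the head-slab electron balance.

    N_W = (rho·d·A − e_head) / 10: whatever electrons the headgroup slab holds
    beyond one headgroup per molecular footprint are water.
    """
    excess = head_slab.rho * head_slab.thickness * area - head_electrons
    if excess < 0:
        raise ValueError(
            "head slab holds fewer electrons than one headgroup per molecule: "
            f"rho*d*A = {head_slab.rho * head_slab.thickness * area:.3f} < "
            f"{head_electrons}"
        )
    return excess / WATER_ELECTRONS


def surface_excess(molar_mass: float, area: float) -> float:
    """Surface excess Gamma (mg/m²) of a species at area per molecule A (Å²)."""
    if area <= 0:
        raise ValueError("area per molecule must be > 0")
    return molar_mass / (N_A * area * A2_TO_M2) * 1e3


def area_from_excess(molar_mass: float, gamma: float) -> float:
    """Inverse of :func:`surface_excess` (Å²/molecule from mg/m²)."""
    if gamma <= 0:
        raise ValueError("surface excess must be > 0")
    return molar_mass * 1e3 / (N_A * gamma * A2_TO_M2)


def waters_from_excesses(gamma_w: float, gamma_s: float, molar_mass_s: float) -> float:
    """N_W from surface excesses: molar ratio of water to the surfactant."""
    if gamma_s <= 0:
        raise ValueError("species surface excess must be > 0")
    return (gamma_w / WATER_MOLAR_MASS) / (gamma_s / molar_mass_s)


def molar_surface_ratio(
    gamma_a: float, gamma_b: float, molar_mass_a: float, molar_mass_b: float
) -> float:
    """Surface molar ratio of species a to species b from their excesses."""
    if gamma_b <= 0:
        raise ValueError("denominator surface excess must be > 0")
    return (gamma_a / molar_mass_a) / (gamma_b / molar_mass_b)


@dataclass(frozen=True)
class BalanceSolution:
    """Solution of the per-slab electron balances."""

    counts: dict[str, float]        # species -> molecules per Å²
    water_count: float              # water molecules per Å² (total)
    water_per_slab: np.ndarray
    residuals: np.ndarray           # relative electron-balance residual per slab
    composition: MonolayerComposition


def _normalize_partition(fractions, n_slabs: int, name: str) -> np.ndarray:
    f = np.asarray(fractions, dtype=float)
    if f.shape != (n_slabs,):
        raise ValueError(f"partition for {name!r} must have one fraction per slab")
    if np.any(f < 0):
        raise ValueError(f"partition fractions for {name!r} must be >= 0")
    if not np.isclose(f.sum(), 1.0):
        raise ValueError(f"partition fractions for {name!r} must sum to 1")
    return f


def mixed_layer_composition(
    slabs: list[Slab] | tuple[Slab, ...],
    fragments: dict[str, SpeciesFragments],
    partition: dict[str, "np.ndarray | list[float]"],
    *,
    reference_species: str | None = None,
    tol: float = 1e-8,
) -> BalanceSolution:
    """Solve the per-slab electron balances for a multi-species film.

    ``partition`` assigns each species' electrons across the slabs as
    fractions summing to 1, and must include an entry ``"water"`` giving the
    water distribution.  One electron balance per slab then forms a linear
    system in the per-area molecule counts, solved by least squares with a
    non-negativity refit when needed.
    """
    slabs = tuple(slabs)
    n = len(slabs)
    if "water" not in partition:
        raise ValueError('partition must include a "water" entry')
    names = [k for k in partition if k != "water"]
    missing = [k for k in names if k not in fragments]
    if missing:
        raise ValueError(f"no SpeciesFragments given for {missing}")

    cols = []
    for k in names:
        f = _normalize_partition(partition[k], n, k)
        cols.append(fragments[k].electrons_total * f)
    f_w = _normalize_partition(partition["water"], n, "water")
    cols.append(WATER_ELECTRONS * f_w)
    a_mat = np.column_stack(cols)
    b = np.array([s.rho * s.thickness for s in slabs], dtype=float)

    x, *_ = np.linalg.lstsq(a_mat, b, rcond=None)
    if np.any(x < -tol):
        warnings.warn(
            "electron balances gave negative molecule counts; refitting with "
            "non-negativity constraints"
        )
        x, _ = nnls(a_mat, b)
    x = np.maximum(x, 0.0)

    resid = np.abs(a_mat @ x - b) / np.maximum(b, 1e-300)
    if np.any(resid > 1e-4) and np.linalg.matrix_rank(a_mat) < min(a_mat.shape):
        raise ValueError(
            f"electron-balance system is singular/infeasible; residuals {resid}"
        )

    counts = dict(zip(names, x[:-1]))
    n_w = float(x[-1])
    ref = reference_species or names[0]
    if counts[ref] <= 0:
        raise ValueError(f"reference species {ref!r} has zero surface count")

    gamma = {
        k: surface_excess(fragments[k].molar_mass, 1.0 / c) if c > 0 else 0.0
        for k, c in counts.items()
    }
    gamma_w = (
        surface_excess(WATER_MOLAR_MASS, 1.0 / n_w) if n_w > 0 else 0.0
    )
    comp = MonolayerComposition(
        area_per_molecule=1.0 / counts[ref],
        gamma=gamma,
        gamma_water=gamma_w,
        waters_per_headgroup=n_w / counts[ref],
        reference_species=ref,
    )
    return BalanceSolution(
        counts=counts,
        water_count=n_w,
        water_per_slab=n_w * f_w,
        residuals=resid,
        composition=comp,
    )


def volume_balance_residual(
    slabs: list[Slab] | tuple[Slab, ...],
    solution: BalanceSolution,
    volumes: dict[str, "np.ndarray | list[float]"],
    *,
    water_volume: float = 29.9,
) -> np.ndarray:
    """Relative molar-volume imbalance per slab (reported, never enforced).

    ``volumes`` maps each species to its per-slab fragment volumes in
    Å³/molecule.  Per unit area, slab i of thickness d_i should hold
    d_i Å³/Å² of matter; the residual is |d_i − occupied volume| / d_i.
    """
    slabs = tuple(slabs)
    n = len(slabs)
    missing = [k for k in solution.counts if k not in volumes]
    if missing:
        raise ValueError(f"fragment volumes missing for species {missing}")
    occupied = np.zeros(n)
    for k, count in solution.counts.items():
        v = np.asarray(volumes[k], dtype=float)
        if v.shape != (n,):
            raise ValueError(f"volumes for {k!r} must have one entry per slab")
        occupied += count * v
    occupied += solution.water_per_slab * water_volume
    d = np.array([s.thickness for s in slabs])
    return np.abs(d - occupied) / d
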