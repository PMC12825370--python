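"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline — forward reflectivity, fitting, composition,
isotherm analysis — can be exercised end-to-end on data generated here, with
a documented ground truth.  Reflectivity curves carry multiplicative
Gaussian noise (constant relative error, the natural model for normalized
R/R_F data with no count scale); tension data carry additive Gaussian noise.

The built-in scenarios are realistic reference films:

``OA-monolayer`` / ``OA-monolayer-compressed``
    the two fitted oleic-acid monolayer slab stacks (depositions of 45.4 and
    34.9 Å²/molecule),
``PS80-layer``
    a two-slab polysorbate-80 adsorption layer constructed from its measured
    surface excesses at the cmc,
``mixed-3-slab``
    a three-slab OA/PS80 mixed film constructed from the measured excesses
    at a bulk OA/PS80 ratio of 5.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import composition as comp
from .isotherm import TensionIsotherm, szyszkowski_tension
from .reflectivity import ReflectivityCurve, parratt_reflectivity
from .slab_model import InterfaceModel, Slab

__all__ = [
    "SyntheticSpec",
    "ScenarioTruth",
    "MEASURED_CONCENTRATION_LADDER_MM",
    "PS80_ISOTHERM_TRUTH",
    "make_qz_grid",
    "make_reflectivity",
    "make_scenario",
    "make_isotherm_data",
    "make_relaxation_trace",
    "stack_from_composition",
]

#: Bulk PS80 concentrations at which reflectivity was measured (mM).
MEASURED_CONCENTRATION_LADDER_MM = np.array([0.0012, 0.012, 0.024, 0.06, 0.12])

#: Fitted PS80 isotherm truth: Gamma_inf (mol/m²), a (mol/L), cmc (mM).
PS80_ISOTHERM_TRUTH = {"gamma_inf": 1.94e-6, "a": 1.058e-7, "cmc": 0.024}


@dataclass
class SyntheticSpec:
    """Seed, qz grid and noise level for synthetic data generation."""

    seed: int = 0
    qz_min: float = 0.016
    qz_max: float = 0.6
    n_qz: int = 200
    noise: float = 0.02          # relative sd for reflectivity
    scenario: str | None = None

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 < self.qz_min < self.qz_max:
            raise ValueError("need 0 < qz_min < qz_max")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ScenarioTruth:
    """A ground-truth model plus the composition that generated it."""

    tag: str
    model: InterfaceModel
    composition: comp.MonolayerComposition
    partition: dict = field(default_factory=dict)
    fragments: dict = field(default_factory=dict)


def make_qz_grid(spec: SyntheticSpec) -> np.ndarray:
    return np.geomspace(spec.qz_min, spec.qz_max, spec.n_qz)


def make_reflectivity(model: InterfaceModel, spec: SyntheticSpec) -> ReflectivityCurve:
    """Forward reflectivity with multiplicative Gaussian noise, r = R·(1+eps)."""
    qz = make_qz_grid(spec)
    r_true = parratt_reflectivity(model, qz).r
    if spec.noise > 0:
        eps = spec.rng().normal(0.0, spec.noise, size=qz.size)
        r = np.maximum(r_true * (1.0 + eps), 1e-300)
    else:
        r = r_true
    dr = spec.noise * r
    return ReflectivityCurve(qz=qz, r=r, dr=dr, normalized=False)


def stack_from_composition(
    counts: dict[str, float],
    water_count: float,
    fragments: dict[str, comp.SpeciesFragments],
    partition: dict[str, "list[float] | np.ndarray"],
    thicknesses: "list[float]",
    sigma: float,
    rho_subphase: float = 0.334,
) -> InterfaceModel:
    """Forward-construct a slab stack whose electron balances hold exactly.

    ``counts`` are molecules per Å² per species; ``partition`` assigns each
    species' (and water's) electrons across the slabs.  Each slab density is
    the assigned areal electron density divided by its thickness.
    """
    n = len(thicknesses)
    rho = np.zeros(n)
    for name, count in counts.items():
        f = np.asarray(partition[name], dtype=float)
        rho += count * fragments[name].electrons_total * f
    rho += water_count * comp.WATER_ELECTRONS * np.asarray(partition["water"], float)
    rho /= np.asarray(thicknesses, dtype=float)
    slabs = tuple(Slab(thickness=d, rho=float(r), sigma=sigma)
                  for d, r in zip(thicknesses, rho))
    return InterfaceModel(slabs=slabs, rho_subphase=rho_subphase, shared_sigma=sigma)


def _counts_from_gamma(gamma: float, molar_mass: float) -> float:
    """mg/m² -> molecules/Å²."""
    return gamma * 1e-3 / molar_mass * comp.N_A * comp.A2_TO_M2


# (gamma_OA, gamma_PS80, gamma_W) in mg/m² for the mixed film at bulk
# OA/PS80 = 5.9, and (gamma_PS80, gamma_W) for pure PS80 at the cmc.
_MIXED_GAMMAS = (1.34, 1.09, 1.51)
_PS80_GAMMAS = (1.79, 1.63)


def make_scenario(tag: str) -> ScenarioTruth:
    """Ground-truth interface model + generating composition for a named case."""
    fragments = {"OA": comp.OLEIC_ACID, "PS80": comp.POLYSORBATE_80}

    if tag in ("OA-monolayer", "OA-monolayer-compressed"):
        if tag == "OA-monolayer":
            slabs = (Slab(10.63, 0.312), Slab(5.025, 0.350))
            sigma = 3.594
        else:
            slabs = (Slab(11.64, 0.303), Slab(6.0, 0.357))
            sigma = 3.758
        model = InterfaceModel(slabs=slabs, shared_sigma=sigma)
        oa = comp.OLEIC_ACID
        partition = {
            "OA": [oa.electrons_tail / oa.electrons_total,
                   oa.electrons_head / oa.electrons_total],
            "water": [0.0, 1.0],
        }
        sol = comp.mixed_layer_composition(slabs, {"OA": oa}, partition)
        return ScenarioTruth(tag=tag, model=model, composition=sol.composition,
                             partition=partition, fragments={"OA": oa})

    if tag == "PS80-layer":
        ps = comp.POLYSORBATE_80
        counts = {"PS80": _counts_from_gamma(_PS80_GAMMAS[0], ps.molar_mass)}
        water = _counts_from_gamma(_PS80_GAMMAS[1], comp.WATER_MOLAR_MASS)
        # tails plus a quarter of the head electrons sit in the compact first
        # layer; the remaining ethoxylates extend into the hydrated second one
        head_in_1 = 0.25
        f1 = (ps.electrons_tail + head_in_1 * ps.electrons_head) / ps.electrons_total
        partition = {"PS80": [f1, 1 - f1], "water": [0.15, 0.85]}
        thick = [14.0, 20.0]
        model = stack_from_composition(counts, water, {"PS80": ps}, partition,
                                       thick, sigma=3.5)
        sol = comp.mixed_layer_composition(model.slabs, {"PS80": ps}, partition)
        return ScenarioTruth(tag=tag, model=model, composition=sol.composition,
                             partition=partition, fragments={"PS80": ps})

    if tag == "mixed-3-slab":
        oa, ps = comp.OLEIC_ACID, comp.POLYSORBATE_80
        counts = {
            "OA": _counts_from_gamma(_MIXED_GAMMAS[0], oa.molar_mass),
            "PS80": _counts_from_gamma(_MIXED_GAMMAS[1], ps.molar_mass),
        }
        water = _counts_from_gamma(_MIXED_GAMMAS[2], comp.WATER_MOLAR_MASS)
        # slab 1: OA + PS80 tails; slab 2: OA heads + part of the PS80 head,
        # hydrated; slab 3: remaining PS80 ethoxylates, strongly hydrated
        f_oa = [oa.electrons_tail / oa.electrons_total,
                oa.electrons_head / oa.electrons_total, 0.0]
        head2 = 0.4
        f_ps = [
            ps.electrons_tail / ps.electrons_total,
            head2 * ps.electrons_head / ps.electrons_total,
            (1 - head2) * ps.electrons_head / ps.electrons_total,
        ]
        partition = {"OA": f_oa, "PS80": f_ps, "water": [0.0, 0.35, 0.65]}
        thick = [12.0, 10.0, 18.0]
        model = stack_from_composition(counts, water, fragments, partition,
                                       thick, sigma=3.5)
        sol = comp.mixed_layer_composition(model.slabs, fragments, partition)
        return ScenarioTruth(tag=tag, model=model, composition=sol.composition,
                             partition=partition, fragments=fragments)

    raise ValueError(
        f"unknown scenario {tag!r}; known tags: OA-monolayer, "
        "OA-monolayer-compressed, PS80-layer, mixed-3-slab"
    )


def make_isotherm_data(
    truth: dict,
    spec: SyntheticSpec,
    *,
    concentrations_mm: np.ndarray | None = None,
    noise: float = 0.3,
    gamma0: float = 72.5,
    temperature: float = 296.15,
) -> TensionIsotherm:
    """Synthetic equilibrium-tension data: Szyszkowski below the cmc, flat above.

    ``truth`` holds ``gamma_inf`` (mol/m²), ``a`` (mol/L) and ``cmc`` (mM).
    The default concentration ladder is 12 log-spaced points over
    0.0012–0.12 mM: a realistic pendant-drop dilution series spanning the
    measured range with enough sub-cmc points to constrain the two-parameter
    fit (the 5-concentration reflectivity ladder has only three).
    """
    if concentrations_mm is None:
        concentrations_mm = np.geomspace(0.0012, 0.12, 12)
    c_mm = np.asarray(concentrations_mm, dtype=float)
    c_molar = c_mm * 1e-3
    cmc_molar = truth["cmc"] * 1e-3
    gamma_cmc = szyszkowski_tension(cmc_molar, gamma0, truth["gamma_inf"],
                                    truth["a"], temperature)
    g = np.where(
        c_molar <= cmc_molar,
        szyszkowski_tension(c_molar, gamma0, truth["gamma_inf"], truth["a"],
                            temperature),
        gamma_cmc,
    )
    if noise > 0:
        g = g + spec.rng().normal(0.0, noise, size=g.size)
    sd = np.full_like(g, max(noise, 1e-6))
    return TensionIsotherm(concentration=c_mm, gamma=g, sd=sd, gamma0=gamma0,
                           temperature=temperature)


def make_relaxation_trace(
    gamma_eq: float,
    gamma0: float,
    timescale: float,
    spec: SyntheticSpec,
    *,
    exponent: float = 1.0,
    t_max: float = 10000.0,
    n_points: int = 400,
    noise: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical monotone tension relaxation toward equilibrium.

    gamma(t) = gamma_eq + (gamma0 - gamma_eq) / (1 + (t/tau)^p), a stand-in
    used only to exercise the plateau-extraction rule; no kinetic model is
    implied.
    """
    if not gamma_eq < gamma0:
        raise ValueError("gamma_eq must be below gamma0")
    t = np.linspace(0.0, t_max, n_points)
    g = gamma_eq + (gamma0 - gamma_eq) / (1.0 + (t / timescale) ** exponent)
    if noise > 0:
        g = g + spec.rng().normal(0.0, noise, size=g.size)
    return t, g
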