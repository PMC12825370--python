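"""Langmuir/Szyszkowski analysis of equilibrium surface tension data.

Below the critical micelle concentration (cmc) the equilibrium tension of a
nonionic surfactant solution follows the Szyszkowski equation, the tension
law conjugate to the Langmuir adsorption isotherm::

    gamma(c) = gamma0 - R T Gamma_inf ln(1 + c/a)

with Gamma_inf the maximum surface coverage (mol/m²) and a the adsorption
constant (mol/L).  Above the cmc added surfactant goes into micelles and the
tension plateaus.  The cmc is located as the breakpoint of a continuous
two-segment piecewise-linear fit of gamma vs ln c — reproducible where the
visual "becomes independent of concentration" criterion is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .constants import DEFAULT_TEMPERATURE, GAMMA0_WATER, R_GAS

__all__ = [
    "TensionIsotherm",
    "IsothermFit",
    "szyszkowski_tension",
    "langmuir_coverage",
    "surface_pressure",
    "equilibrium_tension",
    "fit_isotherm",
]


@dataclass(frozen=True)
class TensionIsotherm:
    """Equilibrium tension (mN/m) vs bulk concentration (mM) data."""

    concentration: np.ndarray          # mM
    gamma: np.ndarray                  # mN/m
    sd: np.ndarray | None = None       # mN/m
    gamma0: float = GAMMA0_WATER
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        if c.ndim != 1 or c.shape != g.shape:
            raise ValueError("concentration and gamma must be equal-length 1-D arrays")
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0")
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "gamma", g)
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if sd.shape != g.shape or np.any(sd < 0):
                raise ValueError("sd must match gamma and be >= 0")
            object.__setattr__(self, "sd", sd)
            if np.any(g > self.gamma0 + 3 * sd):
                raise ValueError("tension exceeds the clean-interface baseline")
        elif np.any(g > self.gamma0 + 1.0):
            raise ValueError("tension exceeds the clean-interface baseline")


@dataclass(frozen=True)
class IsothermFit:
    """Fitted Langmuir/Szyszkowski parameters with standard errors."""

    gamma_inf_mol: float               # mol/m²
    gamma_inf_mg: float                # mg/m²
    a: float                           # mol/L
    cmc: float | None                  # mM; None when no plateau was found
    gamma_inf_mol_sd: float = 0.0
    a_sd: float = 0.0
    cmc_sd: float = 0.0
    molar_mass: float = 1310.0
    gamma0: float = GAMMA0_WATER
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def cmc_determined(self) -> bool:
        return self.cmc is not None


def szyszkowski_tension(
    c: "float | np.ndarray",
    gamma0: float,
    gamma_inf: float,
    a: float,
    temperature: float = DEFAULT_TEMPERATURE,
):
    """Szyszkowski tension (mN/m) at bulk concentration c (mol/L).

    gamma_inf is in mol/m²; R T Gamma_inf converts to mN/m via 1 N/m =
    1e3 mN/m.
    """
    if gamma0 <= 0 or gamma_inf <= 0 or a <= 0 or temperature <= 0:
        raise ValueError("all Szyszkowski parameters must be > 0")
    c = np.asarray(c, dtype=float)
    out = gamma0 - R_GAS * temperature * gamma_inf * 1e3 * np.log1p(c / a)
    return out if out.ndim else float(out)


def langmuir_coverage(c: "float | np.ndarray", a: float):
    """Fractional Langmuir coverage theta = c / (a + c)."""
    if a <= 0:
        raise ValueError("adsorption constant must be > 0")
    c = np.asarray(c, dtype=float)
    out = c / (a + c)
    return out if out.ndim else float(out)


def surface_pressure(gamma, gamma0: float = GAMMA0_WATER):
    """Surface pressure Pi = gamma0 - gamma (mN/m)."""
    out = np.asarray(gamma0, dtype=float) - np.asarray(gamma, dtype=float)
    return out if out.ndim else float(out)


def equilibrium_tension(t: np.ndarray, gamma: np.ndarray, window: float = 0.1) -> float:
    """Equilibrium tension from a relaxation trace: mean of the final window.

    ``window`` is the trailing fraction of the time span used (default the
    last 10%, where the tension has plateaued).
    """
    t = np.asarray(t, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if not 0 < window <= 1:
        raise ValueError("window must lie in (0, 1]")
    t0 = t[-1] - window * (t[-1] - t[0])
    tail = gamma[t >= t0]
    return float(tail.mean())


def _breakpoint_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Continuous two-segment linear fit of y(x); returns (b, sse, s1, s2)."""

    def fit_at(b: float):
        left = np.minimum(x - b, 0.0)
        right = np.maximum(x - b, 0.0)
        design = np.column_stack([np.ones_like(x), left, right]) * w[:, None]
        coef, *_ = np.linalg.lstsq(design, y * w, rcond=None)
        sse = float(np.sum((design @ coef - y * w) ** 2))
        return sse, coef

    # profile the breakpoint on a grid between interior points, then refine
    grid = np.linspace(x[1], x[-2], 200)
    sses = [fit_at(b)[0] for b in grid]
    b0 = grid[int(np.argmin(sses))]

    def resid(p):
        sse, _ = fit_at(p[0])
        return [np.sqrt(sse)]

    sol = least_squares(resid, [b0], bounds=([x[1]], [x[-2]]),
                        diff_step=1e-4, xtol=1e-14, ftol=1e-14)
    b = float(sol.x[0])
    sse, coef = fit_at(b)
    return b, sse, float(coef[1]), float(coef[2])


def fit_isotherm(
    iso: TensionIsotherm,
    *,
    molar_mass: float = 1310.0,
    fit_gamma0: bool = False,
    plateau_slope_ratio: float = 0.25,
) -> IsothermFit:
    """Fit (Gamma_inf, a) below the cmc and locate the cmc breakpoint.

    The cmc comes from a continuous two-segment piecewise-linear fit of gamma
    vs ln c; a plateau is accepted when the upper segment is much flatter
    than the descending branch (|s2| < ``plateau_slope_ratio``·|s1|).  The
    Szyszkowski parameters are then fitted by weighted least squares to the
    sub-cmc points.  When no plateau is found the cmc is reported as None and
    all points are used for the parameter fit.
    """
    c_molar = iso.concentration * 1e-3  # mM -> mol/L (1 mM = 1e-3 mol/L)
    x = np.log(c_molar)
    w = 1.0 / iso.sd if iso.sd is not None and np.all(iso.sd > 0) else np.ones_like(x)

    cmc = None
    cmc_sd = 0.0
    if len(x) >= 5:
        b, _, s1, s2 = _breakpoint_fit(x, iso.gamma, w)
        interior = x[1] + 1e-9 < b < x[-2] - 1e-9
        if interior and s1 < 0 and abs(s2) < plateau_slope_ratio * abs(s1):
            cmc = float(np.exp(b) * 1e3)  # mol/L -> mM

    mask = (
        c_molar <= cmc * 1e-3 * (1 + 1e-9) if cmc is not None
        else np.ones_like(c_molar, dtype=bool)
    )
    if mask.sum() < 5:
        raise ValueError("need at least 5 points below the plateau to fit the isotherm")

    c_fit, g_fit = c_molar[mask], iso.gamma[mask]
    sd_fit = iso.sd[mask] if iso.sd is not None and np.all(iso.sd > 0) else None

    if fit_gamma0:
        def f(c, g0, lg_inf, lg_a):
            return szyszkowski_tension(c, g0, np.exp(lg_inf), np.exp(lg_a),
                                       iso.temperature)
        p0 = [iso.gamma0, np.log(2e-6), np.log(c_fit[0] / 10)]
    else:
        def f(c, lg_inf, lg_a):
            return szyszkowski_tension(c, iso.gamma0, np.exp(lg_inf), np.exp(lg_a),
                                       iso.temperature)
        p0 = [np.log(2e-6), np.log(c_fit[0] / 10)]

    popt, pcov = curve_fit(f, c_fit, g_fit, p0=p0, sigma=sd_fit,
                           absolute_sigma=sd_fit is not None, maxfev=20000)
    perr = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    off = 1 if fit_gamma0 else 0
    gamma_inf = float(np.exp(popt[off]))
    a = float(np.exp(popt[off + 1]))
    return IsothermFit(
        gamma_inf_mol=gamma_inf,
        gamma_inf_mg=gamma_inf * molar_mass * 1e3,
        a=a,
        cmc=cmc,
        gamma_inf_mol_sd=gamma_inf * float(perr[off]),
        a_sd=a * float(perr[off + 1]),
        cmc_sd=cmc_sd,
        molar_mass=molar_mass,
        gamma0=float(popt[0]) if fit_gamma0 else iso.gamma0,
        temperature=iso.temperature,
    )
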