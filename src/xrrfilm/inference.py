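"""Fitting slab models to reflectivity curves and quantifying uncertainty.

The likelihood is Gaussian in log-reflectivity: reflectivity spans many
decades, and working on log R weights every interference fringe about
equally instead of letting the near-total-reflection region dominate.  For
small relative errors the log-space noise scale equals the relative error
dr/r of the data.

A bounded least-squares fit provides the point estimate; an affine-invariant
ensemble sampler (emcee) then explores the posterior.  Parameter errors are
reported from the 16th/84th posterior percentiles about the median, quoting
the larger of the two asymmetric bounds as the conservative error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import emcee
import numpy as np
from scipy.optimize import least_squares

from .reflectivity import ReflectivityCurve, parratt_reflectivity
from .slab_model import InterfaceModel, Slab

__all__ = [
    "FitSpec",
    "FitResult",
    "PosteriorSummary",
    "fit_least_squares",
    "sample_posterior",
    "propagate_independent",
]


def _shared_sigma_builder(n_slabs: int, rho_air: float, rho_subphase: float
                          ) -> Callable[[np.ndarray], InterfaceModel]:
    def build(x: np.ndarray) -> InterfaceModel:
        slabs = tuple(
            Slab(thickness=x[2 * i], rho=x[2 * i + 1], sigma=x[-1])
            for i in range(n_slabs)
        )
        return InterfaceModel(
            slabs=slabs, rho_air=rho_air, rho_subphase=rho_subphase,
            shared_sigma=float(x[-1]),
        )
    return build


@dataclass
class FitSpec:
    """Free parameters, bounds, noise model and sampler settings for a fit.

    ``build`` maps a parameter vector onto an :class:`InterfaceModel`.  The
    default constructor :meth:`for_slab_stack` fits each slab's (d, rho) plus
    one roughness shared by all interfaces — the parameterization used for
    one-sigma-per-sample reflectivity fits.
    """

    param_names: Sequence[str]
    x0: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    build: Callable[[np.ndarray], InterfaceModel]
    noise_scale: float = 0.02     # relative error of r, used when dr absent
    seed: int = 0
    n_walkers: int | None = None  # default 4 x ndim
    n_steps: int = 1000
    burn_fraction: float = 0.25

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        n = len(self.param_names)
        if not (self.x0.size == self.lower.size == self.upper.size == n):
            raise ValueError("param_names, x0 and bounds must have equal length")
        if not np.all(np.isfinite(self.lower)) or not np.all(np.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")
        if np.any(self.x0 < self.lower) or np.any(self.x0 > self.upper):
            raise ValueError("initial values must lie within bounds")
        if self.n_walkers is None:
            self.n_walkers = 4 * n
        if self.n_walkers < 2 * n or self.n_walkers % 2:
            raise ValueError("need an even number of walkers, at least 2 per parameter")

    @property
    def ndim(self) -> int:
        return len(self.param_names)

    @classmethod
    def for_slab_stack(
        cls,
        init: InterfaceModel,
        *,
        rel_window: float = 0.5,
        sigma_bounds: tuple[float, float] = (0.5, 10.0),
        rho_bounds: tuple[float, float] = (0.05, 0.6),
        **kwargs,
    ) -> "FitSpec":
        """Fit spec for an n-slab stack with one shared roughness.

        Bounds default to a +/- ``rel_window`` window around the initial
        thicknesses and to fixed physical windows for densities and sigma.
        """
        names: list[str] = []
        x0: list[float] = []
        lo: list[float] = []
        hi: list[float] = []
        for i, s in enumerate(init.slabs, start=1):
            names += [f"d{i}", f"rho{i}"]
            x0 += [s.thickness, s.rho]
            lo += [s.thickness * (1 - rel_window), rho_bounds[0]]
            hi += [s.thickness * (1 + rel_window), rho_bounds[1]]
        names.append("sigma")
        sigma0 = float(init.interface_sigmas.max())
        x0.append(np.clip(sigma0, *sigma_bounds))
        lo.append(sigma_bounds[0])
        hi.append(sigma_bounds[1])
        build = _shared_sigma_builder(init.n_slabs, init.rho_air, init.rho_subphase)
        return cls(param_names=names, x0=np.array(x0), lower=np.array(lo),
                   upper=np.array(hi), build=build, **kwargs)


@dataclass
class FitResult:
    model: InterfaceModel
    x: np.ndarray
    chisq: float
    chisq_dof: float
    success: bool
    message: str
    at_bounds: list[str] = field(default_factory=list)
    jac: np.ndarray | None = None   # scaled Jacobian at the optimum


@dataclass
class PosteriorSummary:
    """Per-parameter posterior medians with asymmetric 16/84 percentile errors."""

    param_names: Sequence[str]
    median: np.ndarray
    err_lower: np.ndarray   # median - 16th percentile
    err_upper: np.ndarray   # 84th percentile - median
    acceptance_fraction: float
    flat_chain: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def err(self) -> np.ndarray:
        """Conservative symmetric error: the larger of the two bounds."""
        return np.maximum(self.err_lower, self.err_upper)

    def interval(self, name: str) -> tuple[float, float]:
        i = list(self.param_names).index(name)
        return (
            float(self.median[i] - self.err_lower[i]),
            float(self.median[i] + self.err_upper[i]),
        )

    def covers(self, name: str, value: float) -> bool:
        lo, hi = self.interval(name)
        return lo <= value <= hi


def _log_sigma(curve: ReflectivityCurve, spec: FitSpec) -> np.ndarray:
    if curve.dr is not None and np.all(curve.dr > 0):
        return curve.dr / curve.r
    return np.full(len(curve), spec.noise_scale)


def _residuals(x: np.ndarray, curve: ReflectivityCurve, spec: FitSpec,
               sig_log: np.ndarray) -> np.ndarray:
    model = spec.build(x)
    r_model = parratt_reflectivity(model, curve.qz).r
    r_model = np.maximum(r_model, 1e-300)
    return (np.log(r_model) - np.log(curve.r)) / sig_log


def fit_least_squares(curve: ReflectivityCurve, spec: FitSpec) -> FitResult:
    """Bounded least squares on log reflectivity; the MCMC starting point."""
    if curve.normalized:
        raise ValueError("fit expects an unnormalized reflectivity curve")
    if len(curve) < 3 * spec.ndim:
        raise ValueError("need at least 3 data points per free parameter")
    sig_log = _log_sigma(curve, spec)
    res = least_squares(
        _residuals, spec.x0, bounds=(spec.lower, spec.upper),
        args=(curve, spec, sig_log), method="trf", xtol=1e-12, ftol=1e-12,
    )
    chisq = float(2 * res.cost)
    dof = max(len(curve) - spec.ndim, 1)
    at_bounds = [
        n for n, xi, lo, hi in zip(spec.param_names, res.x, spec.lower, spec.upper)
        if np.isclose(xi, lo, rtol=1e-6) or np.isclose(xi, hi, rtol=1e-6)
    ]
    if not res.success:
        warnings.warn(f"least-squares fit did not converge: {res.message}")
    return FitResult(
        model=spec.build(res.x), x=res.x, chisq=chisq, chisq_dof=chisq / dof,
        success=bool(res.success), message=res.message, at_bounds=at_bounds,
        jac=res.jac,
    )


def _ridge_walker_init(
    curve: ReflectivityCurve,
    spec: FitSpec,
    start: FitResult,
    sig_log: np.ndarray,
    rng: np.random.RandomState,
) -> np.ndarray:
    """Seed walkers along the least-identified direction of the posterior.

    Thin-slab stacks at capillary roughness have a long, curved likelihood
    valley (e.g. the split of a total thickness between two slabs that the
    smoothing blurs together).  An ensemble started in a tiny ball around the
    optimum takes thousands of steps to diffuse along that valley, so the
    flattest parameter (largest Laplace standard deviation relative to its
    bound width) is profiled instead: it is pinned on a grid spanning its
    bounds, the remaining parameters are re-optimized at each pin, and the
    walkers are drawn from the profiled points weighted by their likelihood.
    """
    if start.jac is None:
        raise ValueError("ridge initialization needs the least-squares Jacobian")
    jtj = start.jac.T @ start.jac
    try:
        sd = np.sqrt(np.maximum(np.diag(np.linalg.inv(jtj)), 0.0))
    except np.linalg.LinAlgError:
        sd = spec.upper - spec.lower
    p = int(np.argmax(sd / (spec.upper - spec.lower)))

    grid = np.linspace(spec.lower[p], spec.upper[p], 14)
    order = np.argsort(np.abs(grid - start.x[p]))  # profile outward, warm-started
    sols = np.empty((grid.size, spec.ndim))
    chis = np.empty(grid.size)
    done: list[int] = []
    for gi in order:
        u = grid[gi]
        lo, hi = spec.lower.copy(), spec.upper.copy()
        lo[p], hi[p] = u - 1e-9, u + 1e-9
        nearest = min(done, key=lambda g: abs(grid[g] - u)) if done else None
        x0 = np.clip(sols[nearest] if nearest is not None else start.x, lo, hi)
        res = least_squares(
            _residuals, x0, bounds=(lo, hi), args=(curve, spec, sig_log),
            method="trf", xtol=1e-10, ftol=1e-10, max_nfev=80,
        )
        sols[gi], chis[gi] = res.x, 2.0 * res.cost
        done.append(gi)

    dchi = chis - start.chisq
    keep = np.flatnonzero(dchi < 9.0)   # 3-sigma-equivalent along the profile
    if keep.size == 0:
        keep = np.array([int(np.argmin(dchi))])
    wts = np.exp(-0.5 * dchi[keep])
    picks = rng.choice(keep, size=spec.n_walkers, p=wts / wts.sum())
    scale = np.maximum(np.abs(start.x), 1e-3)
    p0 = sols[picks] + 0.01 * scale * rng.randn(spec.n_walkers, spec.ndim)
    return np.clip(p0, spec.lower + 1e-9, spec.upper - 1e-9)


def sample_posterior(
    curve: ReflectivityCurve, spec: FitSpec, start: FitResult
) -> PosteriorSummary:
    """Ensemble MCMC around a least-squares optimum; seeded and reproducible.

    Walkers are seeded along the profiled likelihood ridge (see
    :func:`_ridge_walker_init`) so that weakly identified directions are
    explored from the first step instead of by slow diffusion.
    """
    sig_log = _log_sigma(curve, spec)

    def log_prob(x: np.ndarray) -> float:
        if np.any(x < spec.lower) or np.any(x > spec.upper):
            return -np.inf
        r = _residuals(x, curve, spec, sig_log)
        return -0.5 * float(r @ r)

    rng = np.random.RandomState(spec.seed)
    if start.jac is not None and spec.ndim > 1:
        p0 = _ridge_walker_init(curve, spec, start, sig_log, rng)
    else:
        scale = np.maximum(np.abs(start.x), 1e-3)
        p0 = start.x + 1e-4 * scale * rng.randn(spec.n_walkers, spec.ndim)
        p0 = np.clip(p0, spec.lower, spec.upper)

    # differential-evolution moves mix far better than stretch moves along
    # the curved degenerate valleys of thin-slab stacks
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(spec.n_walkers, spec.ndim, log_prob,
                                    moves=moves)
    sampler.random_state = rng.get_state()
    sampler.run_mcmc(p0, spec.n_steps, progress=False)

    burn = int(spec.burn_fraction * spec.n_steps)
    flat = sampler.get_chain(discard=burn, flat=True)
    q16, q50, q84 = np.percentile(flat, [16, 50, 84], axis=0)
    acc = float(np.mean(sampler.acceptance_fraction))
    warns: list[str] = []
    if not 0.1 <= acc <= 0.7:
        warns.append(f"acceptance fraction {acc:.3f} outside [0.1, 0.7]")
    return PosteriorSummary(
        param_names=spec.param_names, median=q50,
        err_lower=q50 - q16, err_upper=q84 - q50,
        acceptance_fraction=acc, flat_chain=flat, warnings=warns,
    )


def propagate_independent(
    values: Sequence[tuple[float, float]],
    func: Callable[..., float],
    *,
    rel_step: float = 1e-6,
) -> tuple[float, float]:
    """First-order error propagation assuming independent inputs.

    sd_out = sqrt(sum (df/dx_i)^2 sd_i^2) with derivatives from central
    finite differences at a relative step of ``rel_step`` (absolute step of
    the same size when an input is zero).
    """
    x = np.array([v for v, _ in values], dtype=float)
    sd = np.array([s for _, s in values], dtype=float)
    if np.any(sd < 0):
        raise ValueError("standard deviations must be >= 0")
    f0 = float(func(*x))
    var = 0.0
    for i in range(x.size):
        if sd[i] == 0:
            continue
        h = rel_step * abs(x[i]) if x[i] != 0 else rel_step
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        grad = (float(func(*xp)) - float(func(*xm))) / (2 * h)
        var += (grad * sd[i]) ** 2
    return f0, float(np.sqrt(var))
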