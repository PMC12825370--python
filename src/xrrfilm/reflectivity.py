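"""Specular reflectivity of a slab stack: Parratt recursion and Fresnel law.

All wave-vector transfers ``qz`` are in Å⁻¹.  Absorption is neglected (the
imaginary part of the scattering density is zero): at hard-X-ray wavelengths
around 1.3 Å, organic films and water absorb too weakly to affect specular
curves below qz ~ 1 Å⁻¹.

Roughness enters through Névot–Croce damping of each interface's Fresnel
coefficient.  When slabs are thin compared with the roughness
(max sigma > min d / 2 by default) the recursion is instead run on a fine
slicing of the error-function profile, where no damping factors are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import R_E
from .slab_model import InterfaceModel, Slab, build_edp

__all__ = [
    "BeamGeometry",
    "ReflectivityCurve",
    "qz_from_alpha",
    "alpha_from_qz",
    "critical_qz",
    "fresnel",
    "parratt_reflectivity",
    "normalize_to_fresnel",
    "denormalize_from_fresnel",
]


@dataclass(frozen=True)
class BeamGeometry:
    """X-ray wavelength (Å) and incidence angle (rad) of the specular scan."""

    wavelength: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError("wavelength must be > 0")
        if not (0 <= self.alpha < np.pi / 2):
            raise ValueError("alpha must lie in [0, pi/2)")

    @property
    def qz(self) -> float:
        return qz_from_alpha(self.alpha, self.wavelength)


@dataclass(frozen=True)
class ReflectivityCurve:
    """Reflectivity (or Fresnel-normalized reflectivity) on a qz grid."""

    qz: np.ndarray
    r: np.ndarray
    dr: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        qz = np.asarray(self.qz, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if qz.ndim != 1 or qz.shape != r.shape:
            raise ValueError("qz and r must be equal-length 1-D arrays")
        if not np.all(qz > 0) or not np.all(np.diff(qz) > 0):
            raise ValueError("qz must be strictly increasing and positive")
        if np.any(r < 0):
            raise ValueError("reflectivity must be >= 0")
        object.__setattr__(self, "qz", qz)
        object.__setattr__(self, "r", r)
        if self.dr is not None:
            dr = np.asarray(self.dr, dtype=float)
            if dr.shape != r.shape:
                raise ValueError("dr must match r in shape")
            if np.any(dr < 0):
                raise ValueError("dr must be >= 0")
            object.__setattr__(self, "dr", dr)

    def __len__(self) -> int:
        return self.qz.size


def qz_from_alpha(alpha, wavelength: float):
    """Wave-vector transfer qz = (4 pi / lambda) sin(alpha), in Å⁻¹."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > np.pi / 2):
        raise ValueError("alpha must lie in [0, pi/2]")
    if not wavelength > 0:
        raise ValueError("wavelength must be > 0")
    out = 4.0 * np.pi / wavelength * np.sin(alpha)
    return out if out.ndim else float(out)


def alpha_from_qz(qz, wavelength: float):
    """Inverse of :func:`qz_from_alpha`."""
    qz = np.asarray(qz, dtype=float)
    if np.any(qz < 0):
        raise ValueError("qz must be >= 0")
    s = qz * wavelength / (4.0 * np.pi)
    if np.any(s > 1):
        raise ValueError("qz out of range for this wavelength")
    out = np.arcsin(s)
    return out if out.ndim else float(out)


def critical_qz(rho_subphase: float, rho_air: float = 0.0) -> float:
    """Critical wave vector q_c = 4 sqrt(pi r_e (rho_sub - rho_air)), Å⁻¹."""
    if not rho_subphase > rho_air:
        raise ValueError("rho_subphase must exceed rho_air")
    return 4.0 * np.sqrt(np.pi * R_E * (rho_subphase - rho_air))


def fresnel(qz, rho_subphase: float, rho_air: float = 0.0):
    """Fresnel reflectivity of the ideally sharp bare interface.

    Below q_c the transmitted wave is evanescent and R_F = 1 (total external
    reflection); the complex square root handles that branch automatically.
    """
    qz = np.asarray(qz, dtype=float)
    qc = critical_qz(rho_subphase, rho_air)
    kz = np.sqrt(qz.astype(complex) ** 2 - qc**2)
    rf = np.abs((qz - kz) / (qz + kz)) ** 2
    return rf if rf.ndim else float(rf)


def _kz_matrix(qz: np.ndarray, rhos: np.ndarray) -> np.ndarray:
    """kz in each medium referenced to the incident (air) medium."""
    q2 = qz.astype(complex) ** 2
    return 0.5 * np.sqrt(q2[None, :] - 16.0 * np.pi * R_E * (rhos[:, None] - rhos[0]))


def _recursion_numpy(qz: np.ndarray, rhos: np.ndarray, thicknesses: np.ndarray,
                     sigma_sq: np.ndarray) -> np.ndarray:
    """Pure-numpy Parratt recursion (fallback when numba is unavailable)."""
    kz = _kz_matrix(qz, rhos)
    n_if = kz.shape[0] - 1
    # all interface Fresnel coefficients and layer phases up front
    r_all = (kz[:-1] - kz[1:]) / (kz[:-1] + kz[1:])
    if sigma_sq.any():
        r_all = r_all * np.exp(-2.0 * kz[:-1] * kz[1:] * sigma_sq[:, None])
    r_tot = r_all[n_if - 1]
    # walk interfaces from the bottom (film/subphase) up to the top (air/film)
    for j in range(n_if - 2, -1, -1):
        t = r_tot * np.exp(2j * kz[j + 1] * thicknesses[j])
        r_tot = (r_all[j] + t) / (1.0 + r_all[j] * t)
    return np.abs(r_tot) ** 2


try:  # jitted recursion: fine-sliced profiles run over hundreds of interfaces
    from numba import njit

    @njit(cache=True)
    def _recursion_jit(qz, rhos, thicknesses, sigma_sq):  # pragma: no cover
        n_if = rhos.shape[0] - 1
        nq = qz.shape[0]
        c = 16.0 * np.pi * R_E
        out = np.empty(nq)
        kz = np.empty(rhos.shape[0], dtype=np.complex128)
        for iq in range(nq):
            q2 = qz[iq] * qz[iq]
            for m in range(rhos.shape[0]):
                x = q2 - c * (rhos[m] - rhos[0])
                if x >= 0.0:
                    kz[m] = 0.5 * np.sqrt(x)
                else:
                    kz[m] = 0.5j * np.sqrt(-x)
            r_tot = 0.0 + 0.0j
            for j in range(n_if - 1, -1, -1):
                ka = kz[j]
                kb = kz[j + 1]
                rj = (ka - kb) / (ka + kb)
                if sigma_sq[j] != 0.0:
                    rj = rj * np.exp(-2.0 * ka * kb * sigma_sq[j])
                if j == n_if - 1:
                    r_tot = rj
                else:
                    t = r_tot * np.exp(2j * kb * thicknesses[j])
                    r_tot = (rj + t) / (1.0 + rj * t)
            out[iq] = abs(r_tot) ** 2
        return out

    _recursion = _recursion_jit
except Exception:  # pragma: no cover
    _recursion = _recursion_numpy


def _parratt(qz: np.ndarray, rhos: np.ndarray, thicknesses: np.ndarray,
             sigmas: np.ndarray) -> np.ndarray:
    """Parratt recursion for |R|² over a qz grid.

    ``rhos``: densities of the N+2 media, air first.  ``thicknesses``: the N
    internal layers.  ``sigmas``: one roughness per interface (N+1).
    """
    r = _recursion(
        np.ascontiguousarray(qz, dtype=np.float64),
        np.ascontiguousarray(rhos, dtype=np.float64),
        np.ascontiguousarray(thicknesses, dtype=np.float64),
        np.ascontiguousarray(np.asarray(sigmas, dtype=np.float64) ** 2),
    )
    # Névot–Croce factors amplify slightly in the total-reflection region
    # where kz is imaginary; cap at the energy bound.
    return np.minimum(r, 1.0)


def _slice_arrays(
    model: InterfaceModel, slice_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Render the smoothed profile as (thicknesses, densities) of sharp slices."""
    pad = 5.0 * float(model.interface_sigmas.max()) + slice_width
    z0, z1 = -pad, model.total_thickness + pad
    n = max(int(np.ceil((z1 - z0) / slice_width)), 8)
    edges = np.linspace(z0, z1, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    grid = np.concatenate([[z0 - pad], centers, [z1 + pad]])
    rho = np.maximum(build_edp(model, grid).rho[1:-1], 0.0)
    d = np.full(n, edges[1] - edges[0])
    return d, rho


def parratt_reflectivity(
    model: InterfaceModel,
    qz,
    *,
    use_slicing: bool | None = None,
    slice_width: float = 0.25,
    thin_slab_sigma_ratio: float = 0.5,
) -> ReflectivityCurve:
    """Specular reflectivity |R(qz)|² of a slab stack.

    With an empty stack this reduces exactly to :func:`fresnel`.  By default
    Névot–Croce roughness factors are used; if any roughness exceeds
    ``thin_slab_sigma_ratio`` times the thinnest slab (where the damping
    approximation degrades) the calculation automatically switches to a fine
    slicing of the error-function profile.  ``use_slicing`` forces either
    route.
    """
    qz = np.atleast_1d(np.asarray(qz, dtype=float))
    if np.any(qz <= 0):
        raise ValueError("qz must be > 0")

    if use_slicing is None:
        use_slicing = bool(
            model.slabs
            and model.interface_sigmas.max()
            > thin_slab_sigma_ratio * min(s.thickness for s in model.slabs)
        )
    if use_slicing and model.interface_sigmas.max() > 0:
        d, rho_layers = _slice_arrays(model, slice_width)
        rhos = np.concatenate([[model.rho_air], rho_layers, [model.rho_subphase]])
        sigmas = np.zeros(d.size + 1)
    else:
        d = np.array([s.thickness for s in model.slabs], dtype=float)
        rhos = model.layer_rhos
        sigmas = model.interface_sigmas
    r = _parratt(qz, rhos, d, sigmas)
    return ReflectivityCurve(qz=qz, r=r, normalized=False)


def normalize_to_fresnel(
    curve: ReflectivityCurve, model: InterfaceModel
) -> ReflectivityCurve:
    """Divide a measured/computed curve by the bare-interface Fresnel law."""
    if curve.normalized:
        raise ValueError("curve is already Fresnel-normalized")
    rf = fresnel(curve.qz, model.rho_subphase, model.rho_air)
    dr = curve.dr / rf if curve.dr is not None else None
    return replace(curve, r=curve.r / rf, dr=dr, normalized=True)


def denormalize_from_fresnel(
    curve: ReflectivityCurve, model: InterfaceModel
) -> ReflectivityCurve:
    """Inverse of :func:`normalize_to_fresnel`."""
    if not curve.normalized:
        raise ValueError("curve is not Fresnel-normalized")
    rf = fresnel(curve.qz, model.rho_subphase, model.rho_air)
    dr = curve.dr * rf if curve.dr is not None else None
    return replace(curve, r=curve.r * rf, dr=dr, normalized=False)
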