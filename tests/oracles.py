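"""Independent reference implementations used only to cross-check the package.

The reflectivity oracle is an Abelès characteristic-matrix calculation on a
fine sharp-slab rendering of the error-function profile — a different
algorithm (2x2 matrix products) from the package's Parratt recursion, with
roughness realized geometrically instead of through damping factors.
"""

from __future__ import annotations

import numpy as np

from xrrfilm.constants import R_E
from xrrfilm.slab_model import InterfaceModel, build_edp

FOUR_PI_RE = 16.0 * np.pi * R_E  # factor in kz^2 = (q/2)^2 - 4 pi r_e drho


def slice_profile(model: InterfaceModel, width: float = 0.2):
    """Render the smoothed profile as (thicknesses, densities) micro-slabs."""
    pad = 5.0 * float(model.interface_sigmas.max()) + width
    z0, z1 = -pad, model.total_thickness + pad
    n = max(int(np.ceil((z1 - z0) / width)), 8)
    edges = np.linspace(z0, z1, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    grid = np.concatenate([[z0 - pad], centers, [z1 + pad]])
    rho = build_edp(model, grid).rho[1:-1]
    d = np.full(n, edges[1] - edges[0])
    return d, rho


def matrix_reflectivity(
    qz: np.ndarray,
    thicknesses: np.ndarray,
    rhos: np.ndarray,
    rho_air: float,
    rho_subphase: float,
) -> np.ndarray:
    """|R(qz)|^2 by Abelès 2x2 characteristic matrices over sharp layers."""
    qz = np.asarray(qz, dtype=float)
    all_rho = np.concatenate([[rho_air], rhos, [rho_subphase]])
    kz = 0.5 * np.sqrt(
        qz[None, :].astype(complex) ** 2 - FOUR_PI_RE * (all_rho[:, None] - rho_air)
    )
    nq = qz.size
    m11 = np.ones(nq, complex)
    m12 = np.zeros(nq, complex)
    m21 = np.zeros(nq, complex)
    m22 = np.ones(nq, complex)
    for j, d in enumerate(thicknesses, start=1):
        k = kz[j]
        cos, sin = np.cos(k * d), np.sin(k * d)
        # characteristic matrix [[cos, -i sin / k], [-i k sin, cos]]
        a11, a12 = cos, -1j * sin / k
        a21, a22 = -1j * k * sin, cos
        m11, m12, m21, m22 = (
            m11 * a11 + m12 * a21,
            m11 * a12 + m12 * a22,
            m21 * a11 + m22 * a21,
            m21 * a12 + m22 * a22,
        )
    k0, ks = kz[0], kz[-1]
    num = (m11 + m12 * ks) * k0 - (m21 + m22 * ks)
    den = (m11 + m12 * ks) * k0 + (m21 + m22 * ks)
    return np.abs(num / den) ** 2


def oracle_reflectivity(model: InterfaceModel, qz: np.ndarray,
                        width: float = 0.2) -> np.ndarray:
    """Reflectivity of a (possibly rough) slab stack via fine-sliced matrices."""
    if model.interface_sigmas.max() > 0:
        d, rho = slice_profile(model, width)
    else:
        d = np.array([s.thickness for s in model.slabs])
        rho = np.array([s.rho for s in model.slabs])
    return matrix_reflectivity(qz, d, rho, model.rho_air, model.rho_subphase)


def mc_propagate(func, values, sds, n: int, seed: int = 0) -> float:
    """Monte-Carlo standard deviation of func(*x) with independent Gaussians."""
    rng = np.random.default_rng(seed)
    draws = rng.normal(
        np.asarray(values, float), np.asarray(sds, float), size=(n, len(values))
    )
    out = np.array([func(*row) for row in draws])
    return float(out.std(ddof=1))
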