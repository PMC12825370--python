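"""Readers and writers for the plain-text formats the pipeline consumes.

Reflectivity curves are whitespace- or comma-delimited columns
``qz  R [dR]`` with ``#`` comment lines, matching common beamline exports;
qz is in Å⁻¹ (nm⁻¹ accepted with an explicit flag).  Tension isotherms are
CSV with columns ``concentration_mM, gamma_mN_m[, sd]``.  Model and fit
configuration is YAML/JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .isotherm import TensionIsotherm
from .reflectivity import ReflectivityCurve
from .slab_model import ElectronDensityProfile, InterfaceModel, Slab

__all__ = [
    "read_reflectivity",
    "write_reflectivity",
    "read_tension_csv",
    "write_tension_csv",
    "write_edp",
    "load_config",
    "model_from_config",
    "config_hash",
]


def read_reflectivity(path, *, units: str = "A^-1") -> ReflectivityCurve:
    """Parse a text reflectivity file into a :class:`ReflectivityCurve`.

    ``units`` is ``"A^-1"`` (default) or ``"nm^-1"`` (converted by 0.1).
    Malformed rows and non-monotone qz raise errors naming the line.
    """
    if units not in ("A^-1", "nm^-1"):
        raise ValueError(f"unknown qz units {units!r}; use 'A^-1' or 'nm^-1'")
    scale = 0.1 if units == "nm^-1" else 1.0

    qz, r, dr = [], [], []
    n_cols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            if vals[1] < 0:
                raise ValueError(f"{path}:{lineno}: negative reflectivity")
            if qz and vals[0] * scale <= qz[-1]:
                raise ValueError(f"{path}:{lineno}: qz not strictly increasing")
            qz.append(vals[0] * scale)
            r.append(vals[1])
            if n_cols == 3:
                dr.append(vals[2])
    if not qz:
        raise ValueError(f"{path}: no data rows")
    return ReflectivityCurve(
        qz=np.array(qz), r=np.array(r),
        dr=np.array(dr) if dr else None,
    )


def write_reflectivity(path, curve: ReflectivityCurve, *, header: str = "") -> None:
    """Write a curve as full-precision text columns with '#' header lines."""
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write("# qz[A^-1]  R" + ("  dR\n" if curve.dr is not None else "\n"))
        for i in range(len(curve)):
            row = f"{curve.qz[i]:.17g} {curve.r[i]:.17g}"
            if curve.dr is not None:
                row += f" {curve.dr[i]:.17g}"
            fh.write(row + "\n")


def read_tension_csv(path, *, gamma0: float = 72.5, temperature: float = 296.15
                     ) -> TensionIsotherm:
    """Read tension data: CSV columns concentration_mM, gamma_mN_m[, sd]."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (concentration, gamma)")
    c = df.iloc[:, 0].to_numpy(dtype=float)
    g = df.iloc[:, 1].to_numpy(dtype=float)
    sd = df.iloc[:, 2].to_numpy(dtype=float) if df.shape[1] >= 3 else None
    return TensionIsotherm(concentration=c, gamma=g, sd=sd, gamma0=gamma0,
                           temperature=temperature)


def write_tension_csv(path, iso: TensionIsotherm) -> None:
    cols = {"concentration_mM": iso.concentration, "gamma_mN_m": iso.gamma}
    if iso.sd is not None:
        cols["sd_mN_m"] = iso.sd
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def write_edp(path, profile: ElectronDensityProfile, *, header: str = "") -> None:
    """Export an electron-density profile as two-column text (z Å, rho e⁻/Å³)."""
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write("# z[A]  rho[e/A^3]\n")
        for zi, ri in zip(profile.z, profile.rho):
            fh.write(f"{zi:.17g} {ri:.17g}\n")


def load_config(path) -> dict:
    """Load a YAML (or JSON — a YAML subset) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def model_from_config(cfg: dict) -> InterfaceModel:
    """Build an :class:`InterfaceModel` from a config mapping.

    Expected keys: ``slabs`` (list of {d, rho, sigma?}), optional ``rho_air``,
    ``rho_subphase``, ``shared_sigma``.
    """
    try:
        slabs = tuple(
            Slab(thickness=float(s["d"]), rho=float(s["rho"]),
                 sigma=float(s.get("sigma", cfg.get("shared_sigma", 0.0))))
            for s in cfg.get("slabs", [])
        )
    except KeyError as exc:
        raise ValueError(f"slab entry missing key {exc}") from None
    return InterfaceModel(
        slabs=slabs,
        rho_air=float(cfg.get("rho_air", 0.0)),
        rho_subphase=float(cfg.get("rho_subphase", 0.334)),
        shared_sigma=(float(cfg["shared_sigma"]) if "shared_sigma" in cfg else None),
    )


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration, embedded in every output."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
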