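"""Readers and writers for the on-disk formats.

Survival curves are one CSV per curve (``dose_Gy,survival[,stderr]``) plus a
``manifest.json`` carrying per-curve metadata; fluence spectra are
``E_MeV,fluence`` CSVs; event spectra are ``q_keV,density_per_keV`` CSVs
with a JSON sidecar for multiplicity/geometry; parameter sets are JSON.
All CSVs are comma-separated, '.'-decimal, UTF-8, with a mandatory header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import SurvivalCurve
from .errors import DataError
from .microdosimetry import EventSpectrum, PerParticleSpectrum, SVGeometry
from .zf_regression import FluenceSpectrum

__all__ = [
    "read_survival_curve",
    "read_survival_curves",
    "write_survival_curves",
    "read_fluence",
    "write_fluence",
    "read_spectrum",
    "write_spectrum",
]

MANIFEST = "manifest.json"


def _read_csv(path: Path, columns: tuple[str, ...],
              optional: tuple[str, ...] = ()) -> pd.DataFrame:
    if not path.exists():
        raise DataError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing} "
                        f"(header is mandatory)")
    for col in columns + tuple(c for c in optional if c in df.columns):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise DataError(f"{path}: non-numeric value in column {col!r} "
                            f"at data row {int(bad[0]) + 1}")
    return df


def read_survival_curve(path, meta: dict | None = None) -> SurvivalCurve:
    """Read one curve CSV; validation errors carry 1-based data row numbers."""
    path = Path(path)
    df = _read_csv(path, ("dose_Gy", "survival"), optional=("stderr",))
    doses = df["dose_Gy"].to_numpy(dtype=float)
    surv = df["survival"].to_numpy(dtype=float)
    for i, s in enumerate(surv):
        if s <= 0:
            raise DataError(f"{path}: survival <= 0 at data row {i + 1}")
    order = np.argsort(doses)
    doses, surv = doses[order], surv[order]
    if np.any(np.diff(doses) == 0):
        j = int(np.nonzero(np.diff(doses) == 0)[0][0])
        raise DataError(f"{path}: duplicate dose {doses[j]} "
                        f"(sorted data rows {j + 1}/{j + 2})")
    stderr = None
    if "stderr" in df.columns:
        stderr = df["stderr"].to_numpy(dtype=float)[order]
    return SurvivalCurve(doses=doses, survival=surv, stderr=stderr,
                         meta=dict(meta or {}))


def read_survival_curves(path) -> list[SurvivalCurve]:
    """Read a directory of curve CSVs listed in its ``manifest.json``."""
    root = Path(path)
    manifest_path = root / MANIFEST if root.is_dir() else root
    if not manifest_path.exists():
        raise DataError(f"{manifest_path}: manifest not found")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    curves = []
    for entry in manifest.get("curves", []):
        curves.append(read_survival_curve(base / entry["file"],
                                          meta=entry.get("meta", {})))
    if not curves:
        raise DataError(f"{manifest_path}: manifest lists no curves")
    return curves


def write_survival_curves(curves: list[SurvivalCurve], outdir) -> Path:
    """Write one CSV per curve plus the metadata manifest; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, curve in enumerate(curves):
        name = f"curve_{k:02d}.csv"
        cols = {"dose_Gy": curve.doses, "survival": curve.survival}
        if curve.stderr is not None:
            cols["stderr"] = curve.stderr
        pd.DataFrame(cols).to_csv(outdir / name, index=False)
        entries.append({"file": name, "meta": curve.meta})
    with open(outdir / MANIFEST, "w", encoding="utf-8") as fh:
        json.dump({"curves": entries}, fh, indent=2)
    return outdir


def read_fluence(path, label: str = "") -> FluenceSpectrum:
    path = Path(path)
    df = _read_csv(path, ("E_MeV", "fluence"))
    return FluenceSpectrum(df["E_MeV"].to_numpy(dtype=float),
                           df["fluence"].to_numpy(dtype=float),
                           label=label or path.stem)


def write_fluence(phi: FluenceSpectrum, path) -> None:
    pd.DataFrame({"E_MeV": phi.energies,
                  "fluence": phi.values}).to_csv(path, index=False)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_spectrum(spec: EventSpectrum, path) -> None:
    """Spectrum CSV plus JSON sidecar (multiplicity, geometry, hit prob)."""
    path = Path(path)
    pd.DataFrame({"q_keV": spec.q_grid,
                  "density_per_keV": spec.density}).to_csv(path, index=False)
    side: dict = {"multiplicity": spec.multiplicity}
    if spec.site is not None:
        side["R_um"] = spec.site.R
        side["rho"] = spec.site.rho
    if isinstance(spec, PerParticleSpectrum):
        side["hit_prob"] = spec.hit_prob
        if spec.energy is not None:
            side["energy_MeV"] = spec.energy
    with open(_sidecar(path), "w", encoding="utf-8") as fh:
        json.dump(side, fh, indent=2)


def read_spectrum(path) -> EventSpectrum:
    path = Path(path)
    df = _read_csv(path, ("q_keV", "density_per_keV"))
    side = {}
    if _sidecar(path).exists():
        with open(_sidecar(path), encoding="utf-8") as fh:
            side = json.load(fh)
    site = None
    if "R_um" in side:
        site = SVGeometry(R=side["R_um"], rho=side.get("rho", 1.0))
    q = df["q_keV"].to_numpy(dtype=float)
    d = df["density_per_keV"].to_numpy(dtype=float)
    if "hit_prob" in side:
        return PerParticleSpectrum(q, d, multiplicity=side.get("multiplicity", 1),
                                   site=site, hit_prob=side["hit_prob"],
                                   energy=side.get("energy_MeV"))
    return EventSpectrum(q, d, multiplicity=side.get("multiplicity", 1),
                         site=site)
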