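"""Regression model for zF over fluence spectra, and the SV radius solver.

For an arbitrary proton beam described by its fluence spectrum Phi(E), the
frequency-mean specific energy is modelled as

    zF = [ int Phi(E) Bz(E) dE / int Phi(E) dE ]^-1,

with the weighting function Bz(E) a third-order polynomial in 1/E:

    Bz(E) = p1 + p2/E + p3/E^2 + p4/E^3     (E in MeV, Bz in 1/Gy).

Given a zF predicted by this regression, the sensitive-volume radius R
follows from zF = yF(R) / (pi rho R^2) (in keV-pg-um units, with the 0.1602
Gy conversion); because yF depends only weakly on R, the fixed-point update
R <- R sqrt(zF(R)/zF_target) converges in a few iterations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import GY_PER_KEV_PER_PG, WATER_DENSITY
from .errors import (
    ConditioningError,
    ConvergenceError,
    DataError,
    DomainError,
    ModelValidityError,
)

__all__ = [
    "FluenceSpectrum",
    "ZfRegression",
    "bz_weight",
    "zf_from_fluence",
    "solve_radius",
    "fit_regression",
]


@dataclass
class FluenceSpectrum:
    """Tabulated proton fluence spectrum Phi(E), energies in MeV."""

    energies: np.ndarray
    values: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.energies.shape != self.values.shape or self.energies.ndim != 1:
            raise DataError("energies and values must be 1-D and equal length")
        if np.any(self.energies <= 0):
            raise DataError("energies must be > 0")
        if np.any(np.diff(self.energies) <= 0):
            raise DataError("energies must be strictly increasing")
        if np.any(self.values < 0):
            raise DataError("fluence must be nonnegative")
        if self.total <= 0:
            raise DataError("fluence must have positive total integral")

    @property
    def total(self) -> float:
        if self.energies.size == 1:
            return float(self.values[0])
        return float(np.trapezoid(self.values, self.energies))

    @property
    def mean_energy(self) -> float:
        if self.energies.size == 1:
            return float(self.energies[0])
        return float(np.trapezoid(self.values * self.energies, self.energies)
                     / self.total)


@dataclass(frozen=True)
class ZfRegression:
    """Coefficients p1..p4 of Bz(E) = sum_l p_l / E^(l-1), units
    1/Gy * MeV^(l-1); optional declared validity range in E (MeV)."""

    p: tuple[float, float, float, float]
    E_valid: tuple[float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        p = tuple(float(v) for v in self.p)
        if len(p) != 4:
            raise DataError("exactly four coefficients p1..p4 are required")
        object.__setattr__(self, "p", p)
        if self.E_valid is not None:
            lo, hi = self.E_valid
            if not 0 < lo < hi:
                raise DataError("E_valid must satisfy 0 < Emin < Emax")
            E = np.geomspace(lo, hi, 256)
            if np.any(bz_weight(self, E) <= 0):
                raise ModelValidityError(
                    "Bz(E) is not positive over the declared validity range")

    def to_dict(self) -> dict:
        d = {"cell": self.label, "p": list(self.p)}
        if self.E_valid is not None:
            d["E_valid"] = list(self.E_valid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ZfRegression":
        ev = tuple(d["E_valid"]) if "E_valid" in d else None
        return cls(p=tuple(d["p"]), E_valid=ev, label=d.get("cell", ""))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ZfRegression":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def bz_weight(reg: ZfRegression, E) -> np.ndarray | float:
    """Bz(E) = p1 + p2/E + p3/E^2 + p4/E^3 (1/Gy), E in MeV."""
    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr <= 0):
        raise DomainError("E must be > 0")
    inv = 1.0 / E_arr
    p1, p2, p3, p4 = reg.p
    out = p1 + inv * (p2 + inv * (p3 + inv * p4))
    return out if np.ndim(E) else float(out)


def zf_from_fluence(reg: ZfRegression, phi: FluenceSpectrum) -> float:
    """zF (Gy) of a beam: inverse of the fluence-weighted mean of Bz(E).

    Invariant under rescaling of the fluence.  Raises
    :class:`ModelValidityError` when the weighted integral is nonpositive
    (regression evaluated outside its range).
    """
    w = bz_weight(reg, phi.energies)
    if phi.energies.size == 1:
        mean_bz = float(w)
    else:
        mean_bz = float(np.trapezoid(phi.values * w, phi.energies) / phi.total)
    if mean_bz <= 0:
        raise ModelValidityError(
            "weighted Bz integral is nonpositive; regression used outside "
            "its validity range")
    return 1.0 / mean_bz


def _zf_geom(yF: float, R: float, rho: float) -> float:
    return GY_PER_KEV_PER_PG * yF / (math.pi * rho * R * R)


def solve_radius(zF_target: float, yF_of_R: Callable[[float], float],
                 rho: float = WATER_DENSITY, tol: float = 0.01,
                 R0: float = 0.5, max_iter: int = 50) -> float:
    """Solve zF = yF(R) / (pi rho R^2) for the SV radius R (um).

    Fixed-point iteration R <- R sqrt(zF(R)/zF_target), exploiting the 1/R^2
    dependence; when yF varies slowly with R this converges in 2-3 steps.
    ``tol`` is the relative zF acceptance (default +-1%).
    """
    if not zF_target > 0:
        raise DomainError("zF_target must be > 0")
    R = float(R0)
    for _ in range(max_iter):
        yF = yF_of_R(R)
        if not yF > 0:
            raise ConvergenceError(f"yF(R={R:.4g}) is not positive")
        zF = _zf_geom(yF, R, rho)
        if abs(zF - zF_target) / zF_target <= tol:
            return R
        R *= math.sqrt(zF / zF_target)
        if not (1e-6 < R < 1e4):
            raise ConvergenceError(
                f"radius iteration left the physical range (R={R:.3g} um); "
                "target zF outside the attainable range")
    raise ConvergenceError("radius iteration did not converge")


def _design_row(phi: FluenceSpectrum) -> np.ndarray:
    """Fluence-averaged moments of 1/E^(l-1), l = 1..4."""
    E, v = phi.energies, phi.values
    if E.size == 1:
        return np.array([1.0, 1 / E[0], 1 / E[0] ** 2, 1 / E[0] ** 3])
    tot = phi.total
    return np.array([np.trapezoid(v * E ** -(l), E) / tot for l in range(4)])


def fit_regression(points: Sequence[tuple[FluenceSpectrum, float]],
                   label: str = "") -> tuple[ZfRegression, np.ndarray]:
    """Fit p1..p4 to (fluence spectrum, zF) pairs.

    Minimises the sum of squared relative errors of the predicted zF.  The
    model is linear in p through 1/zF, so a weighted linear solve gives the
    start, refined by nonlinear least squares on the true relative error.
    Returns the regression and per-point relative residuals.
    """
    if len(points) < 4:
        raise ConditioningError(
            f"need at least 4 (spectrum, zF) points, got {len(points)}")
    zf = np.array([z for _, z in points], dtype=float)
    if np.any(zf <= 0):
        raise DataError("supplied zF values must be > 0")
    A = np.vstack([_design_row(phi) for phi, _ in points])
    if np.linalg.matrix_rank(A, tol=1e-10 * np.abs(A).max()) < 4:
        raise ConditioningError(
            "fewer distinct spectral shapes than coefficients: design is "
            "rank-deficient")
    # linear start: zf_k * (A p)_k ~= 1 in relative terms
    W = zf[:, None] * A
    p0, *_ = np.linalg.lstsq(W, np.ones_like(zf), rcond=None)

    def rel_resid(p):
        pred_inv = A @ p
        bad = pred_inv <= 0
        pred = np.where(bad, np.inf, 1.0 / np.where(bad, 1.0, pred_inv))
        r = (pred - zf) / zf
        return np.where(bad, 1e6, r)

    sol = least_squares(rel_resid, p0, method="lm", xtol=1e-14, ftol=1e-14)
    Emin = min(float(phi.energies[0]) for phi, _ in points)
    Emax = max(float(phi.energies[-1]) for phi, _ in points)
    E_grid = np.geomspace(Emin, Emax, 256)
    V = np.vstack([E_grid ** -(l) for l in range(4)]).T  # Bz design on grid

    p_best = sol.x
    if np.any(V @ p_best <= 0):
        # noisy training zF can pull the cubic negative at the sparsely
        # weighted edge of the hull; refit with a hinge penalty keeping
        # Bz positive over the declared validity range
        floor = 1e-3 * float(np.median(np.abs(V @ p_best)))

        def penalised(p):
            hinge = np.clip(floor - V @ p, 0.0, None) / floor
            return np.concatenate([rel_resid(p), 10.0 * hinge])

        sol2 = least_squares(penalised, p0, method="lm", xtol=1e-14,
                             ftol=1e-14)
        p_best = sol2.x

    reg = ZfRegression(p=tuple(p_best), E_valid=(Emin, Emax), label=label)
    return reg, rel_resid(p_best)
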