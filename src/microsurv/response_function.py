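"""The biological response function B(q) and energy-domain response tables.

B(q) is the probability that a cell survives a total energy deposit q (keV)
in its sensitive volume.  It is modelled as a scaled hyperbolic tangent

    B(q) = a [ 1/2 tanh(-(q - q0)/b) + 1/2 ]^c,   a = 2 / (tanh(q0/b) + 1)^c,

which satisfies B(0) = 1 exactly, 0 <= B(q) <= 1 and dB/dq <= 0 for q >= 0.
Per-hit survival probabilities follow by quadrature against the multi-event
spectra, s_i = int B(q) f_i(q) dq.

For treatment-planning-style evaluation the q-integrals are pretabulated in
the energy domain: B_i(E, R) = int B(q) f_i(q|1, E, R) dq on an (E, R) grid,
after which s_i for any beam is a one-dimensional fluence integral.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import (
    ConfigurationError,
    CoverageError,
    DataError,
    DomainError,
    ParameterError,
)
from .microdosimetry import (
    EventSpectrum,
    condition_per_particle,
    multi_event_spectra,
    spectrum_moments,
)

__all__ = [
    "ResponseParams",
    "response_value",
    "hit_survival_probs",
    "EnergyResponseTable",
    "tabulate_energy_response",
    "s_from_fluence",
]


@dataclass(frozen=True)
class ResponseParams:
    """Parameters (b, c, q0) of the tanh response; the scale a is derived
    from B(0) = 1 and never stored independently."""

    b: float
    c: float
    q0: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ParameterError(f"b must be > 0, got {self.b}")
        if not self.c > 0:
            raise ParameterError(f"c must be > 0, got {self.c}")
        # tanh(q0/b) + 1 underflows for q0/b <~ -19, degenerating the
        # B(0) = 1 scaling; restrict the domain well clear of that
        if self.q0 / self.b < -18.0:
            raise ParameterError(
                "q0/b < -18: the B(0)=1 normalisation degenerates")

    @property
    def a(self) -> float:
        """Scale factor [2 / (tanh(q0/b) + 1)]^c, the unique value with
        B(0) = a [tanh(q0/b)/2 + 1/2]^c = 1."""
        return (2.0 / (math.tanh(self.q0 / self.b) + 1.0)) ** self.c

    def to_dict(self) -> dict:
        return {"label": self.label, "b_keV": self.b, "c": self.c,
                "q0_keV": self.q0}

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseParams":
        return cls(b=float(d["b_keV"]), c=float(d["c"]),
                   q0=float(d["q0_keV"]), label=d.get("label", ""))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ResponseParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def response_value(rp: ResponseParams, q) -> np.ndarray | float:
    """B(q) for q >= 0 (keV).

    Evaluated as ((tanh(-(q - q0)/b) + 1) / (tanh(q0/b) + 1))^c, which is
    algebraically identical to a [tanh/2 + 1/2]^c and returns exactly 1.0
    at q = 0.
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0):
        raise DomainError("B(q) is undefined for q < 0")
    num = np.tanh(-(q_arr - rp.q0) / rp.b) + 1.0
    den = float(np.tanh(rp.q0 / rp.b)) + 1.0  # same tanh as the numerator
    out = (num / den) ** rp.c
    return out if np.ndim(q) else float(out)


def hit_survival_probs(rp: ResponseParams,
                       spectra: list[EventSpectrum]) -> np.ndarray:
    """s_i = int B(q) f_i(q) dq for each supplied multi-event spectrum.

    Midpoint-rule quadrature on each spectrum's own grid; requires the
    spectra to be unit-normalised.
    """
    out = np.empty(len(spectra))
    for k, f in enumerate(spectra):
        if abs(f.norm - 1.0) > 1e-4:
            raise DataError(
                f"spectrum {k} (multiplicity {f.multiplicity}) is not "
                f"normalised: integral = {f.norm:.6g}")
        B = response_value(rp, f.q_grid)
        out[k] = float((B * f.density).sum() * f.dq)
    return np.clip(out, 0.0, 1.0)


@dataclass
class EnergyResponseTable:
    """Pretabulated B_i(E, R), hit probabilities and yF on an (E, R) grid.

    ``Bi`` has shape (imax, nE, nR); ``hit_prob`` and ``yF`` have shape
    (nE, nR).  Between nodes all quantities interpolate bilinearly.
    """

    energies: np.ndarray
    radii: np.ndarray
    Bi: np.ndarray
    hit_prob: np.ndarray
    yF: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.Bi = np.asarray(self.Bi, dtype=float)
        self.hit_prob = np.asarray(self.hit_prob, dtype=float)
        self.yF = np.asarray(self.yF, dtype=float)
        nE, nR = self.energies.size, self.radii.size
        if self.Bi.shape[1:] != (nE, nR) or self.hit_prob.shape != (nE, nR):
            raise DataError("table shapes are inconsistent with the axes")
        if np.any(self.Bi < 0) or np.any(self.Bi > 1):
            raise DataError("B_i values must lie in [0, 1]")
        if np.any(self.hit_prob <= 0) or np.any(self.hit_prob > 1):
            raise DataError("hit probabilities must lie in (0, 1]")
        self._interp = {}

    @property
    def imax(self) -> int:
        return self.Bi.shape[0]

    def _get_interp(self, key: str, values: np.ndarray):
        if key not in self._interp:
            pts = (self.energies, self.radii)
            if self.radii.size == 1:  # degenerate R axis
                self._interp[key] = lambda E, R, v=values: np.interp(
                    E, self.energies, v[:, 0])
            else:
                f = RegularGridInterpolator(pts, values, method="linear",
                                            bounds_error=True)
                self._interp[key] = lambda E, R, f=f: f(
                    np.column_stack([np.atleast_1d(E),
                                     np.full(np.atleast_1d(E).shape, R)]))
        return self._interp[key]

    def _check_cov(self, E, R) -> None:
        E = np.atleast_1d(E)
        if (np.min(E) < self.energies[0] - 1e-12
                or np.max(E) > self.energies[-1] + 1e-12):
            raise CoverageError("energy outside the tabulated range")
        if self.radii.size > 1 and not (
                self.radii[0] - 1e-12 <= R <= self.radii[-1] + 1e-12):
            raise CoverageError("radius outside the tabulated range")

    def bi_at(self, i: int, E, R: float) -> np.ndarray:
        """Bilinear B_i at energies E and radius R (1-based i)."""
        if not 1 <= i <= self.imax:
            raise DomainError(f"i must be in 1..{self.imax}")
        self._check_cov(E, R)
        return self._get_interp(f"B{i}", self.Bi[i - 1])(E, R)

    def hit_prob_at(self, E, R: float) -> np.ndarray:
        self._check_cov(E, R)
        return self._get_interp("hit", self.hit_prob)(E, R)

    def yf_at(self, E, R: float) -> np.ndarray:
        self._check_cov(E, R)
        return self._get_interp("yF", self.yF)(E, R)

    # --- persistence -----------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            for name in ("energies", "radii", "Bi", "hit_prob", "yF"):
                h5.create_dataset(name, data=getattr(self, name))

    @classmethod
    def from_hdf5(cls, path) -> "EnergyResponseTable":
        import h5py

        with h5py.File(path, "r") as h5:
            return cls(**{name: h5[name][...] for name in
                          ("energies", "radii", "Bi", "hit_prob", "yF")})


def tabulate_energy_response(rp: ResponseParams, provider, energies, radii,
                             imax: int = 4) -> EnergyResponseTable:
    """Build an :class:`EnergyResponseTable` on the (E, R) grid.

    ``provider(E, R)`` must return the monoenergetic
    :class:`PerParticleSpectrum` at that node.  At each node,
    B_i(E, R) = int B(q) f_i(q|1, E, R) dq = hit_prob * s_i with f_i built
    by convolving the conditioned single-event spectrum.

    The default grid in the package CLI is log-spaced E over 0.5-250 MeV
    and linear R over 0.05-1.5 um; imax defaults to 4 (at most four
    dose-independent multi-event spectra are needed in practice).
    """
    energies = np.asarray(energies, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if energies.size < 1 or radii.size < 1:
        raise ConfigurationError("need at least one node per axis")
    nE, nR = energies.size, radii.size
    Bi = np.empty((imax, nE, nR))
    hit = np.empty((nE, nR))
    yF = np.empty((nE, nR))
    for a, E in enumerate(energies):
        for b, R in enumerate(radii):
            pp = provider(E, R)
            if pp is None:
                raise CoverageError(f"missing per-particle spectrum at "
                                    f"(E={E}, R={R})")
            f1 = condition_per_particle(pp)
            spectra = multi_event_spectra(f1, imax)
            s = hit_survival_probs(rp, spectra)
            Bi[:, a, b] = pp.hit_prob * s
            hit[a, b] = pp.hit_prob
            _, _, yF[a, b] = spectrum_moments(f1)
    return EnergyResponseTable(energies=energies, radii=radii, Bi=Bi,
                               hit_prob=hit, yF=yF)


def s_from_fluence(table: EnergyResponseTable, phi, R: float) -> np.ndarray:
    """s_i for a beam from the pretabulated energy response:

        s_i = int Phi(E) B_i(E) dE / int Phi(E) f(q>0|1, E) dE,

    a one-dimensional quadrature over the fluence spectrum at radius R.
    """
    E = phi.energies
    v = phi.values
    hp = np.atleast_1d(table.hit_prob_at(E, R))
    if E.size == 1:
        den = float(hp[0])
        return np.array([float(np.atleast_1d(table.bi_at(i, E, R))[0]) / den
                         for i in range(1, table.imax + 1)])
    den = float(np.trapezoid(v * hp, E))
    if den <= 0:
        raise CoverageError("fluence-weighted hit probability vanishes")
    out = np.empty(table.imax)
    for i in range(1, table.imax + 1):
        out[i - 1] = float(np.trapezoid(v * table.bi_at(i, E, R), E)) / den
    return np.clip(out, 0.0, 1.0)
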