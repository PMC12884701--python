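"""Grid-sampled energy-deposition spectra and compound-Poisson machinery.

A single-event spectrum f1(q) is the probability density of the energy q
(keV) deposited in the sensitive volume (SV) by one event.  Multi-event
spectra f_i(q) are built from f1 by the convolution recurrence

    f_{i+1}(q) = integral_0^q f_i(q') f1(q - q') dq',

and the spectrum of total deposited energy after dose D is the Poisson
mixture over the event count i with mean N = D/zF, plus an atom exp(-N)
at q = 0 (the no-hit outcome), which is stored separately: densities are
normalised to 1 excluding the singular point q = 0.

All spectra live on uniform midpoint grids (first node at start + dq/2 by
default).  The discrete convolution of two such grids naturally lands on a
grid offset by the sum of the starts; it is resampled back onto a midpoint
grid by adjacent averaging, which preserves both total mass and mean
exactly (up to discarded sub-1e-8 tail mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import poisson

from .constants import GY_PER_KEV_PER_PG, WATER_DENSITY, mean_chord_um, sphere_mass_pg
from .errors import (
    ConfigurationError,
    DegenerateSpectrumError,
    DomainError,
    GridError,
    CoverageError,
)

__all__ = [
    "SVGeometry",
    "EventSpectrum",
    "PerParticleSpectrum",
    "normalize_event_spectrum",
    "spectrum_moments",
    "convolve_spectra",
    "multi_event_spectra",
    "compound_dose_spectrum",
    "condition_per_particle",
    "mix_polyenergetic",
    "zf_from_geometry",
]

_NORM_TOL = 1e-6
_TAIL_DISCARD = 1e-8


@dataclass(frozen=True)
class SVGeometry:
    """Spherical sensitive volume: radius R (um) and density rho (g/cm^3)."""

    R: float
    rho: float = WATER_DENSITY

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise DomainError(f"R must be > 0, got {self.R}")
        if not self.rho > 0:
            raise DomainError(f"rho must be > 0, got {self.rho}")

    @property
    def mass_pg(self) -> float:
        return sphere_mass_pg(self.R, self.rho)

    @property
    def mean_chord(self) -> float:
        return mean_chord_um(self.R)


@dataclass
class EventSpectrum:
    """Probability density of energy q (keV) deposited by exactly
    ``multiplicity`` events.

    ``q_grid`` is uniform with spacing ``dq``; ``density`` has units 1/keV.
    ``multiplicity=None`` marks a Poisson mixture (compound spectrum).
    """

    q_grid: np.ndarray
    density: np.ndarray
    multiplicity: int | None = 1
    site: SVGeometry | None = None

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.q_grid.shape != self.density.shape or self.q_grid.ndim != 1:
            raise GridError("q_grid and density must be 1-D and equal length")
        if self.q_grid.size < 2:
            raise GridError("need at least two grid points")
        steps = np.diff(self.q_grid)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise GridError("q_grid must be uniform")
        if np.any(self.density < 0):
            raise DegenerateSpectrumError("density must be nonnegative")

    @property
    def dq(self) -> float:
        return float(self.q_grid[1] - self.q_grid[0])

    @property
    def norm(self) -> float:
        """Midpoint-rule integral of the density."""
        return float(self.density.sum() * self.dq)

    @property
    def mean(self) -> float:
        return float((self.q_grid * self.density).sum() * self.dq / self.norm)

    @property
    def var(self) -> float:
        m = self.mean
        return float(((self.q_grid - m) ** 2 * self.density).sum() * self.dq
                     / self.norm)

    def cdf(self, q) -> np.ndarray:
        """Piecewise-constant-density CDF evaluated at q (right bin edges)."""
        edges = np.concatenate([[max(self.q_grid[0] - 0.5 * self.dq, 0.0)],
                                self.q_grid + 0.5 * self.dq])
        cum = np.concatenate([[0.0], np.cumsum(self.density) * self.dq])
        return np.interp(np.asarray(q, dtype=float), edges, cum,
                         left=0.0, right=cum[-1])


@dataclass
class PerParticleSpectrum(EventSpectrum):
    """Energy-deposit spectrum normalised per one source particle.

    ``density`` is the continuous (q > 0) part and integrates to
    ``hit_prob``, the probability of a nonzero deposit per source particle;
    the q = 0 atom carries the remaining 1 - hit_prob and is never stored
    as a density bin.
    """

    hit_prob: float = 1.0
    energy: float | None = None  # source proton energy, MeV, if monoenergetic

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 < self.hit_prob <= 1.0:
            raise DegenerateSpectrumError(
                f"hit_prob must be in (0, 1], got {self.hit_prob}")


def _midpoint_grid(n: int, dq: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * dq


def normalize_event_spectrum(raw, dq: float, multiplicity: int = 1,
                             site: SVGeometry | None = None,
                             q_grid=None) -> EventSpectrum:
    """Scale nonnegative grid samples into a unit-normalised EventSpectrum.

    ``raw`` are density samples on a uniform grid of width ``dq`` (midpoint
    grid starting at dq/2 unless ``q_grid`` is given).
    """
    raw = np.asarray(raw, dtype=float)
    if not dq > 0:
        raise DomainError("dq must be > 0")
    if np.any(raw < 0):
        raise DegenerateSpectrumError("samples must be nonnegative")
    total = raw.sum() * dq
    if total <= 0:
        raise DegenerateSpectrumError("all-zero spectrum cannot be normalised")
    grid = _midpoint_grid(raw.size, dq) if q_grid is None else np.asarray(q_grid, float)
    return EventSpectrum(grid, raw / total, multiplicity=multiplicity, site=site)


def spectrum_moments(f1: EventSpectrum) -> tuple[float, float, float]:
    """(qF keV, zF Gy, yF keV/um) of a single-event spectrum.

    qF is the mean event energy; zF = 0.1602 qF / m with the site mass m in
    pg; yF = qF / (4R/3).  The identity zF = 0.1602 yF / (pi rho R^2) holds
    exactly by construction.
    """
    if f1.site is None:
        raise ConfigurationError("spectrum has no attached SVGeometry")
    if f1.multiplicity != 1:
        raise ConfigurationError("moments are defined for a single-event spectrum")
    qF = f1.mean
    zF = GY_PER_KEV_PER_PG * qF / f1.site.mass_pg
    yF = qF / f1.site.mean_chord
    return qF, zF, yF


def zf_from_geometry(yF: float, geom: SVGeometry) -> float:
    """zF (Gy) from the frequency-mean lineal energy and a spherical site:
    zF = 0.1602 yF / (pi rho R^2)."""
    if not yF > 0:
        raise DomainError("yF must be > 0")
    return GY_PER_KEV_PER_PG * yF / (np.pi * geom.rho * geom.R**2)


def _resample_to_midpoint(conv: np.ndarray, start: float, dq: float) -> np.ndarray:
    """Resample density samples at start + m*dq onto the midpoint grid
    (m + 1/2)*dq by linear interpolation (adjacent averaging when the offset
    is dq: exactly mass- and mean-preserving)."""
    n_out = int(np.ceil((start + (conv.size - 1) * dq) / dq - 0.5)) + 1
    target = _midpoint_grid(n_out, dq)
    src = start + np.arange(conv.size) * dq
    out = np.interp(target, src, conv, left=0.0, right=0.0)
    # the q=0 end: density below the first source node is extrapolated as 0,
    # which slightly clips mass; compensate by renormalising at the caller.
    return out


def _truncate_tail(density: np.ndarray, dq: float,
                   tol: float = _TAIL_DISCARD) -> np.ndarray:
    """Drop trailing bins whose cumulative mass is below ``tol``."""
    tail = np.cumsum(density[::-1])[::-1] * dq
    keep = np.nonzero(tail > tol)[0]
    last = keep[-1] + 1 if keep.size else density.size
    return density[: max(last, 2)]


def convolve_spectra(fi: EventSpectrum, f1: EventSpectrum) -> EventSpectrum:
    """One step of the multi-event recurrence: the (i+1)-event spectrum as
    the convolution of the i-event spectrum with the single-event spectrum.
    """
    if abs(fi.dq - f1.dq) > 1e-9 * f1.dq:
        raise GridError(f"grid steps differ: {fi.dq} vs {f1.dq}")
    dq = f1.dq
    for s, name in ((fi, "fi"), (f1, "f1")):
        if abs(s.norm - 1.0) > 1e-4:
            raise GridError(f"{name} is not normalised (norm={s.norm:.6g})")
    conv = signal.fftconvolve(fi.density, f1.density) * dq
    np.clip(conv, 0.0, None, out=conv)
    start = fi.q_grid[0] + f1.q_grid[0]
    dens = _resample_to_midpoint(conv, start, dq)
    dens = _truncate_tail(dens, dq)
    norm = dens.sum() * dq
    if abs(norm - 1.0) > 1e-4:
        raise GridError(f"convolution lost mass: norm={norm:.6g}")
    mult = (fi.multiplicity or 0) + (f1.multiplicity or 0)
    return EventSpectrum(_midpoint_grid(dens.size, dq), dens / norm,
                         multiplicity=mult, site=f1.site)


def multi_event_spectra(f1: EventSpectrum, imax: int) -> list[EventSpectrum]:
    """[f_1, f_2, ..., f_imax] by repeated convolution with f_1."""
    if imax < 1:
        raise DomainError("imax must be >= 1")
    out = [f1]
    for _ in range(imax - 1):
        out.append(convolve_spectra(out[-1], f1))
    return out


def poisson_truncation(N: float, tail_tol: float) -> int:
    """Smallest imax with Poisson(N) tail beyond imax below tail_tol."""
    if N == 0:
        return 0
    imax = int(poisson.isf(tail_tol, N))
    while poisson.sf(imax, N) >= tail_tol:  # isf can be off by one
        imax += 1
    return max(imax, 1)


def compound_dose_spectrum(
    f1: EventSpectrum, N: float, tail_tol: float = 1e-8,
    spectra: list[EventSpectrum] | None = None,
) -> tuple[float, EventSpectrum | None]:
    """Total-energy spectrum after a dose giving mean hit number ``N``.

    Returns ``(zero_prob, mixture)``: the q = 0 atom exp(-N) plus the
    continuous Poisson mixture sum_i>=1 exp(-N) N^i/i! f_i(q), truncated
    where the discarded Poisson tail is below ``tail_tol``.  The mixture
    density integrates to 1 - exp(-N) - tail; it is deliberately not
    renormalised.  Precomputed ``spectra`` (from :func:`multi_event_spectra`)
    may be supplied to avoid re-convolution.
    """
    if N < 0:
        raise DomainError("N must be >= 0")
    if not 0 < tail_tol <= 1e-4:
        raise DomainError("tail_tol must be in (0, 1e-4]")
    zero_prob = float(np.exp(-N))
    if N == 0:
        return 1.0, None
    imax = poisson_truncation(N, tail_tol)
    fis = spectra if spectra is not None else multi_event_spectra(f1, imax)
    if len(fis) < imax:
        fis = fis + multi_event_spectra(f1, imax)[len(fis):]
    dq = f1.dq
    n = max(s.density.size for s in fis[:imax])
    mix = np.zeros(n)
    w = poisson.pmf(np.arange(1, imax + 1), N)
    for i in range(imax):
        d = fis[i].density
        mix[: d.size] += w[i] * d
    return zero_prob, EventSpectrum(_midpoint_grid(n, dq), mix,
                                    multiplicity=None, site=f1.site)


def condition_per_particle(pp: PerParticleSpectrum) -> EventSpectrum:
    """Single-event spectrum conditional on a nonzero deposit:
    f1(q) = f1(q|1) / f(q>0|1)."""
    dens = pp.density / pp.hit_prob
    norm = dens.sum() * pp.dq
    return EventSpectrum(pp.q_grid.copy(), dens / norm, multiplicity=1,
                         site=pp.site)


def mix_polyenergetic(per_energy: list[PerParticleSpectrum],
                      phi: "FluenceSpectrum") -> PerParticleSpectrum:
    """Fluence-weighted per-particle spectrum for a polyenergetic beam.

    Weights are the fluence density evaluated at each tabulated spectrum's
    energy times the local trapezoid energy width; mixed density and hit
    probability are the corresponding weighted averages.
    """
    if any(s.energy is None for s in per_energy):
        raise ConfigurationError("per-energy spectra must carry an energy")
    E = np.array([s.energy for s in per_energy], dtype=float)
    order = np.argsort(E)
    E = E[order]
    per_energy = [per_energy[i] for i in order]
    lo, hi = phi.energies[0], phi.energies[-1]
    if E[0] > lo + 1e-12 or E[-1] < hi - 1e-12:
        raise CoverageError(
            f"tabulated energies [{E[0]}, {E[-1]}] do not cover the fluence "
            f"support [{lo}, {hi}]")
    vals = np.interp(E, phi.energies, phi.values, left=0.0, right=0.0)
    if E.size == 1:
        w = np.array([1.0])
    else:
        widths = np.gradient(E)
        w = vals * widths
    total = w.sum()
    if total <= 0:
        raise CoverageError("fluence has no weight on the tabulated energies")
    w = w / total
    dq = per_energy[0].dq
    if any(abs(s.dq - dq) > 1e-9 * dq for s in per_energy):
        raise GridError("per-energy spectra must share a grid step")
    n = max(s.density.size for s in per_energy)
    dens = np.zeros(n)
    for wi, s in zip(w, per_energy):
        dens[: s.density.size] += wi * s.density
    hit = float((w * np.array([s.hit_prob for s in per_energy])).sum())
    Ebar = float((w * E).sum())
    return PerParticleSpectrum(_midpoint_grid(n, dq), dens, multiplicity=1,
                               site=per_energy[0].site, hit_prob=hit,
                               energy=Ebar if E.size == 1 else None)
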