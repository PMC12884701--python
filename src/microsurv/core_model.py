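"""The non-linear-quadratic (non-LQ) cell survival model and derived quantities.

A cell type under a given beam quality is summarised by the frequency-mean
specific energy per event ``zF`` and per-hit survival probabilities
``s_0=1, s_1, s_2, ...``.  At dose ``D`` the number of energy-deposition
events ("hits") in the sensitive volume is Poisson with mean ``N = D/zF``,
and the surviving fraction is the Poisson mixture

    S(D) = S0 * exp(-N) * sum_i N^i s_i / i!

The series is linear-quadratic at low dose (alpha = (1-s1)/zF,
beta = (s1^2-s2)/(2 zF^2)) and tends to the pure exponential exp(-D/zF)
at high dose, which is what makes it usable for hypofractionation-scale
doses where the LQ model fails.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
import numpy as np
from scipy.special import gammaln

from .errors import ConvergenceError, DataError, DomainError, ParameterError

__all__ = [
    "CellResponseParams",
    "SurvivalCurve",
    "survival_fraction",
    "log_survival",
    "lq_limit_coefficients",
    "dose_for_survival",
    "rbe_at_dose",
    "hit_kill_distribution",
]


@dataclass(frozen=True)
class CellResponseParams:
    """Parameters of the non-LQ survival formula for one cell type / beam.

    Parameters
    ----------
    zF : float
        Frequency-mean specific energy per event, Gy (> 0).
    s : sequence of float
        Per-hit survival probabilities ``s_0 .. s_imax``; ``s_0`` must be 1,
        each ``s_i`` in [0, 1].  Indices beyond the list are treated as 0.
    lnS0 : float
        Log-survival offset at zero dose (plating-efficiency slack); bounded
        within +-0.05 when produced by fitting.
    label : str
        Free-text identifier (cell line, radiation, source).
    """

    zF: float
    s: tuple[float, ...]
    lnS0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.zF > 0:
            raise ParameterError(f"zF must be > 0, got {self.zF}")
        s = tuple(float(v) for v in self.s)
        if len(s) == 0 or abs(s[0] - 1.0) > 0:
            raise ParameterError("s must start with s_0 = 1 exactly")
        if any(v < 0 or v > 1 for v in s):
            raise ParameterError("all s_i must lie in [0, 1]")
        if any(s[i + 1] > s[i] + 1e-12 for i in range(len(s) - 1)):
            warnings.warn(
                f"s_i not nonincreasing for {self.label!r}: {s}", stacklevel=3
            )
        object.__setattr__(self, "s", s)

    # --- convenience -----------------------------------------------------
    @property
    def support(self) -> int:
        """Largest i with s_i > 0 (series truncation index)."""
        nz = [i for i, v in enumerate(self.s) if v > 0]
        return nz[-1] if nz else 0

    def with_label(self, label: str) -> "CellResponseParams":
        return replace(self, label=label)

    def to_dict(self) -> dict:
        return {"label": self.label, "zF_Gy": self.zF, "s": list(self.s),
                "lnS0": self.lnS0}

    @classmethod
    def from_dict(cls, d: dict) -> "CellResponseParams":
        return cls(zF=float(d["zF_Gy"]), s=tuple(d["s"]),
                   lnS0=float(d.get("lnS0", 0.0)), label=d.get("label", ""))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CellResponseParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SurvivalCurve:
    """A measured (or simulated) clonogenic survival curve."""

    doses: np.ndarray
    survival: np.ndarray
    stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.doses.ndim != 1 or self.doses.shape != self.survival.shape:
            raise DataError("doses and survival must be 1-D and equal length")
        if np.any(np.diff(self.doses) <= 0):
            raise DataError("doses must be strictly increasing")
        if np.any(self.doses < 0):
            raise DataError("doses must be >= 0")
        if np.any(self.survival <= 0):
            raise DataError("survival must be > 0 (log scale is used)")
        if np.any(self.survival > 1.2):
            raise DataError("survival > 1.2 is outside plating-efficiency slack")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.doses.shape:
                raise DataError("stderr must match doses in length")

    def __len__(self) -> int:
        return self.doses.size


def log_survival_raw(zF: float, s, lnS0: float, D: np.ndarray) -> np.ndarray:
    """ln S for raw arrays, skipping parameter validation (fitting hot path)."""
    N = np.asarray(D, dtype=float) / zF
    return lnS0 - N + _log_poisson_sum_arrays(np.asarray(s, dtype=float), N)


def _log_poisson_sum(params: CellResponseParams, N: np.ndarray) -> np.ndarray:
    """log( sum_{i=0..support} N^i s_i / i! ), stable for large N."""
    return _log_poisson_sum_arrays(np.asarray(params.s), N)


def _log_poisson_sum_arrays(s_full: np.ndarray, N: np.ndarray) -> np.ndarray:
    i = np.arange(s_full.size)
    keep = s_full > 0
    i, s = i[keep], s_full[keep]
    logN = np.where(N > 0, np.log(np.where(N > 0, N, 1.0)), -np.inf)
    # terms: i*logN + log s_i - log i!  (the i=0 term is 0*logN = 0 even at N=0)
    with np.errstate(invalid="ignore"):
        ilogN = np.where(i[None, :] == 0, 0.0, i[None, :] * logN[:, None])
    logterms = ilogN + np.log(s)[None, :] - gammaln(i + 1)[None, :]
    m = logterms.max(axis=1)
    return m + np.log(np.exp(logterms - m[:, None]).sum(axis=1))


def log_survival(params: CellResponseParams, D) -> np.ndarray | float:
    """ln S(D) for scalar or array dose (Gy)."""
    D_arr = np.atleast_1d(np.asarray(D, dtype=float))
    if np.any(D_arr < 0):
        raise DomainError("dose must be >= 0")
    N = D_arr / params.zF
    out = params.lnS0 - N + _log_poisson_sum(params, N)
    return out if np.ndim(D) else float(out[0])


def survival_fraction(params: CellResponseParams, D) -> np.ndarray | float:
    """Surviving fraction S(D); series truncated at the last nonzero s_i."""
    return np.exp(log_survival(params, D))


def lq_limit_coefficients(params: CellResponseParams) -> tuple[float, float]:
    """LQ coefficients of the low-dose expansion ln S ~ lnS0 - aD - bD^2.

    The first two nonzero orders of the power series in dose coincide with
    the linear-quadratic model: alpha = (1 - s1)/zF and
    beta = (s1^2 - s2)/(2 zF^2).
    """
    s1 = params.s[1] if len(params.s) > 1 else 0.0
    s2 = params.s[2] if len(params.s) > 2 else 0.0
    alpha = (1.0 - s1) / params.zF
    beta = (s1 * s1 - s2) / (2.0 * params.zF**2)
    return alpha, beta


def dose_for_survival(params: CellResponseParams, target: float,
                      rtol: float = 1e-8) -> float:
    """Dose (Gy) at which the surviving fraction equals ``target``.

    Bracket found by doubling, then bisection; deterministic.  D10, the dose
    at which 10% of cells survive, is ``dose_for_survival(p, 0.1)``.
    """
    S0 = math.exp(params.lnS0)
    if not (0.0 < target < S0):
        raise DomainError(f"target must lie in (0, {S0:.6g}), got {target}")
    log_t = math.log(target)
    hi = params.zF  # doubling search for the upper bracket
    for _ in range(200):
        if log_survival(params, hi) < log_t:
            break
        hi *= 2.0
    else:
        raise ConvergenceError("no bracket: survival does not reach target")
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if log_survival(params, mid) > log_t:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rtol * max(hi, params.zF):
            break
    D = 0.5 * (lo + hi)
    if abs(survival_fraction(params, D) - target) / target > 1e-6:
        raise ConvergenceError("bisection did not reach requested tolerance")
    return D


def rbe_at_dose(test: CellResponseParams, reference: CellResponseParams,
                D_test: float) -> float:
    """Relative biological effectiveness at test dose ``D_test``.

    The iso-survival ratio D_ref / D_test, where D_ref is the reference-
    radiation dose producing the same surviving fraction as the test
    radiation at D_test.
    """
    if not D_test > 0:
        raise DomainError("D_test must be > 0")
    level = survival_fraction(test, D_test)
    if not (0.0 < level < math.exp(reference.lnS0)):
        raise DomainError("iso-survival level unreachable by reference model")
    return dose_for_survival(reference, level) / D_test


def hit_kill_distribution(params: CellResponseParams, D: float,
                          tail_tol: float = 1e-10,
                          normalise: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Probability that death is caused by exactly n hits, at dose ``D``.

    The unnormalised terms are ``P_n = exp(-N) N^n (1 - s_n) / n!`` for
    n >= 1 (s_n = 0 beyond the stored support).  With ``normalise=True``
    the terms are divided by their sum, giving the distribution of the
    hit multiplicity conditional on cell death.

    Returns ``(n, P_n)`` with n running over the retained range.
    """
    if not D > 0:
        raise DomainError("D must be > 0")
    N = D / params.zF
    # retain n until the Poisson tail beyond is < tail_tol
    from scipy.stats import poisson

    nmax = max(int(poisson.isf(tail_tol, N)) + 1, 2)
    n = np.arange(1, nmax + 1)
    s = np.array([params.s[i] if i < len(params.s) else 0.0 for i in n])
    logw = -N + n * math.log(N) - gammaln(n + 1)
    terms = np.exp(logw) * (1.0 - s)
    total = terms.sum()
    if total <= 0:
        raise DomainError("all s_i = 1 over the retained range: no kill mechanism")
    return (n, terms / total) if normalise else (n, terms)
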