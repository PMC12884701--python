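"""Robust fitting of the non-LQ model to survival data.

Fitting always happens on ln S (so high-dose points carry weight comparable
to low-dose ones) with a per-curve Huber loss H_k summed over curves,
L = sum_k H_k.  The Huber transition scale delta is not a free choice of the
user by default: it is set to 1.345 times a MAD-based robust scale of the
current residuals and re-estimated between refits, the standard
robust-regression convention.

The full calibration of a cell type against a set of survival curves is a
five-step procedure:

1. each curve is fitted separately for (zF_k, a 2-3 element window of free
   s_i, lnS0), trying several windows and keeping the best;
2. the per-curve zF_k train the fluence-spectrum regression for zF;
3. for each curve the SV radius R_k is solved so the event spectra
   reproduce the regression zF_k within +-1%, and multi-event spectra are
   built at those radii;
4. a global fit optimises the regression coefficients p_l and the response
   parameters (b, c, q0) against all curves simultaneously, re-solving
   radii/spectra once per outer iteration;
5. a final global fit re-optimises (b, c, q0) only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .core_model import (
    CellResponseParams,
    SurvivalCurve,
    log_survival,
    log_survival_raw,
)
from .errors import ConvergenceError, DataError, DomainError, ParameterError
from .response_function import ResponseParams, hit_survival_probs
from .zf_regression import FluenceSpectrum, ZfRegression, fit_regression, zf_from_fluence
from .microdosimetry import spectrum_moments

__all__ = [
    "SubsetSpec",
    "FitResult",
    "huber_objective",
    "robust_delta",
    "goodness_metrics",
    "fit_single_curve",
    "select_subset",
    "default_candidates",
    "global_fit",
    "run_pipeline",
    "PipelineConfig",
    "PipelineResult",
]

_LNS0_BOUND = 0.05


# ---------------------------------------------------------------------------
# loss and diagnostics


def huber_objective(residuals, delta: float) -> float:
    """Huber loss of ln-survival residuals.

    r^2/2 within |r| <= delta; delta (|r| - delta/2) beyond, so distant
    outliers contribute linearly instead of quadratically.
    """
    if not delta > 0:
        raise DomainError("delta must be > 0")
    r = np.abs(np.asarray(residuals, dtype=float))
    quad = 0.5 * r * r
    lin = delta * (r - 0.5 * delta)
    return float(np.where(r <= delta, quad, lin).sum())


def robust_delta(residuals, floor: float = 1e-3) -> float:
    """Huber transition scale: 1.345 x MAD-based robust sigma."""
    r = np.asarray(residuals, dtype=float)
    mad = np.median(np.abs(r - np.median(r)))
    return max(1.345 * 1.4826 * mad, floor)


def goodness_metrics(observed, predicted, n_free: int) -> tuple[float, float]:
    """(rms of ln-survival residuals, adjusted r^2 on ln S)."""
    obs = np.log(np.asarray(observed, dtype=float))
    pred = np.log(np.asarray(predicted, dtype=float))
    if obs.shape != pred.shape:
        raise DataError("observed and predicted lengths differ")
    n = obs.size
    if n < n_free + 2:
        raise DataError(f"need at least n_free + 2 = {n_free + 2} points")
    resid = obs - pred
    rms = float(np.sqrt(np.mean(resid**2)))
    sst = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_free - 1)
    return rms, adj


# ---------------------------------------------------------------------------
# subset specification


@dataclass(frozen=True)
class SubsetSpec:
    """Which s_i are free in a per-curve fit.

    ``free`` is a window of 2-3 consecutive indices; everything below the
    window is pinned at 1 (damage always repaired), everything above at 0
    (damage never repaired).
    """

    free: tuple[int, ...]
    imax: int = 6

    def __post_init__(self) -> None:
        free = tuple(int(i) for i in self.free)
        if not 2 <= len(free) <= 3:
            raise ParameterError("free window must contain 2-3 indices")
        if list(free) != list(range(free[0], free[-1] + 1)):
            raise ParameterError("free indices must be consecutive")
        if free[0] < 1 or free[-1] > self.imax:
            raise ParameterError(f"free indices must lie in 1..{self.imax}")
        object.__setattr__(self, "free", free)

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def ones_below(self) -> tuple[int, ...]:
        return tuple(range(1, self.free[0]))

    @property
    def zeros_above(self) -> tuple[int, ...]:
        return tuple(range(self.free[-1] + 1, self.imax + 1))

    def s_vector(self, values: Sequence[float]) -> tuple[float, ...]:
        """Full (s_0 .. s_imax) with the free window filled from ``values``."""
        if len(values) != self.n_free:
            raise ParameterError("wrong number of free values")
        s = [1.0] * self.free[0] + [float(v) for v in values]
        s += [0.0] * (self.imax - self.free[-1])
        return tuple(s)


def default_candidates(imax: int = 6) -> list[SubsetSpec]:
    """All 2- and 3-wide windows of consecutive free s_i within 1..imax."""
    out = [SubsetSpec(free=tuple(range(i, i + 2)), imax=imax)
           for i in range(1, imax)]
    out += [SubsetSpec(free=tuple(range(i, i + 3)), imax=imax)
            for i in range(1, imax - 1)]
    return out


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Outcome of a fit: fitted parameters plus ln-S diagnostics."""

    params: CellResponseParams
    loss: float
    rms_lnS: float
    adj_r2: float
    n_points: int
    n_free: int
    subset: SubsetSpec | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-curve fitting (step 1)


def _curve_loss(x: np.ndarray, subset: SubsetSpec, doses: np.ndarray,
                ln_obs: np.ndarray, delta: float | None) -> float:
    zF, lnS0 = x[0], x[-1]
    sfree = np.clip(x[1:-1], 0.0, 1.0)
    s = subset.s_vector(sfree)
    ln_pred = log_survival_raw(zF, s, lnS0, doses)
    r = ln_obs - ln_pred
    if delta is None:
        return float((r * r).sum())  # plain least squares
    return huber_objective(r, delta)


def _curve_loss_grad(x: np.ndarray, subset: SubsetSpec, doses: np.ndarray,
                     ln_obs: np.ndarray,
                     delta: float | None) -> tuple[float, np.ndarray]:
    """Loss and analytic gradient in (zF, free s_i, lnS0).

    With T(N) = sum_i N^i s_i / i! the derivatives of ln S are
    d/dzF = (1 - T'/T) N/zF, d/ds_j = (N^j/j!)/T, d/dlnS0 = 1; the Huber
    influence is psi(r) = r clipped at +-delta (2r for least squares).
    """
    zF, lnS0 = x[0], x[-1]
    sfree = np.clip(x[1:-1], 0.0, 1.0)
    s = np.asarray(subset.s_vector(sfree))
    N = doses / zF
    i = np.arange(s.size)
    fact = _FACTORIALS[: s.size]
    powers = N[:, None] ** i[None, :] / fact[None, :]  # N^i / i!
    T = powers @ s
    dT = powers[:, :-1] @ s[1:]  # dT/dN = sum_i N^(i-1)/(i-1)! s_i
    ln_pred = lnS0 - N + np.log(T)
    r = ln_obs - ln_pred
    if delta is None:
        loss = float((r * r).sum())
        psi = 2.0 * r
    else:
        a = np.abs(r)
        loss = float(np.where(a <= delta, 0.5 * r * r,
                              delta * (a - 0.5 * delta)).sum())
        psi = np.clip(r, -delta, delta)
    # d loss / d theta = sum psi * (-d lnS/d theta)
    dlnS_dzF = (1.0 - dT / T) * N / zF
    grad = np.empty(x.size)
    grad[0] = float((psi * -dlnS_dzF).sum())
    for col, j in enumerate(subset.free):
        grad[1 + col] = float((psi * -(powers[:, j] / T)).sum())
    grad[-1] = float((psi * -1.0).sum())
    return loss, grad


_FACTORIALS = np.array([math.factorial(i) for i in range(21)], dtype=float)


def fit_single_curve(curve: SurvivalCurve, subset: SubsetSpec,
                     zF_bounds: tuple[float, float] = (0.02, 20.0),
                     n_starts: int = 8, seed: int = 0,
                     loss: str = "huber") -> FitResult:
    """Fit (zF, free s_i, lnS0) to one survival curve on ln S.

    Multi-start bounded quasi-Newton (L-BFGS-B); with ``loss="huber"`` the
    transition scale is re-estimated from the residuals of the best fit and
    the fit repeated until the scale stabilises.  ``loss="lsq"`` gives plain
    least squares (used for robustness comparisons).
    """
    if len(curve) < 4:
        raise DataError(f"need >= 4 dose points, got {len(curve)}")
    doses = curve.doses
    ln_obs = np.log(curve.survival)
    nf = subset.n_free
    bounds = ([zF_bounds] + [(0.0, 1.0)] * nf
              + [(-_LNS0_BOUND, _LNS0_BOUND)])

    # crude slope-based zF guess from the deepest part of the curve
    slope = (ln_obs[-1] - ln_obs[0]) / (doses[-1] - doses[0])
    zF_guess = float(np.clip(-1.0 / slope if slope < 0 else 1.0, *zF_bounds))

    rng = np.random.default_rng(seed)
    starts = [np.array([zF_guess] + [max(0.6 - 0.25 * j, 0.0)
                                     for j in range(nf)] + [0.0])]
    for _ in range(n_starts - 1):
        z = zF_guess * float(np.exp(rng.uniform(-0.7, 0.7)))
        sv = np.sort(rng.uniform(0.0, 1.0, nf))[::-1]
        starts.append(np.array([np.clip(z, *zF_bounds), *sv, 0.0]))

    def run(delta):
        best = None
        for x0 in starts:
            res = minimize(_curve_loss_grad, x0, jac=True,
                           args=(subset, doses, ln_obs, delta),
                           method="L-BFGS-B", bounds=bounds,
                           options={"ftol": 1e-14, "gtol": 1e-10,
                                    "maxiter": 300})
            if best is None or res.fun < best.fun:
                best = res
        return best

    if loss == "lsq":
        best = run(None)
        delta = None
    elif loss == "huber":
        best = run(None)  # LS pass to seed the residual scale
        delta = None
        for _ in range(3):
            zF, lnS0 = best.x[0], best.x[-1]
            s = subset.s_vector(np.clip(best.x[1:-1], 0, 1))
            r = ln_obs - log_survival_raw(zF, s, lnS0, doses)
            new_delta = robust_delta(r)
            if delta is not None and abs(new_delta - delta) < 0.01 * delta:
                break
            delta = new_delta
            best = run(delta)
    else:
        raise ParameterError(f"unknown loss {loss!r}")

    zF = float(best.x[0])
    sfree = tuple(float(v) for v in np.clip(best.x[1:-1], 0.0, 1.0))
    lnS0 = float(best.x[-1])
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # a fitted window may break monotonicity
        params = CellResponseParams(zF=zF, s=subset.s_vector(sfree),
                                    lnS0=lnS0,
                                    label=curve.meta.get("label", ""))
    pred = np.exp(log_survival_raw(zF, params.s, lnS0, doses))
    n_free_total = 2 + nf  # zF, lnS0 and the free window
    rms, adj = goodness_metrics(curve.survival, pred,
                                min(n_free_total, len(curve) - 2))
    return FitResult(params=params, loss=float(best.fun), rms_lnS=rms,
                     adj_r2=adj, n_points=len(curve), n_free=n_free_total,
                     subset=subset, converged=bool(best.success),
                     extra={"delta": delta})


def select_subset(curve: SurvivalCurve,
                  candidates: Sequence[SubsetSpec] | None = None,
                  **kw) -> tuple[SubsetSpec, FitResult]:
    """Fit the curve under each candidate window and keep the best.

    The candidate with the lowest final Huber loss wins; near-ties (within
    1e-9 relative) go to the candidate with fewer free parameters, and to
    the earlier candidate among equals.
    """
    cands = list(candidates) if candidates is not None else None
    if cands is None:
        cands = default_candidates()
    if len(cands) < 1:
        raise DataError("need at least one candidate subset")
    best: tuple[SubsetSpec, FitResult] | None = None
    for cand in cands:
        res = fit_single_curve(curve, cand, **kw)
        if best is None:
            best = (cand, res)
            continue
        tol = 1e-9 * max(abs(best[1].loss), 1.0)
        if res.loss < best[1].loss - tol:
            best = (cand, res)
        elif res.loss <= best[1].loss + tol and cand.n_free < best[0].n_free:
            best = (cand, res)
    return best


# ---------------------------------------------------------------------------
# global fitting (steps 4 and 5)


@dataclass
class PipelineConfig:
    """Settings of the five-step calibration."""

    imax: int = 4                     # multi-event truncation for spectra
    candidates: list[SubsetSpec] | None = None
    n_starts: int = 8                 # multi-starts for per-curve fits
    seed: int = 0
    zf_tol: float = 0.01              # +-1% radius acceptance
    outer_max: int = 10               # stage-4 outer iterations
    zf_change_tol: float = 0.005      # stop when the zF set moves < 0.5%
    maxiter_global: int = 400


@dataclass
class PipelineResult:
    """Structured report of a pipeline run."""

    regression: ZfRegression
    response: ResponseParams
    zF: np.ndarray
    radii: np.ndarray
    s: np.ndarray
    lnS0: np.ndarray
    per_curve: list[FitResult]
    loss: float
    rms_lnS: float
    adj_r2: float
    history: list[dict] = field(default_factory=list)

    def report(self) -> dict:
        return {
            "regression": self.regression.to_dict(),
            "response": self.response.to_dict(),
            "zF_Gy": [float(v) for v in self.zF],
            "R_um": [float(v) for v in self.radii],
            "s": [[float(v) for v in row] for row in self.s],
            "lnS0": [float(v) for v in self.lnS0],
            "loss": float(self.loss),
            "rms_lnS": float(self.rms_lnS),
            "adj_r2": float(self.adj_r2),
            "per_curve": [
                {"label": r.params.label, "zF_Gy": r.params.zF,
                 "s": list(r.params.s), "lnS0": r.params.lnS0,
                 "loss": r.loss, "rms_lnS": r.rms_lnS, "adj_r2": r.adj_r2,
                 "free": list(r.subset.free) if r.subset else None}
                for r in self.per_curve],
            "history": self.history,
        }


def _solve_radius_with_provider(provider, zF_target: float, tol: float,
                                R0: float = 0.4) -> tuple[float, list, object]:
    """1/R^2 fixed-point radius solve against provider-built spectra."""
    R = R0
    for _ in range(40):
        spectra, mixed = provider(R)
        _, zF, _ = spectrum_moments(spectra[0])
        if abs(zF - zF_target) / zF_target <= tol:
            return R, spectra, mixed
        R *= math.sqrt(zF / zF_target)
        if not (1e-4 < R < 1e3):
            raise ConvergenceError("radius solve left the physical range")
    raise ConvergenceError("provider radius solve did not converge")


def _dataset_loss(curves, ln_preds, deltas):
    L = 0.0
    for curve, ln_pred, delta in zip(curves, ln_preds, deltas):
        L += huber_objective(np.log(curve.survival) - ln_pred, delta)
    return L


class _GlobalObjective:
    """Loss L = sum_k H_k as a function of (p_l, b, c, q0) with radii and
    spectra frozen (they are re-solved once per outer iteration)."""

    def __init__(self, curves, fluences, spectra_sets, lnS0, imax, deltas,
                 fit_regression_too: bool):
        self.curves = curves
        self.fluences = fluences
        self.spectra_sets = spectra_sets
        self.lnS0 = lnS0
        self.imax = imax
        self.deltas = deltas
        self.fit_p = fit_regression_too

    def unpack(self, x, p_fixed=None):
        if self.fit_p:
            p = tuple(x[:4])
            b, c, q0 = x[4], x[5], x[6]
        else:
            p = p_fixed
            b, c, q0 = x
        return p, ResponseParams(b=float(b), c=float(c), q0=float(q0))

    def lnS_set(self, p, rp):
        reg = ZfRegression(p=p)
        out = []
        for curve, phi, spectra in zip(self.curves, self.fluences,
                                       self.spectra_sets):
            zF = zf_from_fluence(reg, phi)
            s = hit_survival_probs(rp, spectra)
            out.append(log_survival_raw(zF, (1.0, *s), self.lnS0[len(out)],
                                        curve.doses))
        return out

    def __call__(self, x, p_fixed=None):
        try:
            p, rp = self.unpack(x, p_fixed)
            ln_preds = self.lnS_set(p, rp)
        except Exception:
            return 1e12
        return _dataset_loss(self.curves, ln_preds, self.deltas)


def global_fit(curves: list[SurvivalCurve], fluences: list[FluenceSpectrum],
               spectra_sets: list, reg0: ZfRegression, rp0: ResponseParams,
               lnS0: np.ndarray, stage: int = 4,
               deltas: Sequence[float] | None = None,
               maxiter: int = 400,
               ) -> tuple[ZfRegression, ResponseParams, float, float]:
    """One global optimisation pass with radii/spectra frozen.

    Stage 4 optimises the regression coefficients p_l jointly with the
    response parameters (b, c, q0); stage 5 freezes p_l and optimises the
    response only.  Returns (regression, response, loss, start_loss); the
    returned loss never exceeds the start loss (best-of contract).
    """
    if stage not in (4, 5):
        raise DomainError("stage must be 4 or 5")
    if deltas is None:
        obj0 = _GlobalObjective(curves, fluences, spectra_sets, lnS0,
                                len(spectra_sets[0]), [1.0] * len(curves),
                                stage == 4)
        x0_tmp = (list(reg0.p) + [rp0.b, rp0.c, rp0.q0] if stage == 4
                  else [rp0.b, rp0.c, rp0.q0])
        ln_preds = obj0.lnS_set(reg0.p, rp0)
        deltas = [robust_delta(np.log(c.survival) - lp)
                  for c, lp in zip(curves, ln_preds)]
    obj = _GlobalObjective(curves, fluences, spectra_sets, lnS0,
                           len(spectra_sets[0]), list(deltas), stage == 4)
    qscale = max(abs(rp0.q0), rp0.b)
    if stage == 4:
        x0 = np.array(list(reg0.p) + [rp0.b, rp0.c, rp0.q0])
        bounds = [(None, None)] * 4 + [(1e-4, None), (0.05, 20.0),
                                       (-50 * qscale, 50 * qscale)]
        args = (None,)
    else:
        x0 = np.array([rp0.b, rp0.c, rp0.q0])
        bounds = [(1e-4, None), (0.05, 20.0), (-50 * qscale, 50 * qscale)]
        args = (reg0.p,)
    loss0 = obj(x0, *args)
    res = minimize(obj, x0, args=args, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-6,
                            "fatol": 1e-10})
    if res.fun <= loss0:
        x = res.x
        loss = float(res.fun)
    else:  # optimiser must never worsen the accepted state
        x = x0
        loss = float(loss0)
    p, rp = obj.unpack(x, *args)
    reg = ZfRegression(p=tuple(p), E_valid=reg0.E_valid, label=reg0.label)
    return reg, rp, loss, float(loss0)


def run_pipeline(curves: list[SurvivalCurve],
                 fluences: list[FluenceSpectrum],
                 provider_factory: Callable[[FluenceSpectrum], Callable],
                 config: PipelineConfig | None = None,
                 rp0: ResponseParams | None = None) -> PipelineResult:
    """Execute the five-step calibration.

    ``provider_factory(phi)`` must return a deterministic ``provider(R)``
    giving ``(spectra list f1..f_imax, mixed per-particle spectrum)`` for
    the beam ``phi`` at SV radius R (see
    :func:`microsurv.synthetic_data.spectra_provider`).
    """
    cfg = config or PipelineConfig()
    if len(curves) != len(fluences):
        raise DataError("one fluence spectrum per curve is required")
    history: list[dict] = []

    # --- step 1: independent per-curve fits -----------------------------
    per_curve: list[FitResult] = []
    for k, curve in enumerate(curves):
        _, res = select_subset(curve, cfg.candidates,
                               n_starts=cfg.n_starts, seed=cfg.seed + k)
        per_curve.append(res)
    zF_set = np.array([r.params.zF for r in per_curve])
    lnS0 = np.array([r.params.lnS0 for r in per_curve])
    history.append({"stage": 1, "zF": zF_set.tolist(),
                    "loss": float(sum(r.loss for r in per_curve))})

    # --- step 2: regression fit ------------------------------------------
    reg, resid = fit_regression(list(zip(fluences, zF_set)))
    zF_set = np.array([zf_from_fluence(reg, phi) for phi in fluences])
    history.append({"stage": 2, "p": list(reg.p), "zF": zF_set.tolist(),
                    "resid": [float(r) for r in resid]})

    providers = [provider_factory(phi) for phi in fluences]

    def solve_all(zfs):
        radii, spectra_sets = [], []
        for prov, z in zip(providers, zfs):
            R, spectra, _ = _solve_radius_with_provider(prov, z, cfg.zf_tol)
            radii.append(R)
            spectra_sets.append(spectra)
        return np.array(radii), spectra_sets

    # --- step 3: radii and spectra ---------------------------------------
    radii, spectra_sets = solve_all(zF_set)
    history.append({"stage": 3, "R": radii.tolist()})

    # initial response guess: transition at the scale of the mean event size
    if rp0 is None:
        qFs = [spectrum_moments(ss[0])[0] for ss in spectra_sets]
        qbar = float(np.median(qFs))
        rp0 = ResponseParams(b=0.5 * qbar, c=1.0, q0=0.2 * qbar)

    # --- step 4: joint (p, B) optimisation, radii refreshed per outer pass
    rp = rp0
    loss = math.inf
    for outer in range(cfg.outer_max):
        reg, rp, loss, loss0 = global_fit(curves, fluences, spectra_sets,
                                          reg, rp, lnS0, stage=4,
                                          maxiter=cfg.maxiter_global)
        new_zF = np.array([zf_from_fluence(reg, phi) for phi in fluences])
        change = float(np.max(np.abs(new_zF - zF_set) / zF_set))
        zF_set = new_zF
        radii, spectra_sets = solve_all(zF_set)
        history.append({"stage": 4, "outer": outer, "loss_start": loss0,
                        "loss": loss, "zF": zF_set.tolist(),
                        "R": radii.tolist(), "zF_change": change,
                        "response": rp.to_dict()})
        if change < cfg.zf_change_tol:
            break

    # --- step 5: response-only refinement --------------------------------
    reg, rp, loss, loss0 = global_fit(curves, fluences, spectra_sets, reg,
                                      rp, lnS0, stage=5,
                                      maxiter=cfg.maxiter_global)
    history.append({"stage": 5, "loss_start": loss0, "loss": loss,
                    "response": rp.to_dict()})

    # final diagnostics
    s_rows = np.vstack([hit_survival_probs(rp, ss) for ss in spectra_sets])
    obs_all, pred_all = [], []
    import warnings as _w

    for k, curve in enumerate(curves):
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            params = CellResponseParams(zF=zF_set[k], s=(1.0, *s_rows[k]),
                                        lnS0=lnS0[k])
            pred = np.exp(log_survival(params, curve.doses))
        obs_all.append(curve.survival)
        pred_all.append(pred)
    n_free = 7 + len(curves)  # p1..p4, b, c, q0 plus per-curve lnS0
    rms, adj = goodness_metrics(np.concatenate(obs_all),
                                np.concatenate(pred_all), n_free)
    return PipelineResult(regression=reg, response=rp, zF=zF_set,
                          radii=radii, s=s_rows, lnS0=lnS0,
                          per_curve=per_curve, loss=loss, rms_lnS=rms,
                          adj_r2=adj, history=history)
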