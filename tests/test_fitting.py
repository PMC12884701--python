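"""Huber machinery, per-curve fits, subset selection and the five-step
pipeline."""

import numpy as np
import pytest

from microsurv.core_model import CellResponseParams, SurvivalCurve, log_survival
from microsurv.errors import DataError, ParameterError
from microsurv.fitting import (
    PipelineConfig,
    SubsetSpec,
    default_candidates,
    fit_single_curve,
    global_fit,
    goodness_metrics,
    huber_objective,
    run_pipeline,
    select_subset,
)
from microsurv.response_function import hit_survival_probs
from microsurv.synthetic_data import spectra_provider
from microsurv.zf_regression import zf_from_fluence


class TestHuber:
    def test_zero_residuals(self):
        assert huber_objective(np.zeros(5), 1.0) == 0.0

    def test_branch_continuity_at_knee(self):
        delta = 0.7
        quad = huber_objective([delta - 1e-12], delta)
        lin = huber_objective([delta + 1e-12], delta)
        assert quad == pytest.approx(delta**2 / 2, rel=1e-9)
        assert lin == pytest.approx(delta**2 / 2, rel=1e-9)

    def test_outlier_contribution_reduced(self):
        delta = 0.5
        r = 10 * delta
        assert huber_objective([r], delta) == pytest.approx(
            9.5 * delta**2, rel=1e-12)
        # versus r^2/2 = 50 delta^2 under squared loss
        assert 0.5 * r**2 == pytest.approx(50 * delta**2, rel=1e-12)


class TestGoodness:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 0.5, 0.1, 0.01, 0.001])
        rms, adj = goodness_metrics(obs, obs, 2)
        assert rms == 0.0 and adj == 1.0

    def test_constant_predictor_negative_adj(self):
        obs = np.array([1.0, 0.5, 0.1, 0.01, 0.001])
        pred = np.full(5, np.exp(np.mean(np.log(obs))))
        rms, adj = goodness_metrics(obs, pred, 2)
        assert adj < 0

    def test_hand_computed_case(self):
        # spreadsheet arithmetic on ln-residuals of a 5-point case
        obs = np.array([1.0, 0.6, 0.3, 0.1, 0.03])
        pred = np.array([0.95, 0.65, 0.28, 0.11, 0.025])
        ln_r = np.log(obs) - np.log(pred)
        rms_hand = float(np.sqrt(np.mean(ln_r**2)))
        r2_hand = 1 - np.sum(ln_r**2) / np.sum(
            (np.log(obs) - np.mean(np.log(obs)))**2)
        adj_hand = 1 - (1 - r2_hand) * 4 / (5 - 1 - 1)
        rms, adj = goodness_metrics(obs, pred, 1)
        assert rms == pytest.approx(rms_hand, rel=1e-12)
        assert adj == pytest.approx(adj_hand, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            goodness_metrics([1.0, 0.5], [1.0, 0.5, 0.2], 1)


class TestSubsetSpec:
    def test_partition(self):
        sub = SubsetSpec(free=(2, 3), imax=6)
        assert sub.ones_below == (1,)
        assert sub.zeros_above == (4, 5, 6)
        s = sub.s_vector([0.4, 0.1])
        assert s == (1.0, 1.0, 0.4, 0.1, 0.0, 0.0, 0.0)

    def test_invalid_windows(self):
        with pytest.raises(ParameterError):
            SubsetSpec(free=(1,))
        with pytest.raises(ParameterError):
            SubsetSpec(free=(1, 3))  # not consecutive
        with pytest.raises(ParameterError):
            SubsetSpec(free=(5, 6, 7), imax=6)

    def test_default_candidates(self):
        cands = default_candidates(6)
        assert len(cands) == 9
        assert all(2 <= c.n_free <= 3 for c in cands)


def _curve_from_params(params, doses):
    return SurvivalCurve(doses=np.asarray(doses, float),
                         survival=np.exp(log_survival(params,
                                                      np.asarray(doses,
                                                                 float))),
                         meta={"label": params.label})


class TestFitSingleCurve:
    DOSES = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)

    def test_noise_free_recovery_matching_subset(self):
        truth = CellResponseParams(zF=0.62, s=(1.0, 0.35, 0.08, 0.0, 0.0,
                                               0.0, 0.0), lnS0=0.0)
        curve = _curve_from_params(truth, self.DOSES)
        res = fit_single_curve(curve, SubsetSpec(free=(1, 2)), seed=1)
        assert res.params.zF == pytest.approx(truth.zF, rel=0.01)
        assert res.params.s[1] == pytest.approx(truth.s[1], abs=0.01)
        assert res.params.s[2] == pytest.approx(truth.s[2], abs=0.01)

    def test_recovery_under_noise(self):
        truth = CellResponseParams(zF=0.62, s=(1.0, 0.35, 0.08, 0.0, 0.0,
                                               0.0, 0.0), lnS0=0.0)
        rng = np.random.default_rng(17)
        doses = np.linspace(0.5, 10, 10)
        lnS = log_survival(truth, doses) + 0.05 * rng.standard_normal(10)
        curve = SurvivalCurve(doses=doses, survival=np.exp(lnS))
        res = fit_single_curve(curve, SubsetSpec(free=(1, 2)), seed=1)
        assert res.params.zF == pytest.approx(truth.zF, rel=0.10)

    def test_exponential_curve_drives_s1_to_zero(self):
        truth = CellResponseParams(zF=0.8, s=(1.0, 0.0))
        curve = _curve_from_params(truth, self.DOSES)
        res = fit_single_curve(curve, SubsetSpec(free=(1, 2)), seed=1)
        assert res.params.s[1] < 0.01
        assert res.params.zF == pytest.approx(0.8, rel=0.01)

    def test_too_few_points(self):
        truth = CellResponseParams(zF=0.8, s=(1.0, 0.0))
        curve = _curve_from_params(truth, (1.0, 2.0, 3.0))
        with pytest.raises(DataError):
            fit_single_curve(curve, SubsetSpec(free=(1, 2)))

    def test_lnS0_bound_respected(self):
        truth = CellResponseParams(zF=0.62, s=(1.0, 0.4, 0.1), lnS0=0.0)
        curve = _curve_from_params(truth, self.DOSES)
        res = fit_single_curve(curve, SubsetSpec(free=(1, 2)), seed=1)
        assert abs(res.params.lnS0) <= 0.05 + 1e-12


class TestSelectSubset:
    def test_true_window_wins(self):
        truth = CellResponseParams(zF=0.62, s=(1.0, 0.35, 0.08, 0.0, 0.0,
                                               0.0, 0.0), lnS0=0.0)
        curve = _curve_from_params(truth, np.linspace(0.5, 10, 10))
        sub, res = select_subset(curve, [SubsetSpec(free=(1, 2)),
                                         SubsetSpec(free=(3, 4))], seed=2)
        assert sub.free == (1, 2)

    def test_identical_candidates_first_returned(self):
        truth = CellResponseParams(zF=0.62, s=(1.0, 0.35, 0.08), lnS0=0.0)
        curve = _curve_from_params(truth, np.linspace(0.5, 10, 10))
        c1, c2 = SubsetSpec(free=(1, 2)), SubsetSpec(free=(1, 2))
        sub, _ = select_subset(curve, [c1, c2], seed=2)
        assert sub is c1

    def test_single_candidate(self):
        truth = CellResponseParams(zF=0.62, s=(1.0, 0.35, 0.08), lnS0=0.0)
        curve = _curve_from_params(truth, np.linspace(0.5, 10, 10))
        only = SubsetSpec(free=(2, 3))
        sub, _ = select_subset(curve, [only], seed=2)
        assert sub is only


class TestPipeline:
    def test_zero_noise_end_to_end(self, zero_noise_dataset):
        scn, curves, truth = zero_noise_dataset
        result = run_pipeline(
            curves, truth.fluences,
            lambda phi: spectra_provider(scn.spectrum_model, phi,
                                         imax=scn.imax),
            PipelineConfig(imax=scn.imax, seed=1))
        # radii recovered within 3%
        assert np.all(np.abs(result.radii / truth.radii - 1.0) < 0.03)
        # final rms below the (zero) noise scale up to numerical slack
        assert result.rms_lnS < 0.05
        assert result.adj_r2 > 0.99
        # within each accepted optimisation stage the loss never increases
        # (between outer iterations the objective itself is refreshed:
        # new radii, spectra and Huber scales)
        for h in result.history:
            if h["stage"] in (4, 5):
                assert h["loss"] <= h["loss_start"] + 1e-12

    def test_determinism(self, zero_noise_dataset):
        scn, curves, truth = zero_noise_dataset
        kw = dict(config=PipelineConfig(imax=scn.imax, seed=7))
        factory = lambda phi: spectra_provider(scn.spectrum_model, phi,
                                               imax=scn.imax)
        r1 = run_pipeline(curves, truth.fluences, factory, **kw)
        r2 = run_pipeline(curves, truth.fluences, factory, **kw)
        assert r1.report() == r2.report()

    def test_optimiser_does_not_worsen_truth(self, zero_noise_dataset):
        """A global fit started at the generating truth keeps a loss no
        worse than the truth's, and its survival predictions stay within
        1% of the noise-free data everywhere."""
        scn, curves, truth = zero_noise_dataset
        factory = lambda phi: spectra_provider(scn.spectrum_model, phi,
                                               imax=scn.imax)
        spectra_sets = [factory(phi)(R)[0]
                        for phi, R in zip(truth.fluences, truth.radii)]
        lnS0 = np.zeros(len(curves))
        reg, rp, loss, loss_truth = global_fit(
            curves, truth.fluences, spectra_sets, scn.regression,
            scn.response, lnS0, stage=4)
        assert loss <= loss_truth + 1e-12
        for k, curve in enumerate(curves):
            s = hit_survival_probs(rp, spectra_sets[k])
            zF = zf_from_fluence(reg, truth.fluences[k])
            params = CellResponseParams(zF=zF, s=(1.0, *s), lnS0=0.0)
            pred = np.exp(log_survival(params, curve.doses))
            assert np.allclose(pred, curve.survival, rtol=0.01)

    def test_fitted_curves_close_to_data(self, zero_noise_dataset):
        scn, curves, truth = zero_noise_dataset
        factory = lambda phi: spectra_provider(scn.spectrum_model, phi,
                                               imax=scn.imax)
        result = run_pipeline(curves, truth.fluences, factory,
                              PipelineConfig(imax=scn.imax, seed=1))
        for k, curve in enumerate(curves):
            s = hit_survival_probs(result.response,
                                   factory(truth.fluences[k])(
                                       result.radii[k])[0])
            params = CellResponseParams(zF=result.zF[k], s=(1.0, *s),
                                        lnS0=result.lnS0[k])
            pred = np.exp(log_survival(params, curve.doses))
            assert np.allclose(pred, curve.survival, rtol=0.05)

    def test_stage5_fixed_point(self, zero_noise_dataset):
        """Re-running the response-only stage from an already optimal state
        must not move the parameters appreciably."""
        scn, curves, truth = zero_noise_dataset
        factory = lambda phi: spectra_provider(scn.spectrum_model, phi,
                                               imax=scn.imax)
        spectra_sets = [factory(phi)(R)[0]
                        for phi, R in zip(truth.fluences, truth.radii)]
        reg, rp, loss, _ = global_fit(curves, truth.fluences, spectra_sets,
                                      scn.regression, scn.response,
                                      np.zeros(len(curves)), stage=5)
        assert rp.b == pytest.approx(scn.response.b, rel=0.05)
        assert rp.c == pytest.approx(scn.response.c, rel=0.05)
        assert rp.q0 == pytest.approx(scn.response.q0, abs=0.05)
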