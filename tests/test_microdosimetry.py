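"""Spectrum normalisation, convolution recurrence, compound-Poisson mixing
and specific-energy geometry."""

import numpy as np
import pytest

from microsurv.constants import GY_PER_KEV_PER_PG
from microsurv.errors import (
    ConfigurationError,
    DegenerateSpectrumError,
    DomainError,
    GridError,
)
from microsurv.microdosimetry import (
    EventSpectrum,
    PerParticleSpectrum,
    SVGeometry,
    compound_dose_spectrum,
    condition_per_particle,
    convolve_spectra,
    mix_polyenergetic,
    multi_event_spectra,
    normalize_event_spectrum,
    spectrum_moments,
    zf_from_geometry,
)
from microsurv.synthetic_data import synth_fluence_spectrum
from microsurv.zf_regression import FluenceSpectrum


def sample_from(spec, rng, n):
    """Inverse-CDF draws from a grid spectrum (Monte-Carlo oracle)."""
    edges = np.concatenate([[spec.q_grid[0] - spec.dq / 2],
                            spec.q_grid + spec.dq / 2])
    cdf = np.concatenate([[0.0], np.cumsum(spec.density) * spec.dq])
    cdf /= cdf[-1]
    return np.interp(rng.uniform(size=n), cdf, edges)


def ks_distance(spec, samples):
    xs = np.sort(samples)
    ecdf = np.arange(1, xs.size + 1) / xs.size
    return float(np.max(np.abs(spec.cdf(xs) - ecdf)))


class TestNormalize:
    def test_uniform(self):
        sp = normalize_event_spectrum(np.full(100, 7.0), dq=0.1)
        assert np.allclose(sp.density, 0.1)
        assert sp.norm == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        raw = np.exp(-0.5 * ((np.arange(200) * 0.05 - 3) / 0.7) ** 2)
        sp1 = normalize_event_spectrum(raw, dq=0.05)
        sp2 = normalize_event_spectrum(sp1.density, dq=0.05)
        assert np.allclose(sp1.density, sp2.density, rtol=1e-12)

    def test_gaussian_integral_one(self):
        q = (np.arange(400) + 0.5) * 0.02
        raw = 13.7 * np.exp(-0.5 * ((q - 3) / 0.5) ** 2)
        sp = normalize_event_spectrum(raw, dq=0.02)
        # quadrature oracle on the same grid
        assert np.sum(sp.density) * 0.02 == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            normalize_event_spectrum(np.zeros(10), dq=0.1)


class TestMoments:
    def test_unit_mass_sphere_conversion(self):
        # 1 pg water sphere has R = (3/(4 pi))^(1/3) um
        R = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        dq = 1e-4
        # narrow spike at q = 1 keV
        raw = np.zeros(400)
        raw[200] = 1.0
        sp = normalize_event_spectrum(raw, dq=dq, site=SVGeometry(R=R))
        # shift grid so the spike sits exactly at 1 keV
        sp = EventSpectrum(sp.q_grid + (1.0 - sp.q_grid[200]), sp.density,
                           multiplicity=1, site=SVGeometry(R=R))
        qF, zF, yF = spectrum_moments(sp)
        assert qF == pytest.approx(1.0, rel=1e-12)
        assert zF == pytest.approx(GY_PER_KEV_PER_PG, rel=1e-9)

    def test_identity_between_outputs(self, gamma_f1):
        qF, zF, yF = spectrum_moments(gamma_f1)
        R, rho = gamma_f1.site.R, gamma_f1.site.rho
        assert zF == pytest.approx(
            GY_PER_KEV_PER_PG * yF / (np.pi * rho * R**2), rel=1e-12)

    def test_xray_reference_geometry(self):
        # yF = 2.0 keV/um with zF = 0.6749 Gy implies R ~ 0.39 um
        R = np.sqrt(GY_PER_KEV_PER_PG * 2.0 / (np.pi * 0.6749))
        assert 0.35 < R < 0.45
        assert zf_from_geometry(2.0, SVGeometry(R=R)) == pytest.approx(
            0.6749, rel=1e-12)

    def test_inverse_square_law(self):
        z1 = zf_from_geometry(2.0, SVGeometry(R=0.3))
        z2 = zf_from_geometry(2.0, SVGeometry(R=0.6))
        assert z1 == pytest.approx(4 * z2, rel=1e-12)

    def test_missing_geometry(self, uniform_f1):
        naked = EventSpectrum(uniform_f1.q_grid, uniform_f1.density)
        with pytest.raises(ConfigurationError):
            spectrum_moments(naked)


class TestConvolution:
    def test_uniform_self_convolution_is_triangular(self, uniform_f1):
        f2 = convolve_spectra(uniform_f1, uniform_f1)
        tri = np.where(f2.q_grid <= 1.0, f2.q_grid, 2.0 - f2.q_grid)
        tri = np.clip(tri, 0.0, None)
        assert np.allclose(f2.density, tri, atol=0.02)
        assert f2.q_grid[np.argmax(f2.density)] == pytest.approx(1.0,
                                                                 abs=0.02)

    def test_mean_additivity(self, gamma_f1):
        f2 = convolve_spectra(gamma_f1, gamma_f1)
        assert f2.mean == pytest.approx(2 * gamma_f1.mean, rel=1e-3)

    def test_variance_additivity(self, gamma_f1):
        spectra = multi_event_spectra(gamma_f1, 4)
        v1 = gamma_f1.var
        for i, f in enumerate(spectra, start=1):
            assert f.var == pytest.approx(i * v1, rel=5e-3)

    def test_means_in_integer_ratio(self, gamma_f1):
        spectra = multi_event_spectra(gamma_f1, 4)
        m1 = gamma_f1.mean
        for i, f in enumerate(spectra, start=1):
            assert f.mean == pytest.approx(i * m1, rel=2e-3)
            assert f.multiplicity == i

    def test_monte_carlo_oracle(self, gamma_f1):
        rng = np.random.default_rng(1234)
        draws = sample_from(gamma_f1, rng, 10**5) + \
            sample_from(gamma_f1, rng, 10**5)
        f2 = convolve_spectra(gamma_f1, gamma_f1)
        assert ks_distance(f2, draws) < 0.01

    def test_grid_mismatch(self, gamma_f1, uniform_f1):
        with pytest.raises(GridError):
            convolve_spectra(gamma_f1, uniform_f1)

    def test_imax_one_identity(self, gamma_f1):
        assert multi_event_spectra(gamma_f1, 1) == [gamma_f1]


class TestCompound:
    def test_no_hits(self, gamma_f1):
        zero, mix = compound_dose_spectrum(gamma_f1, 0.0)
        assert zero == 1.0 and mix is None

    def test_total_mass(self, gamma_f1):
        for N in (0.5, 2.0, 10.0):
            zero, mix = compound_dose_spectrum(gamma_f1, N, tail_tol=1e-8)
            assert zero + mix.norm >= 1.0 - 1e-8 - 1e-6

    def test_truncation_index(self, gamma_f1):
        from microsurv.microdosimetry import poisson_truncation

        imax = poisson_truncation(1.0, 1e-8)
        assert 9 <= imax <= 13
        zero, mix = compound_dose_spectrum(gamma_f1, 1.0, tail_tol=1e-8)
        assert zero + mix.norm == pytest.approx(1.0, abs=1e-7)

    def test_mean_identity(self, gamma_f1):
        # compound-Poisson mean: E[q] = N qF (atom contributes 0)
        qF = gamma_f1.mean
        for N in (0.5, 2.0, 10.0):
            zero, mix = compound_dose_spectrum(gamma_f1, N, tail_tol=1e-10)
            mean_total = (mix.q_grid * mix.density).sum() * mix.dq
            assert mean_total == pytest.approx(N * qF, rel=1e-3)

    def test_monte_carlo_oracle(self, gamma_f1):
        rng = np.random.default_rng(99)
        n_cells = 10**5
        for N in (0.5, 2.0, 10.0):
            counts = rng.poisson(N, n_cells)
            deposits = np.zeros(n_cells)
            for ci in np.unique(counts):
                if ci == 0:
                    continue
                idx = counts == ci
                deposits[idx] = sample_from(
                    gamma_f1, rng, int(idx.sum()) * ci).reshape(-1, ci).sum(
                        axis=1)
            zero, mix = compound_dose_spectrum(gamma_f1, N, tail_tol=1e-10)
            pos = deposits[deposits > 0]
            xs = np.sort(pos)
            ecdf = np.arange(1, xs.size + 1) / xs.size
            model_cdf = mix.cdf(xs) / mix.norm
            assert np.max(np.abs(model_cdf - ecdf)) < 0.015

    def test_negative_n_rejected(self, gamma_f1):
        with pytest.raises(DomainError):
            compound_dose_spectrum(gamma_f1, -1.0)


class TestPerParticle:
    def _pp(self, hit_prob):
        n = 300
        dq = 0.01
        dens = np.exp(-((np.arange(n) + 0.5) * dq))
        dens = dens / (dens.sum() * dq) * hit_prob
        return PerParticleSpectrum((np.arange(n) + 0.5) * dq, dens,
                                   site=SVGeometry(R=0.4),
                                   hit_prob=hit_prob, energy=30.0)

    def test_hit_prob_one_unchanged(self):
        pp = self._pp(1.0)
        f1 = condition_per_particle(pp)
        assert np.allclose(f1.density, pp.density, rtol=1e-9)

    def test_half_mass_doubles(self):
        pp = self._pp(0.5)
        f1 = condition_per_particle(pp)
        assert np.allclose(f1.density, 2 * pp.density, rtol=1e-9)
        assert f1.norm == pytest.approx(1.0, abs=1e-9)

    def test_mix_single_energy_identity(self):
        pp = self._pp(0.7)
        phi = FluenceSpectrum(np.array([30.0]), np.array([1.0]))
        mixed = mix_polyenergetic([pp], phi)
        assert np.allclose(mixed.density, pp.density)
        assert mixed.hit_prob == pytest.approx(0.7)
        f1 = condition_per_particle(mixed)
        assert f1.norm == pytest.approx(1.0, abs=1e-9)

    def test_mix_two_equal_components(self):
        a, b = self._pp(0.2), self._pp(0.4)
        b = PerParticleSpectrum(b.q_grid, b.density, site=b.site,
                                hit_prob=0.4, energy=40.0)
        E = np.linspace(30, 40, 41)
        phi = FluenceSpectrum(E, np.ones_like(E))
        mixed = mix_polyenergetic([a, b], phi)
        assert mixed.hit_prob == pytest.approx(0.3, rel=1e-9)

    def test_mixture_mean_between_components(self):
        from microsurv.synthetic_data import (
            SpectrumModel,
            synth_single_event_spectrum,
        )

        model = SpectrumModel()
        dq = 0.01
        lo = synth_single_event_spectrum(model, 20.0, 0.4, dq=dq)
        hi = synth_single_event_spectrum(model, 40.0, 0.4, dq=dq)
        E = np.linspace(20, 40, 61)
        phi = FluenceSpectrum(E, np.ones_like(E))
        mixed = mix_polyenergetic([lo, hi], phi)
        m = condition_per_particle(mixed).mean
        m_lo = condition_per_particle(hi).mean  # smaller qF (higher E)
        m_hi = condition_per_particle(lo).mean
        assert m_lo < m < m_hi


class TestGridRefinement:
    def test_halving_dq_stable(self):
        from microsurv.response_function import (
            ResponseParams,
            hit_survival_probs,
        )
        from microsurv.synthetic_data import (
            SpectrumModel,
            synth_single_event_spectrum,
        )

        model = SpectrumModel()
        rp = ResponseParams(b=0.8, c=1.3, q0=0.3)
        vals = {}
        for frac in (1 / 200, 1 / 400):
            m = SpectrumModel(dq_frac=frac)
            pp = synth_single_event_spectrum(m, 30.0, 0.4)
            f1 = condition_per_particle(pp)
            qF, zF, yF = spectrum_moments(f1)
            s = hit_survival_probs(rp, multi_event_spectra(f1, 4))
            vals[frac] = (qF, zF, *s)
        a, b = np.array(vals[1 / 200]), np.array(vals[1 / 400])
        assert np.all(np.abs(a - b) / np.abs(b) < 0.002)
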