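"""Global spectral analysis: profiles, variable projection, model selection."""

import numpy as np
import pytest

from aaokin.errors import InputError
from aaokin.spectral import (
    GlobalSpectralFit,
    SpectraMatrix,
    StepScheme,
    estimate_rank,
    global_fit,
    monochromator_fit,
    select_step_model,
    species_profiles,
)
from aaokin.synthetic_data import (
    FlavinSpectrumTemplate,
    NoiseSpec,
    gen_mono_trace,
    gen_spectra,
)

NOISELESS = NoiseSpec(kind="additive_gaussian", sd=0.0)


class TestSpeciesProfiles:
    def test_initial_condition(self):
        c = species_profiles(StepScheme([100.0]), [0.0])
        np.testing.assert_allclose(c, [[1.0, 0.0]])

    def test_half_life(self):
        t = np.log(2.0) / 100.0
        c = species_profiles(StepScheme([100.0]), [t])
        assert c[0, 0] == pytest.approx(0.5, rel=1e-12)

    def test_confluent_limit(self):
        # k1 = k2 = 50: c_B(1/50) = k1*t*exp(-k1*t) = e^-1
        c = species_profiles(StepScheme([50.0, 50.0]), [1.0 / 50.0])
        assert c[0, 1] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_confluent_continuity(self):
        t = np.geomspace(1e-4, 0.2, 20)
        near = species_profiles(StepScheme([50.0, 50.0 * (1 + 1e-7)]), t)
        exact = species_profiles(StepScheme([50.0, 50.0]), t)
        np.testing.assert_allclose(near, exact, atol=1e-5)

    def test_fractions_sum_to_one(self):
        t = np.geomspace(1e-4, 1.0, 30)
        c = species_profiles(StepScheme([200.0, 20.0]), t)
        np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-12)


class TestGlobalFit:
    def test_one_step_noiseless_recovery(self):
        data = gen_spectra(StepScheme([100.0]), noise=NOISELESS)
        res = global_fit(data, 1)
        assert res.scheme.rate_constants[0] == pytest.approx(100.0, rel=1e-6)
        assert res.residual_rms < 1e-9

    def test_two_step_noiseless_recovery(self):
        data = gen_spectra(StepScheme([200.0, 20.0]), noise=NOISELESS)
        res = global_fit(data, 2)
        assert res.scheme.rate_constants[0] == pytest.approx(200.0, rel=1e-6)
        assert res.scheme.rate_constants[1] == pytest.approx(20.0, rel=1e-6)
        assert res.residual_rms < 1e-9

    def test_recovered_spectra_match_template(self):
        tpl = FlavinSpectrumTemplate()
        data = gen_spectra(StepScheme([100.0]), template=tpl, noise=NOISELESS)
        res = global_fit(data, 1)
        np.testing.assert_allclose(
            res.species_spectra[0],
            tpl.spectrum("oxidized", data.wavelengths),
            atol=1e-10,
        )

    def test_rate_ordering_fast_first(self):
        data = gen_spectra(StepScheme([20.0, 200.0]), noise=NOISELESS)
        res = global_fit(data, 2)
        k1, k2 = res.scheme.rate_constants
        assert k1 >= k2

    def test_overparameterized_fit_flags_degeneracy(self):
        data = gen_spectra(StepScheme([100.0]),
                           noise=NoiseSpec(kind="additive_gaussian",
                                           sd=1e-4, seed=2))
        fit = GlobalSpectralFit(n_steps=2).fit(data)
        sel = select_step_model(data, noise_sd=1e-4)
        # either the 2-step fit itself degenerates or selection rejects it
        assert fit.degenerate_warning_ or sel.choice == 1

    def test_time_shift_leaves_rates_unchanged(self):
        data = gen_spectra(StepScheme([100.0]), noise=NOISELESS)
        shifted = SpectraMatrix(data.times + 0.005, data.wavelengths,
                                data.absorbance)
        k0 = global_fit(data, 1).scheme.rate_constants[0]
        k1 = global_fit(shifted, 1).scheme.rate_constants[0]
        assert k1 == pytest.approx(k0, abs=1e-9 * k0 + 1e-9)

    def test_too_few_times_rejected(self):
        data = gen_spectra(StepScheme([100.0]),
                           times=np.geomspace(0.003, 0.15, 5),
                           noise=NOISELESS)
        with pytest.raises(InputError):
            global_fit(data, 2)


class TestRankEstimate:
    def test_noiseless_two_species(self):
        data = gen_spectra(StepScheme([100.0]), noise=NOISELESS)
        assert estimate_rank(data, 0.0) == 2

    def test_noisy_two_species(self):
        data = gen_spectra(
            StepScheme([100.0]),
            noise=NoiseSpec(kind="additive_gaussian", sd=0.002, seed=4),
        )
        assert estimate_rank(data, 0.002) == 2

    def test_constant_spectra_rank_one(self):
        data = gen_spectra(StepScheme([100.0]), noise=NOISELESS)
        flat = SpectraMatrix(
            data.times, data.wavelengths,
            np.tile(data.absorbance[:1], (data.times.size, 1)),
        )
        assert estimate_rank(flat, 0.0) == 1


class TestModelSelection:
    def test_two_species_selects_one_step(self):
        data = gen_spectra(StepScheme([100.0]), noise=NOISELESS)
        assert select_step_model(data).choice == 1

    def test_three_species_selects_two_step(self):
        data = gen_spectra(StepScheme([200.0, 20.0]), noise=NOISELESS)
        sel = select_step_model(data)
        assert sel.choice == 2
        assert sel.rank == 3

    def test_rank_one_degrades_with_warning(self):
        data = gen_spectra(StepScheme([100.0]), noise=NOISELESS)
        flat = SpectraMatrix(
            data.times, data.wavelengths,
            np.tile(data.absorbance[:1], (data.times.size, 1)),
        )
        sel = select_step_model(flat)
        assert sel.choice == 1
        assert sel.zero_amplitude_warning


class TestMonochromator:
    def test_single_exponential_exact(self):
        t, y = gen_mono_trace(StepScheme([100.0]), noise=NOISELESS)
        fit = monochromator_fit(t, y, 1)
        assert fit.rates[0] == pytest.approx(100.0, rel=1e-8)

    def test_biexponential_noisy_recovery(self):
        t, y = gen_mono_trace(
            StepScheme([200.0, 20.0]),
            noise=NoiseSpec(kind="additive_gaussian", sd=0.001, seed=1),
        )
        fit = monochromator_fit(t, y, 2)
        assert fit.rates[0] == pytest.approx(200.0, rel=0.05)
        assert fit.rates[1] == pytest.approx(20.0, rel=0.05)

    def test_constant_trace_zero_amplitude(self):
        t = np.geomspace(0.003, 0.15, 20)
        fit = monochromator_fit(t, np.full_like(t, 0.42), 1)
        np.testing.assert_allclose(fit.amplitudes, 0.0)
        assert fit.offset == pytest.approx(0.42)

    def test_agrees_with_global_fit(self):
        """Single-wavelength and all-wavelength routes see the same rate."""
        noise = NoiseSpec(kind="additive_gaussian", sd=0.001, seed=9)
        data = gen_spectra(StepScheme([100.0]), noise=noise)
        k_global = global_fit(data, 1).scheme.rate_constants[0]
        i462 = int(np.argmin(np.abs(data.wavelengths - 462.0)))
        fit = monochromator_fit(data.times, data.absorbance[:, i462], 1)
        tol = 2.0 * (fit.rate_stderr[0] + 1e-3 * k_global)
        assert abs(fit.rates[0] - k_global) < max(tol, 0.02 * k_global)
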