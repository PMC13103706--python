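"""Emission-spectrum processing: smoothing, peak, FWHM, SNR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioflash import (
    EmissionSpectrum,
    NoPeakError,
    SpectrumError,
    SpectrumModel,
    UnboundedWidthError,
    fwhm,
    generate_spectrum,
    peak_wavelength,
    savitzky_golay,
    snr,
    subtract_background,
    summarize_spectrum,
)

GAUSS_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = factor * sigma


def gaussian_spectrum(center=474.0, sigma=12.739, amp=1000.0, baseline=0.0,
                      start=350.0, stop=700.0, step=1.0):
    wl = np.arange(start, stop + 0.5 * step, step)
    y = baseline + amp * np.exp(-((wl - center) ** 2) / (2 * sigma**2))
    return EmissionSpectrum(wavelengths=wl, intensities=y)


class TestSubtractBackground:
    def test_measured_background_vector(self):
        spec = gaussian_spectrum(baseline=50.0)
        spec = EmissionSpectrum(
            wavelengths=spec.wavelengths,
            intensities=spec.intensities,
            background=np.full(spec.wavelengths.size, 50.0),
        )
        out = subtract_background(spec)
        pure = gaussian_spectrum(baseline=0.0)
        np.testing.assert_allclose(out.intensities, pure.intensities, atol=1e-10)

    def test_constant_spectrum_goes_to_zero(self):
        wl = np.arange(350.0, 701.0)
        out = subtract_background(
            EmissionSpectrum(wavelengths=wl, intensities=np.full(wl.size, 10.0))
        )
        np.testing.assert_allclose(out.intensities, 0.0)

    def test_baseline_recovered_from_dim_channels(self, rng):
        # Poisson-like counting noise on a bright constant offset.
        baseline = 2000.0
        spec = gaussian_spectrum(amp=1000.0, baseline=baseline)
        noisy = spec.intensities + rng.normal(
            0.0, np.sqrt(spec.intensities), size=spec.intensities.size
        )
        out = subtract_background(
            EmissionSpectrum(wavelengths=spec.wavelengths, intensities=noisy)
        )
        estimated = noisy - out.intensities
        assert estimated[0] == pytest.approx(baseline, rel=0.05)

    def test_grid_mismatch_rejected(self):
        wl = np.arange(350.0, 701.0)
        with pytest.raises(SpectrumError):
            EmissionSpectrum(
                wavelengths=wl,
                intensities=np.ones(wl.size),
                background=np.ones(wl.size - 1),
            )


class TestSavitzkyGolay:
    @given(
        a=st.floats(-100, 100),
        b=st.floats(-5, 5),
        c=st.floats(-0.05, 0.05),
    )
    @settings(max_examples=25, deadline=None)
    def test_quadratics_preserved_exactly(self, a, b, c):
        wl = np.arange(350.0, 701.0)
        x = wl - 500.0
        y = a + b * x + c * x**2
        spec = EmissionSpectrum(wavelengths=wl, intensities=y)
        out = savitzky_golay(spec, window=25, degree=2)
        scale = max(1.0, float(np.max(np.abs(y))))
        np.testing.assert_allclose(out.intensities, y, atol=1e-9 * scale)

    def test_impulse_center_weight_matches_lstsq_oracle(self):
        # Oracle: explicit least-squares solve of the 25-point quadratic fit.
        window, degree = 25, 2
        x = np.arange(window) - window // 2
        X = np.vander(x, degree + 1, increasing=True)
        e = np.zeros(window)
        e[window // 2] = 1.0
        coef, *_ = np.linalg.lstsq(X, e, rcond=None)
        center_weight = coef[0]

        wl = np.arange(350.0, 701.0)
        y = np.zeros(wl.size)
        y[175] = 1.0
        out = savitzky_golay(EmissionSpectrum(wavelengths=wl, intensities=y))
        assert out.intensities[175] == pytest.approx(center_weight, rel=1e-9)

    def test_linearity(self, rng):
        wl = np.arange(350.0, 701.0)
        y1 = rng.normal(size=wl.size)
        y2 = rng.normal(size=wl.size)
        sm = lambda y: savitzky_golay(
            EmissionSpectrum(wavelengths=wl, intensities=y)
        ).intensities
        np.testing.assert_allclose(
            sm(2.0 * y1 - 3.0 * y2), 2.0 * sm(y1) - 3.0 * sm(y2), atol=1e-9
        )

    def test_passes_counted_and_contractive_on_noise(self, rng):
        # Residual white noise shrinks monotonically with each extra pass.
        wl = np.arange(350.0, 701.0)
        rms_by_pass = []
        for _ in range(10):
            y = rng.normal(size=wl.size)
            rms = []
            for p in range(1, 4):
                spec_p = savitzky_golay(
                    EmissionSpectrum(wavelengths=wl, intensities=y), passes=p
                )
                assert spec_p.smoothed_passes == p
                rms.append(float(np.sqrt(np.mean(spec_p.intensities**2))))
            rms_by_pass.append(rms)
        mean_rms = np.mean(rms_by_pass, axis=0)
        assert mean_rms[0] >= mean_rms[1] >= mean_rms[2]

    @pytest.mark.parametrize("window, degree", [(24, 2), (3, 4), (25, 25)])
    def test_invalid_parameters_rejected(self, window, degree):
        spec = gaussian_spectrum()
        with pytest.raises(SpectrumError):
            savitzky_golay(spec, window=window, degree=degree)


class TestPeakWavelength:
    def test_gaussian_peak_at_grid_sample(self):
        assert peak_wavelength(gaussian_spectrum(center=474.0)) == 474.0

    def test_tie_broken_toward_blue(self):
        wl = np.arange(350.0, 701.0)
        y = np.zeros(wl.size)
        y[wl == 470.0] = 5.0
        y[wl == 480.0] = 5.0
        assert peak_wavelength(EmissionSpectrum(wavelengths=wl, intensities=y)) == 470.0

    def test_noisy_gaussian_after_one_pass(self):
        model = SpectrumModel(center_nm=474.0, fwhm_nm=30.0, amplitude=1000.0,
                              baseline=100.0, noise_sd=20.0, seed=5)
        raw, _ = generate_spectrum(model)
        smoothed = savitzky_golay(subtract_background(raw))
        assert abs(peak_wavelength(smoothed) - 474.0) <= 1.0

    def test_all_negative_rejected(self):
        wl = np.arange(350.0, 701.0)
        with pytest.raises(NoPeakError):
            peak_wavelength(
                EmissionSpectrum(wavelengths=wl, intensities=-np.ones(wl.size))
            )


class TestFwhm:
    def test_gaussian_closed_form(self):
        sigma = 12.739
        assert fwhm(gaussian_spectrum(sigma=sigma)) == pytest.approx(
            GAUSS_FACTOR * sigma, abs=0.1
        )
        assert fwhm(gaussian_spectrum(sigma=sigma)) == pytest.approx(30.0, abs=0.1)

    def test_gaussian_converges_with_grid_refinement(self):
        sigma = 12.739
        errors = [
            abs(fwhm(gaussian_spectrum(sigma=sigma, step=step)) - GAUSS_FACTOR * sigma)
            for step in (2.0, 1.0, 0.25)
        ]
        assert errors[-1] <= errors[0]
        assert errors[-1] < 0.01

    def test_triangle_geometry(self):
        wl = np.arange(350.0, 701.0)
        w = 20.0  # half-width at half height per side
        y = np.maximum(0.0, 1.0 - np.abs(wl - 500.0) / (2 * w))
        assert fwhm(EmissionSpectrum(wavelengths=wl, intensities=y)) == pytest.approx(
            2 * w, abs=1e-9
        )

    def test_noisy_gaussian_within_1nm(self):
        model = SpectrumModel(center_nm=474.0, fwhm_nm=30.0, amplitude=1000.0,
                              baseline=100.0, noise_sd=20.0, seed=5)
        raw, _ = generate_spectrum(model)
        smoothed = savitzky_golay(subtract_background(raw))
        assert fwhm(smoothed) == pytest.approx(30.0, abs=1.0)

    def test_unbounded_side_named(self):
        wl = np.arange(350.0, 701.0)
        y = np.exp(-((wl - 360.0) ** 2) / (2 * 30.0**2))  # left tail cut off
        with pytest.raises(UnboundedWidthError) as err:
            fwhm(EmissionSpectrum(wavelengths=wl, intensities=y))
        assert err.value.side == "left"

    def test_scale_invariance_of_peak_and_fwhm(self):
        spec = gaussian_spectrum()
        scaled = EmissionSpectrum(
            wavelengths=spec.wavelengths, intensities=37.5 * spec.intensities
        )
        assert peak_wavelength(scaled) == peak_wavelength(spec)
        assert fwhm(scaled) == pytest.approx(fwhm(spec))


class TestSnr:
    def test_arithmetic(self):
        wl = np.arange(350.0, 701.0)
        smooth = np.zeros(wl.size)
        smooth[100] = 100.0
        resid = np.where(np.arange(wl.size) % 2 == 0, 10.0, -10.0)
        raw = smooth + resid
        val = snr(
            EmissionSpectrum(wavelengths=wl, intensities=raw),
            EmissionSpectrum(wavelengths=wl, intensities=smooth),
        )
        assert val == pytest.approx(10.0)

    def test_doubling_noise_halves_snr(self):
        wl = np.arange(350.0, 701.0)
        smooth = np.zeros(wl.size)
        smooth[100] = 100.0
        resid = np.where(np.arange(wl.size) % 2 == 0, 10.0, -10.0)
        s1 = snr(EmissionSpectrum(wavelengths=wl, intensities=smooth + resid),
                 EmissionSpectrum(wavelengths=wl, intensities=smooth))
        s2 = snr(EmissionSpectrum(wavelengths=wl, intensities=smooth + 2 * resid),
                 EmissionSpectrum(wavelengths=wl, intensities=smooth))
        assert s2 == pytest.approx(s1 / 2)

    def test_generated_spectrum_snr_near_amplitude_over_sigma(self):
        model = SpectrumModel(amplitude=1000.0, noise_sd=20.0, seed=9)
        raw, _ = generate_spectrum(model)
        corrected = subtract_background(raw)
        smoothed = savitzky_golay(corrected)
        value = snr(corrected, smoothed)
        assert value == pytest.approx(1000.0 / 20.0, rel=0.15)

    def test_identical_inputs_give_infinity(self):
        spec = gaussian_spectrum()
        assert snr(spec, spec) == math.inf


def test_summarize_spectrum_end_to_end():
    model = SpectrumModel(center_nm=474.0, fwhm_nm=30.0, amplitude=1000.0,
                          baseline=100.0, noise_sd=20.0, seed=12)
    raw, _ = generate_spectrum(model)
    summary = summarize_spectrum(raw)
    assert abs(summary.peak_wavelength_nm - 474.0) <= 1.0
    assert summary.fwhm_nm == pytest.approx(30.0, abs=1.5)
    assert summary.snr == pytest.approx(50.0, rel=0.2)
    assert summary.smoothed_passes == 1
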