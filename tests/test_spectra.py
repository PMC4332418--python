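import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serpinscope import spectra as sp
from serpinscope.synthetic_data import (
    PRESET_SIGMAS,
    SpectrumRecipe,
    make_spectrum_pair,
)


def gaussian(lam, center, sigma, area):
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((lam - center) / sigma) ** 2
    )


class TestEmissionSpectrum:
    def test_grid_must_increase(self):
        with pytest.raises(sp.SpectrumError):
            sp.EmissionSpectrum(np.array([300.0, 300.0, 301.0]), np.zeros(3), 275.0)

    def test_length_mismatch(self):
        with pytest.raises(sp.SpectrumError):
            sp.EmissionSpectrum(np.array([300.0, 301.0]), np.zeros(3), 275.0)


class TestInstrumentResponse:
    def test_identity(self, flat_spectrum, grid):
        curve = sp.CorrectionCurve(grid, np.ones_like(grid))
        out = sp.correct_instrument_response(flat_spectrum, curve)
        np.testing.assert_allclose(out.intensity, flat_spectrum.intensity)

    def test_constant_scaling(self, grid):
        raw = sp.EmissionSpectrum(grid, np.full_like(grid, 2.0), 275.0)
        curve = sp.CorrectionCurve(grid, np.full_like(grid, 0.5))
        out = sp.correct_instrument_response(raw, curve)
        np.testing.assert_allclose(out.intensity, 1.0)

    def test_round_trip_recovers_reference(self, grid):
        # distort a synthetic Trp-in-water reference, build the correction
        # from reference/distorted, apply it to the distorted measurement
        reference = gaussian(grid, 350.0, 30.0, 1.0)
        distortion = 1.0 + 0.4 * np.sin(grid / 37.0) ** 2
        measured = reference * distortion
        curve = sp.CorrectionCurve(grid, reference / measured)
        out = sp.correct_instrument_response(
            sp.EmissionSpectrum(grid, measured, 275.0), curve
        )
        np.testing.assert_allclose(out.intensity, reference, atol=1e-6)

    def test_non_covering_curve_rejected(self, flat_spectrum):
        curve = sp.CorrectionCurve(np.array([300.0, 400.0]), np.array([1.0, 1.0]))
        with pytest.raises(sp.SpectrumError):
            sp.correct_instrument_response(flat_spectrum, curve)

    def test_non_positive_factor_rejected(self, grid):
        with pytest.raises(sp.SpectrumError):
            sp.CorrectionCurve(grid, np.zeros_like(grid))


class TestSubtractRayleigh:
    def test_no_intensity_near_excitation_unchanged(self, grid):
        y = gaussian(grid, 420.0, 10.0, 1.0)
        spec = sp.EmissionSpectrum(grid, y, 275.0)
        out = sp.subtract_rayleigh(spec, 8.0)
        outside = np.abs(grid - 275.0) > 8.0
        np.testing.assert_allclose(out.intensity[outside], y[outside])
        np.testing.assert_allclose(out.intensity, y, atol=1e-12)

    def test_spike_removed_to_baseline(self, grid):
        y = 1.0 + gaussian(grid, 275.0, 1.5, 0.5)
        out = sp.subtract_rayleigh(sp.EmissionSpectrum(grid, y, 275.0), 8.0)
        np.testing.assert_allclose(out.intensity, 1.0, atol=1e-3)

    def test_distant_spike_preserved(self, grid):
        spike = gaussian(grid, 275.0 + 24.0, 1.5, 0.5)
        y = 1.0 + spike
        out = sp.subtract_rayleigh(sp.EmissionSpectrum(grid, y, 275.0), 8.0)
        i = int(np.argmax(spike))
        assert out.intensity[i] == pytest.approx(y[i])

    def test_window_covering_grid_rejected(self):
        lam = np.arange(270.0, 281.0)
        spec = sp.EmissionSpectrum(lam, np.ones_like(lam), 275.0)
        with pytest.raises(sp.SpectrumError):
            sp.subtract_rayleigh(spec, 100.0)


class TestNormalizeAndTailScale:
    def _ref(self, grid):
        y = gaussian(grid, 340.0, 25.0, 2.0) + gaussian(grid, 430.0, 60.0, 0.6)
        return sp.EmissionSpectrum(grid, y, 295.0, label="ref")

    def test_reference_maps_to_normalized_self(self, grid):
        ref = self._ref(grid)
        out = sp.normalize_and_tail_scale(ref, ref)
        np.testing.assert_allclose(out.intensity, ref.intensity / ref.integral())

    def test_scale_invariance(self, grid):
        ref = self._ref(grid)
        scaled = sp.EmissionSpectrum(grid, 3.0 * ref.intensity, 275.0)
        out1 = sp.normalize_and_tail_scale(ref, ref)
        out3 = sp.normalize_and_tail_scale(scaled, ref)
        np.testing.assert_allclose(out3.intensity, out1.intensity, rtol=1e-12)

    def test_tail_mismatch_gives_closed_form_factor(self, grid):
        ref = self._ref(grid)
        rnorm = ref.intensity / ref.integral()
        tail = grid >= 450.0
        # unit-integral spectrum whose tail is exactly 0.8 x the normalized
        # reference tail: inner part rescaled to absorb the missing mass
        tail_mass = float(np.trapezoid(np.where(tail, rnorm, 0.0), grid))
        y = np.where(tail, 0.8 * rnorm, rnorm * (1 - 0.8 * tail_mass) / (1 - tail_mass))
        spec = sp.EmissionSpectrum(grid, y * 5.0, 275.0)
        out = sp.normalize_and_tail_scale(spec, ref)
        # least-squares tail factor is exactly 1/0.8 = 1.25
        np.testing.assert_allclose(out.intensity, 1.25 * y, rtol=1e-6)
        np.testing.assert_allclose(out.intensity[tail], rnorm[tail], rtol=1e-6)

    def test_idempotence(self, grid):
        ref = self._ref(grid)
        spec = sp.EmissionSpectrum(
            grid, gaussian(grid, 335.0, 28.0, 1.0) + gaussian(grid, 460.0, 40.0, 0.2),
            275.0,
        )
        once = sp.normalize_and_tail_scale(spec, ref)
        twice = sp.normalize_and_tail_scale(once, ref)
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-9)

    def test_empty_tail_rejected(self, grid):
        ref = self._ref(grid)
        with pytest.raises(sp.SpectrumError):
            sp.normalize_and_tail_scale(ref, ref, tail_start_nm=600.0)


class TestSecondDerivativeMinima:
    def test_single_gaussian_minimum_at_center(self, single_band_spectrum):
        minima = sp.second_derivative_minima(single_band_spectrum)
        assert len(minima) == 1
        assert minima[0] == pytest.approx(331.0, abs=0.5)

    def test_flat_spectrum_empty(self, flat_spectrum):
        assert sp.second_derivative_minima(flat_spectrum) == []

    def test_five_band_centers_recovered(self):
        # highly structured preset: narrow bands, SNR 200
        sigmas = {304.0: 4.5, 318.0: 4.5, 331.0: 5.0, 344.0: 5.5, 360.0: 6.5}
        rec = SpectrumRecipe(
            band_spec=tuple((c, s, 0.2) for c, s in sorted(sigmas.items())),
            noise_sigma=0.005, seed=5,
        )
        _, s295, _ = make_spectrum_pair(rec)
        minima = sp.second_derivative_minima(s295)
        for center in sigmas:
            assert min(abs(m - center) for m in minima) <= 1.5

    def test_short_spectrum_rejected(self):
        lam = np.arange(300.0, 306.0)
        spec = sp.EmissionSpectrum(lam, np.ones_like(lam), 275.0)
        with pytest.raises(sp.SpectrumError):
            sp.second_derivative_minima(spec, window_pts=11)


class TestFitGaussianBands:
    def test_single_band_exact(self, single_band_spectrum):
        model = sp.BandModel(
            centers_nm=(331.0,), center_bounds_nm=(2.0,), width_bounds_nm=(4.0, 20.0)
        )
        dec = sp.fit_gaussian_bands(single_band_spectrum, model)
        assert dec.converged
        assert dec.residual_norm < 1e-6
        assert dec.bands[0].fraction == pytest.approx(1.0)
        assert dec.bands[0].center_nm == pytest.approx(331.0, abs=0.01)
        assert dec.bands[0].sigma_nm == pytest.approx(12.0, abs=0.01)

    def test_two_band_area_ratio(self, grid):
        # area ratio matching the reported cleaved-at-295nm value
        y = gaussian(grid, 304.0, 6.5, 0.51) + gaussian(grid, 331.0, 9.5, 1.0)
        spec = sp.EmissionSpectrum(grid, y, 295.0)
        model = sp.BandModel(
            centers_nm=(304.0, 331.0), center_bounds_nm=(2.0, 2.0)
        )
        dec = sp.fit_gaussian_bands(spec, model)
        assert dec.area_ratio(304.0, 331.0) == pytest.approx(0.51, abs=0.02)

    def test_five_band_fraction_recovery_noisy(self):
        rec = SpectrumRecipe(
            band_spec=tuple(
                (c, PRESET_SIGMAS[c], w)
                for c, w in zip(sorted(PRESET_SIGMAS), (0.15, 0.2, 0.3, 0.2, 0.15))
            ),
            noise_sigma=0.01, seed=11,
        )
        _, s295, truth = make_spectrum_pair(rec)
        dec = sp.fit_gaussian_bands(s295, sp.BandModel.pinned())
        for band in dec.bands:
            assert band.fraction == pytest.approx(
                truth.fractions[band.center_nm // 1 if False else min(
                    truth.fractions, key=lambda c: abs(c - band.center_nm))],
                abs=0.03,
            )

    def test_fraction_conservation_and_area_identity(self, native_pair):
        _, s295, _ = native_pair
        dec = sp.fit_gaussian_bands(s295, sp.BandModel.pinned())
        assert sum(b.fraction for b in dec.bands) == pytest.approx(1.0, abs=1e-6)
        for b in dec.bands:
            assert b.area == pytest.approx(
                b.amplitude * b.sigma_nm * np.sqrt(2 * np.pi), rel=1e-9
            )

    def test_area_matches_trapezoidal_integration(self, native_pair, grid):
        # oracle equivalence: analytic area vs numeric integral of the component
        _, s295, _ = native_pair
        dec = sp.fit_gaussian_bands(s295, sp.BandModel.pinned())
        wide = np.arange(100.0, 700.0, 0.5)
        for b in dec.bands:
            comp = b.amplitude * np.exp(-0.5 * ((wide - b.center_nm) / b.sigma_nm) ** 2)
            assert np.trapezoid(comp, wide) == pytest.approx(b.area, rel=1e-3)


class TestTyrSpectrum:
    def test_identical_pair_gives_zero(self, grid):
        y = gaussian(grid, 340.0, 20.0, 1.0)
        a = sp.EmissionSpectrum(grid, y, 275.0)
        b = sp.EmissionSpectrum(grid, y, 295.0)
        tyr = sp.tyr_spectrum(a, b)
        np.testing.assert_allclose(tyr.intensity, 0.0)
        assert tyr.a_tyr == 0.0

    def test_known_band_recovered(self, grid):
        base = gaussian(grid, 340.0, 20.0, 1.0)
        band = gaussian(grid, 304.0, 7.0, 0.25)
        tyr = sp.tyr_spectrum(
            sp.EmissionSpectrum(grid, base + band, 275.0),
            sp.EmissionSpectrum(grid, base, 295.0),
        )
        assert tyr.a_tyr == pytest.approx(0.25, abs=1e-6)
        np.testing.assert_allclose(tyr.intensity, band, atol=1e-12)

    def test_a_tyr_is_trapezoidal_integral(self, grid):
        rng = np.random.default_rng(1)
        y1 = gaussian(grid, 320.0, 15.0, 1.0) + 0.01 * rng.normal(size=grid.size)
        y2 = gaussian(grid, 320.0, 15.0, 0.9)
        tyr = sp.tyr_spectrum(
            sp.EmissionSpectrum(grid, y1, 275.0), sp.EmissionSpectrum(grid, y2, 295.0)
        )
        assert tyr.a_tyr == pytest.approx(
            float(np.trapezoid(tyr.intensity, grid)), rel=1e-9
        )

    def test_tyrosinate_widens_difference(self, noiseless_presets):
        s275, s295, _ = make_spectrum_pair(noiseless_presets["native"])
        tyr = sp.tyr_spectrum(sp.subtract_rayleigh(s275), sp.subtract_rayleigh(s295))
        pure = gaussian(tyr.lambda_nm, *sp.TYR_BAND_NM, tyr.a_tyr)
        # compare widths at 20% of maximum
        def width(y):
            idx = np.where(y > 0.2 * y.max())[0]
            return tyr.lambda_nm[idx[-1]] - tyr.lambda_nm[idx[0]]
        assert width(tyr.intensity) > width(pure)

    def test_mismatched_grids_rejected(self, grid):
        a = sp.EmissionSpectrum(grid, np.ones_like(grid), 275.0)
        b = sp.EmissionSpectrum(grid[:-1] + 0.5, np.ones(grid.size - 1), 295.0)
        with pytest.raises(sp.SpectrumError):
            sp.tyr_spectrum(a, b)


class TestTyrosinateSplit:
    def _tyr(self, grid, a304, a340):
        y = gaussian(grid, 304.0, 7.0, a304) + gaussian(grid, 340.0, 12.0, a340)
        return sp.TyrSpectrum(grid, y, a_tyr=a304 + a340)

    def test_pure_tyr(self, grid):
        f_tyr, f_tyrosinate = sp.tyrosinate_split(self._tyr(grid, 1.0, 0.0))
        assert f_tyr == pytest.approx(1.0, abs=0.01)
        assert f_tyrosinate == pytest.approx(0.0, abs=0.01)

    def test_equal_areas(self, grid):
        f_tyr, f_tyrosinate = sp.tyrosinate_split(self._tyr(grid, 0.5, 0.5))
        assert f_tyr == pytest.approx(0.5, abs=0.02)
        assert f_tyrosinate == pytest.approx(0.5, abs=0.02)

    def test_pure_tyrosinate(self, grid):
        f_tyr, f_tyrosinate = sp.tyrosinate_split(self._tyr(grid, 0.0, 1.0))
        assert f_tyr == pytest.approx(0.0, abs=0.01)
        assert f_tyrosinate == pytest.approx(1.0, abs=0.01)

    def test_non_positive_integral_rejected(self, grid):
        with pytest.raises(sp.SpectrumError):
            sp.tyrosinate_split(sp.TyrSpectrum(grid, -np.ones_like(grid), -1.0))


class TestRatioR:
    def test_identical_spectra_give_unity(self, grid):
        y = gaussian(grid, 330.0, 20.0, 1.0) + 0.1
        fp = sp.ratio_R(
            sp.EmissionSpectrum(grid, y, 275.0), sp.EmissionSpectrum(grid, y, 295.0)
        )
        assert fp.r_value == pytest.approx(1.0, rel=1e-12)
        assert fp.classification == "unknown"

    def test_constructed_arithmetic(self, grid):
        # I(275;304)/I(275;331) = 2 and I(295;304)/I(295;331) = 1 -> R = 2
        y275 = np.interp(grid, [260.0, 304.0, 331.0, 520.0], [2.0, 2.0, 1.0, 1.0])
        y295 = np.ones_like(grid)
        fp = sp.ratio_R(
            sp.EmissionSpectrum(grid, y275, 275.0),
            sp.EmissionSpectrum(grid, y295, 295.0),
        )
        assert fp.r_value == pytest.approx(2.0, rel=1e-9)
        assert fp.ratio_304_331_ex275 == pytest.approx(2.0, rel=1e-9)
        assert fp.ratio_304_331_ex295 == pytest.approx(1.0, rel=1e-9)

    @given(
        a=st.floats(min_value=1e-3, max_value=1e3),
        b=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, a, b):
        grid = np.arange(260.0, 521.0)
        y275 = gaussian(grid, 320.0, 15.0, 1.0) + 0.2
        y295 = gaussian(grid, 335.0, 18.0, 1.0) + 0.1
        fp0 = sp.ratio_R(
            sp.EmissionSpectrum(grid, y275, 275.0),
            sp.EmissionSpectrum(grid, y295, 295.0),
        )
        fp1 = sp.ratio_R(
            sp.EmissionSpectrum(grid, a * y275, 275.0),
            sp.EmissionSpectrum(grid, b * y295, 295.0),
        )
        assert fp1.r_value == pytest.approx(fp0.r_value, rel=1e-9)

    def test_r_consistency_invariant(self, grid):
        y275 = gaussian(grid, 320.0, 15.0, 1.0) + 0.2
        y295 = gaussian(grid, 335.0, 18.0, 1.0) + 0.1
        fp = sp.ratio_R(
            sp.EmissionSpectrum(grid, y275, 275.0),
            sp.EmissionSpectrum(grid, y295, 295.0),
        )
        assert fp.r_value == pytest.approx(
            fp.ratio_304_331_ex275 / fp.ratio_304_331_ex295, rel=1e-9
        )

    def test_non_positive_probe_intensity_rejected(self, grid):
        y = np.zeros_like(grid)
        with pytest.raises(sp.SpectrumError):
            sp.ratio_R(
                sp.EmissionSpectrum(grid, y, 275.0),
                sp.EmissionSpectrum(grid, y + 1.0, 295.0),
            )


class TestClassification:
    def test_reference_values_map_to_labels(self):
        for r, label in ((1.33, "native"), (1.42, "cleaved"), (1.55, "latent")):
            fp = sp.FingerprintResult(r, r, 1.0)
            assert sp.classify_conformer(fp) == label

    def test_redshift_overrides(self):
        fp = sp.FingerprintResult(1.33, 1.33, 1.0, redshift_nm=12.0)
        assert sp.classify_conformer(fp) == "polymer"

    def test_far_r_is_unknown(self):
        fp = sp.FingerprintResult(2.5, 2.5, 1.0)
        assert sp.classify_conformer(fp) == "unknown"


class TestDenoiseJoint:
    def test_noiseless_projection_is_exact(self, native_pair):
        s275, s295, truth = native_pair
        d275, d295 = sp.denoise_joint(s275, s295)
        fp = sp.ratio_R(d275, d295)
        assert fp.r_value == pytest.approx(truth.r_value, rel=1e-9)
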