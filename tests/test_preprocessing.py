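import numpy as np
import pytest
from scipy import signal as sps

from aquafuzz.preprocessing import (
    CalibrationError,
    FilterDesignError,
    FilterSpec,
    PreprocessingError,
    SaturationError,
    TemperatureModel,
    TurbidityCalibration,
    compensate_turbidity,
    compute_absorbance,
    correct_baseline_shift,
    design_lowpass,
    estimate_turbidity,
    preprocess_bundle,
    subtract_blank,
    temperature_correct,
    zero_phase_filter,
    zero_phase_filter_values,
)
from aquafuzz.spectral_io import Modality, Spectrum, WavelengthGrid
from aquafuzz.synthetic_data import ScenarioConfig, generate_bundle

from .conftest import gaussian_spectrum


def flat(grid, value, modality=Modality.UVVIS, **kw):
    return Spectrum(grid=grid, values=np.full(len(grid), float(value)),
                    modality=modality, **kw)


class TestAbsorbance:
    def test_decade_ratio_gives_unit_absorbance(self, grid):
        out = compute_absorbance(flat(grid, 10.0), flat(grid, 100.0))
        assert np.allclose(out.absorbance, 1.0)

    def test_blank_against_itself_gives_zero(self, grid):
        out = compute_absorbance(flat(grid, 100.0), flat(grid, 100.0))
        assert np.allclose(out.absorbance, 0.0)

    def test_log_additivity_of_chained_media(self, grid):
        a01 = compute_absorbance(flat(grid, 100.0), flat(grid, 1000.0)).absorbance
        a12 = compute_absorbance(flat(grid, 10.0), flat(grid, 100.0)).absorbance
        a02 = compute_absorbance(flat(grid, 10.0), flat(grid, 1000.0)).absorbance
        assert np.allclose(a01 + a12, a02)

    def test_antisymmetric_under_swap(self, grid):
        rng = np.random.default_rng(3)
        s = flat(grid, 1.0).with_values(rng.uniform(10, 1000, len(grid)))
        b = flat(grid, 1.0).with_values(rng.uniform(10, 1000, len(grid)))
        forward = compute_absorbance(s, b).absorbance
        backward = compute_absorbance(b, s).absorbance
        assert np.allclose(forward, -backward)

    def test_zero_blank_is_calibration_error(self, grid):
        with pytest.raises(CalibrationError):
            compute_absorbance(flat(grid, 10.0), flat(grid, 0.0))

    def test_nonpositive_sample_clipped_and_flagged(self, grid):
        values = np.full(len(grid), 50.0)
        values[5] = 0.0
        out = compute_absorbance(flat(grid, 1.0).with_values(values), flat(grid, 100.0))
        assert np.all(np.isfinite(out.absorbance))
        assert any("clipped" in w for w in out.warnings)


class TestBlankSubtraction:
    def test_simple_difference(self, grid):
        out = subtract_blank(flat(grid, 500, Modality.FL440), flat(grid, 100, Modality.FL440))
        assert np.allclose(out.values, 400.0)

    def test_blank_against_itself_gives_zero(self, grid):
        out = subtract_blank(flat(grid, 100, Modality.FL590), flat(grid, 100, Modality.FL590))
        assert np.allclose(out.values, 0.0)

    def test_negative_values_preserved(self, grid):
        out = subtract_blank(flat(grid, 80, Modality.SC850), flat(grid, 100, Modality.SC850))
        assert np.all(out.values < 0)

    def test_modality_mismatch_rejected(self, grid):
        with pytest.raises(PreprocessingError, match="mismatch"):
            subtract_blank(flat(grid, 500, Modality.FL440), flat(grid, 100, Modality.FL590))

    def test_baseline_shift_correction_removes_negative_offset(self):
        rng = np.random.default_rng(0)
        shifted = rng.normal(-50.0, 1.0, 500)
        corrected = correct_baseline_shift(shifted)
        assert np.percentile(corrected, 5) >= -1e-9
        untouched = rng.normal(50.0, 1.0, 500)
        assert np.array_equal(correct_baseline_shift(untouched), untouched)


class TestLowpassDesign:
    def test_unit_dc_gain(self):
        assert abs(design_lowpass().sum() - 1.0) < 1e-9

    def test_linear_phase_symmetry(self):
        taps = design_lowpass()
        assert len(taps) == 31
        assert np.allclose(taps, taps[::-1])

    def test_stopband_attenuated_relative_to_passband(self):
        taps = design_lowpass()
        w, h = sps.freqz(taps, worN=2048, fs=1.0)
        h = np.abs(h)
        assert h[np.argmin(np.abs(w - 0.4))] < h[np.argmin(np.abs(w - 0.05))]
        # passband essentially flat, stopband strongly suppressed
        assert h[np.argmin(np.abs(w - 0.05))] > 0.95
        assert h[np.argmin(np.abs(w - 0.4))] < 0.01

    def test_inverted_band_edges_rejected(self):
        with pytest.raises(FilterDesignError):
            FilterSpec(order=30, passband_frac=0.3, stopband_frac=0.1)

    def test_odd_order_rejected(self):
        with pytest.raises(FilterDesignError):
            FilterSpec(order=31)


class TestZeroPhaseFilter:
    def test_constant_preserved(self, grid):
        taps = design_lowpass()
        out = zero_phase_filter(flat(grid, 123.0, Modality.FL440), taps)
        assert np.allclose(out.values, 123.0, atol=1e-9)

    def test_peak_position_unchanged(self, grid):
        taps = design_lowpass()
        spec = gaussian_spectrum(grid, 501.0, 20.0, 1000.0)  # on-grid center
        out = zero_phase_filter(spec, taps)
        assert spec.wavelengths[np.argmax(out.values)] == 501.0

    def test_high_frequency_oscillation_suppressed(self, grid):
        """Steady-state response: a 0.45 fs oscillation is suppressed below
        1% RMS (edge-transient zones of the signal extension excluded)."""
        taps = design_lowpass()
        n = len(grid)
        osc = np.cos(2 * np.pi * 0.45 * np.arange(n))
        out = zero_phase_filter_values(osc, taps)
        pad = 3 * len(taps)
        interior = out[pad:-pad]
        assert np.sqrt(np.mean(interior**2)) < 0.01 * np.sqrt(np.mean(osc**2))

    def test_linearity(self, grid):
        taps = design_lowpass()
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=(2, len(grid)))
        lhs = zero_phase_filter_values(2.5 * x - 1.5 * y, taps)
        rhs = 2.5 * zero_phase_filter_values(x, taps) - 1.5 * zero_phase_filter_values(y, taps)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_short_spectrum_rejected(self):
        taps = design_lowpass()
        with pytest.raises(PreprocessingError, match="short"):
            zero_phase_filter_values(np.zeros(50), taps)


class TestTemperatureCorrection:
    def test_reference_temperature_is_identity(self, grid):
        model = TemperatureModel()
        spec = gaussian_spectrum(grid, 500, 30, 1000.0, temperature_c=21.3)
        out = temperature_correct(spec, model)
        assert np.allclose(out.values, spec.values)

    def test_known_drift_recovered(self, grid):
        model = TemperatureModel()
        reference = gaussian_spectrum(grid, 500, 30, 1000.0, baseline=100.0)
        factor = model.response_factor(Modality.FL440, 25.0)
        drifted = Spectrum(grid=grid, values=reference.values * factor,
                           modality=Modality.FL440, temperature_c=25.0)
        out = temperature_correct(drifted, model)
        assert np.allclose(out.values, reference.values, rtol=1e-3)

    def test_above_validity_bound_warns_but_corrects(self, grid):
        model = TemperatureModel()
        spec = gaussian_spectrum(grid, 500, 30, 1000.0, temperature_c=32.0)
        out = temperature_correct(spec, model)
        assert np.all(np.isfinite(out.values))
        assert any("warning" in p for p in out.provenance)

    def test_missing_temperature_rejected(self, grid):
        with pytest.raises(PreprocessingError):
            temperature_correct(gaussian_spectrum(grid, 500, 30, 1000.0), TemperatureModel())


class TestTurbidity:
    def test_zero_spectrum_gives_zero_fnu(self, grid, turbidity_cal):
        assert estimate_turbidity(flat(grid, 0.0, Modality.SC850), turbidity_cal) == 0.0

    def test_band_mean_equal_to_slope_gives_one_fnu(self, grid, turbidity_cal):
        spec = flat(grid, turbidity_cal.counts_per_fnu, Modality.SC850)
        assert estimate_turbidity(spec, turbidity_cal) == pytest.approx(1.0)

    def test_generated_turbidity_recovered(self, grid, turbidity_cal):
        cfg = ScenarioConfig(composition={"turbidity": 12.0}, noise_sd=5.0,
                             temperature_c=21.3, seed=4)
        pre = preprocess_bundle(generate_bundle(cfg, cal=turbidity_cal),
                                turbidity_cal=turbidity_cal)
        assert pre.turbidity_fnu == pytest.approx(12.0, abs=0.1)

    def test_saturated_band_rejected(self, grid, turbidity_cal):
        spec = flat(grid, 40_000.0, Modality.SC850)
        with pytest.raises(SaturationError):
            estimate_turbidity(spec, turbidity_cal)

    def test_zero_fnu_compensation_is_identity(self, grid, turbidity_cal):
        absorbance = compute_absorbance(flat(grid, 10.0), flat(grid, 100.0))
        out = compensate_turbidity(absorbance, 0.0, turbidity_cal)
        assert np.array_equal(out.absorbance, absorbance.absorbance)

    def test_additive_construction_recovered(self, grid, turbidity_cal):
        wl = grid.wavelengths()
        pure = 0.5 * np.exp(-((wl - 440) ** 2) / 800.0)
        absorbance = compute_absorbance(flat(grid, 10.0), flat(grid, 100.0)).with_absorbance(
            pure + 8.0 * turbidity_cal.profile)
        out = compensate_turbidity(absorbance, 8.0, turbidity_cal)
        assert np.allclose(out.absorbance, pure, atol=1e-6)

    def test_above_validity_bound_flagged(self, grid, turbidity_cal):
        absorbance = compute_absorbance(flat(grid, 10.0), flat(grid, 100.0))
        out = compensate_turbidity(absorbance, 25.0, turbidity_cal)
        assert any("low confidence" in w for w in out.warnings)


class TestFullChain:
    def test_chain_recovers_pure_absorbance(self, grid, turbidity_cal):
        """Blank handling + thermal + filtering + turbidity compensation
        recover the noise-free substance absorbance within 5% relative RMS."""
        cfg = ScenarioConfig(composition={"chlorophyll": 25.0}, fnu=8.0,
                             temperature_c=26.0, seed=10)
        bundle = generate_bundle(cfg, cal=turbidity_cal)
        pre = preprocess_bundle(bundle, turbidity_cal=turbidity_cal)
        truth = bundle.metadata["absorbance_true"]
        err = np.sqrt(np.mean((pre.absorbance.absorbance - truth) ** 2))
        scale = np.sqrt(np.mean(truth ** 2))
        assert err / scale <= 0.05

    def test_chain_is_deterministic(self, grid, turbidity_cal):
        cfg = ScenarioConfig(composition={"phycocyanin": 100.0}, fnu=3.0,
                             temperature_c=24.0, seed=5)
        pre1 = preprocess_bundle(generate_bundle(cfg, cal=turbidity_cal),
                                 turbidity_cal=turbidity_cal)
        pre2 = preprocess_bundle(generate_bundle(cfg, cal=turbidity_cal),
                                 turbidity_cal=turbidity_cal)
        assert np.array_equal(pre1.absorbance.absorbance, pre2.absorbance.absorbance)
        for m in pre1.emissions:
            assert np.array_equal(pre1.emissions[m].values, pre2.emissions[m].values)

    def test_warnings_surface_for_hot_turbid_sample(self, grid, turbidity_cal):
        # 22 FNU: above the compensation validity bound, below band saturation
        cfg = ScenarioConfig(composition={"turbidity": 22.0}, temperature_c=32.0, seed=6)
        pre = preprocess_bundle(generate_bundle(cfg, cal=turbidity_cal),
                                turbidity_cal=turbidity_cal)
        assert any("degC" in w for w in pre.warnings)
        assert any("FNU" in w for w in pre.warnings)
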