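import numpy as np
import pytest

from aquafuzz.preprocessing import preprocess_bundle
from aquafuzz.reference_fitting import (
    DegenerateReferenceError,
    EmptyReferenceError,
    GaussianComponent,
    ReferenceSpectrum,
    build_reference,
    extract_features,
    find_significant_peaks,
    load_library,
    save_library,
    score_against_reference,
)
from aquafuzz.spectral_io import Modality, Spectrum, WavelengthGrid
from aquafuzz.synthetic_data import ScenarioConfig, generate_bundle


def make_spectrum(grid, values, modality=Modality.FL440):
    return Spectrum(grid=grid, values=values, modality=modality)


class TestPeakDetection:
    def test_flat_spectrum_has_no_peaks(self, grid):
        assert find_significant_peaks(make_spectrum(grid, np.zeros(len(grid)))) == []

    def test_single_gaussian_found_at_center(self, grid):
        wl = grid.wavelengths()
        spec = make_spectrum(grid, 1000 * np.exp(-((wl - 440) ** 2) / 800))
        peaks = find_significant_peaks(spec)
        assert len(peaks) == 1
        assert abs(peaks[0][0] - 440) <= grid.step_nm

    def test_two_peaks_sorted_by_height(self, grid):
        wl = grid.wavelengths()
        values = (1000 * np.exp(-((wl - 440) ** 2) / 800)
                  + 500 * np.exp(-((wl - 680) ** 2) / 800))
        peaks = find_significant_peaks(make_spectrum(grid, values))
        assert [round(p[0]) for p in peaks[:2]] == [440, 680]
        assert peaks[0][1] > peaks[1][1]


class TestBuildReference:
    def test_noiseless_single_gaussian_recovered(self, grid):
        wl = grid.wavelengths()
        truth = GaussianComponent(1000.0, 440.0, 800.0)
        ref = build_reference(truth(wl), "x", Modality.FL440, wavelengths=wl)
        assert ref.n_components == 1
        comp = ref.components[0]
        assert comp.amplitude == pytest.approx(1000.0, rel=0.01)
        assert comp.center_nm == pytest.approx(440.0, rel=0.01)
        assert comp.width_nm2 == pytest.approx(800.0, rel=0.01)

    def test_two_separated_gaussians_recovered(self, grid):
        wl = grid.wavelengths()
        g1 = GaussianComponent(1000.0, 440.0, 800.0)
        g2 = GaussianComponent(600.0, 680.0, 1200.0)
        ref = build_reference(g1(wl) + g2(wl), "x", Modality.FL440, wavelengths=wl)
        assert ref.n_components == 2
        centers = sorted(c.center_nm for c in ref.components)
        assert abs(centers[0] - 440.0) <= grid.step_nm
        assert abs(centers[1] - 680.0) <= grid.step_nm

    def test_pure_noise_raises_empty_reference(self, grid):
        rng = np.random.default_rng(0)
        with pytest.raises(EmptyReferenceError):
            build_reference(rng.normal(0, 10, len(grid)), "noise",
                            Modality.FL440, wavelengths=grid.wavelengths())

    def test_residual_not_worse_than_input(self, grid):
        """The fit-subtract loop only accepts components that reduce the
        residual RMS, so the model never describes the data worse than a
        zero model."""
        wl = grid.wavelengths()
        rng = np.random.default_rng(1)
        values = (1000 * np.exp(-((wl - 440) ** 2) / 800)
                  + 400 * np.exp(-((wl - 520) ** 2) / 1500)
                  + rng.normal(0, 10, len(grid)))
        ref = build_reference(values, "x", Modality.FL440, wavelengths=wl)
        fit = score_against_reference(values, ref, wavelengths=wl)
        assert fit.residual_rms <= np.sqrt(np.mean(values**2))
        assert fit.r_squared >= 0.95


class TestScoring:
    def _ref(self):
        return ReferenceSpectrum("x", Modality.FL440,
                                 [GaussianComponent(1000.0, 440.0, 800.0),
                                  GaussianComponent(300.0, 500.0, 1000.0)])

    def test_scaled_reference_scores_perfectly(self, grid):
        ref = self._ref()
        wl = grid.wavelengths()
        fit = score_against_reference(2.0 * ref.evaluate(wl), ref, wavelengths=wl)
        assert fit.scale == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_shape_mismatch_floors_to_zero(self, grid):
        wl = grid.wavelengths()
        flat_spec = np.full(len(wl), 500.0)
        fit = score_against_reference(flat_spec, self._ref(), wavelengths=wl)
        assert fit.r_squared == 0.0

    def test_small_noise_keeps_high_r2(self, grid):
        wl = grid.wavelengths()
        rng = np.random.default_rng(2)
        clean = self._ref().evaluate(wl)
        noisy = clean + rng.normal(0, clean.max() / 100, len(wl))
        fit = score_against_reference(noisy, self._ref(), wavelengths=wl)
        assert fit.r_squared >= 0.99

    @pytest.mark.parametrize("s", [0.1, 3.0, 42.0])
    def test_scale_equivariance(self, grid, s):
        wl = grid.wavelengths()
        rng = np.random.default_rng(3)
        spec = self._ref().evaluate(wl) + rng.normal(0, 20, len(wl))
        base = score_against_reference(spec, self._ref(), wavelengths=wl)
        scaled = score_against_reference(s * spec, self._ref(), wavelengths=wl)
        assert scaled.scale == pytest.approx(s * base.scale, rel=1e-9)
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-9)

    def test_reference_far_outside_grid_is_degenerate(self):
        grid = WavelengthGrid(800, 900, 1.5)
        ref = ReferenceSpectrum("x", Modality.FL440,
                                [GaussianComponent(1000.0, 250.0, 200.0)])
        with pytest.raises(DegenerateReferenceError):
            score_against_reference(np.ones(len(grid)), ref,
                                    wavelengths=grid.wavelengths())


class TestParameterRecovery:
    def test_center_recovery_under_noise(self, grid):
        """Across seeded noisy single-Gaussian spectra the median center
        error stays within one grid step."""
        wl = grid.wavelengths()
        errors = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            center = rng.uniform(300, 800)
            truth = GaussianComponent(1000.0, center, rng.uniform(400, 2000))
            values = truth(wl) + rng.normal(0, 10.0, len(wl))
            ref = build_reference(values, "x", Modality.FL440, wavelengths=wl)
            main = max(ref.components, key=lambda c: c.amplitude)
            errors.append(abs(main.center_nm - center))
        assert np.median(errors) <= grid.step_nm


class TestFeatureExtraction:
    def test_self_consistency_of_library_substances(self, grid, turbidity_cal, library):
        """Bundles generated from the library's own substances score >= 0.99
        in their marker modality."""
        cases = {
            "chlorophyll": (25.0, Modality.FL440),
            "phycocyanin": (250.0, Modality.FL590),
            "turbidity": (10.0, Modality.SC850),
        }
        for substance, (conc, marker) in cases.items():
            cfg = ScenarioConfig(composition={substance: conc}, noise_sd=0.0,
                                 gain_jitter_sd=0.0, shape_jitter=False,
                                 temperature_c=21.3, seed=0)
            pre = preprocess_bundle(generate_bundle(cfg, cal=turbidity_cal),
                                    turbidity_cal=turbidity_cal)
            fv = extract_features(pre, library)
            assert fv.r2_by_modality[marker] >= 0.99, substance

    def test_missing_modality_scored_zero(self, grid, turbidity_cal, library):
        cfg = ScenarioConfig(composition={"chlorophyll": 25.0}, seed=1)
        bundle = generate_bundle(cfg, cal=turbidity_cal)
        del bundle.spectra[Modality.FL590]
        pre = preprocess_bundle(bundle, turbidity_cal=turbidity_cal)
        fv = extract_features(pre, library)
        assert fv.r2_by_modality[Modality.FL590] == 0.0

    def test_pure_water_scores_low_everywhere(self, grid, turbidity_cal, library):
        cfg = ScenarioConfig(composition={}, fnu=0.05, seed=2)
        pre = preprocess_bundle(generate_bundle(cfg, cal=turbidity_cal),
                                turbidity_cal=turbidity_cal)
        fv = extract_features(pre, library)
        for m, r2 in fv.r2_by_modality.items():
            assert r2 < 0.3, m

    def test_empty_library_rejected(self, grid, turbidity_cal):
        cfg = ScenarioConfig(composition={}, seed=3)
        pre = preprocess_bundle(generate_bundle(cfg, cal=turbidity_cal),
                                turbidity_cal=turbidity_cal)
        with pytest.raises(ValueError, match="empty"):
            extract_features(pre, {})


def test_library_round_trip(library, tmp_path):
    path = tmp_path / "library.json"
    save_library(library, path)
    back = load_library(path)
    assert set(back) == set(library)
    for key, ref in library.items():
        for a, b in zip(ref.components, back[key].components):
            assert a == b
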