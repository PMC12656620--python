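"""Seeded generator of realistic multi-modality water spectra.

Emulates the emulated instrument end to end: per modality a pure-water
blank (lamp/LED stray light plus dark counts), substance signals built
from Gaussian pigment bands, particle scattering proportional to turbidity
in FNU, a multiplicative thermal drift per light source, additive counts
noise, and clipping at the 40,000-count detector ceiling.

The substance models encode the qualitative spectral fingerprints the
method relies on: chlorophyll-type extracts absorb near 435/675 nm and
fluoresce near 680 nm under 440 nm excitation; phycocyanin — the
cyanobacteria marker — fluoresces near 650 nm under 590 nm excitation
(and only weakly under 440 nm); uranine (fluorescein) emits near 515 nm;
formazin-like turbidity standards only scatter.  Band parameters are
generator conventions chosen to be spectroscopically plausible, not
instrument measurements.

``generate_training_corpus`` reproduces the composition of the training
campaign: 40 spinach dilutions (0.25–40 %), 22 phycocyanin solutions
(10–700 mg/L), 12 moderately turbid (2–10 FNU) and 12 highly turbid
(10–20 FNU) samples, 11 pure-water samples and 22 uranine solutions —
119 labeled bundles across the six expert classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .fuzzy_classifier import CLASS_LABELS
from .preprocessing import (
    TemperatureModel,
    TurbidityCalibration,
    preprocess_bundle,
)
from .reference_fitting import (
    FeatureVector,
    GaussianComponent,
    ReferenceSpectrum,
    build_reference,
)
from .spectral_io import (
    SATURATION_CEILING,
    MeasurementBundle,
    Modality,
    Spectrum,
    WavelengthGrid,
)


# ---------------------------------------------------------------------------
# Substance models


@dataclass(frozen=True)
class SubstanceModel:
    """Spectral fingerprint of one substance, per unit concentration.

    ``emission_bands`` amplitudes are detector counts per concentration
    unit; ``absorbance_bands`` amplitudes are absorbance units per
    concentration unit; ``fnu_per_unit`` is the particle-scattering
    contribution in FNU per concentration unit.
    """

    name: str
    emission_bands: Mapping[Modality, tuple[GaussianComponent, ...]] = field(
        default_factory=dict)
    absorbance_bands: tuple[GaussianComponent, ...] = ()
    fnu_per_unit: float = 0.0


def _g(amplitude: float, center_nm: float, sigma_nm: float) -> GaussianComponent:
    return GaussianComponent(amplitude, center_nm, 2.0 * sigma_nm ** 2)


#: counts (or AU) are per % dilution of the stock solution
CHLOROPHYLL = SubstanceModel(
    name="chlorophyll",
    emission_bands={
        # red chlorophyll emission under 440 nm excitation, with vibronic shoulder
        Modality.FL440: (_g(800.0, 680.0, 22.0), _g(180.0, 735.0, 25.0)),
    },
    absorbance_bands=(
        _g(0.040, 270.0, 30.0),   # dissolved organic matter of the extract
        _g(0.030, 435.0, 25.0),   # Soret band
        _g(0.020, 675.0, 20.0),   # Q band
    ),
    fnu_per_unit=0.15,
)

#: per mg/L; phycocyanin is excited efficiently at 590 nm and only weakly at
#: 440 nm, so the 440 nm response stays below 10 % of the 590 nm response.
#: Cyanobacteria-derived pigment preparations carry a chlorophyll remnant
#: that emits near 680 nm under 440 nm excitation.
PHYCOCYANIN = SubstanceModel(
    name="phycocyanin",
    emission_bands={
        Modality.FL590: (_g(40.0, 650.0, 18.0),),
        Modality.FL440: (_g(1.2, 650.0, 18.0), _g(1.8, 680.0, 22.0)),
    },
    absorbance_bands=(
        _g(0.0015, 280.0, 25.0),  # aromatic protein band of the biliprotein
        _g(0.0012, 620.0, 25.0),
    ),
    fnu_per_unit=0.002,
)

#: formazin-like turbidity standard, per FNU: scattering only
TURBIDITY_STANDARD = SubstanceModel(name="turbidity", fnu_per_unit=1.0)

#: uranine (fluorescein), per mg/L: bright green emission with the typical
#: asymmetric red tail, visible absorption at 490 nm plus the UV band
URANINE = SubstanceModel(
    name="uranine",
    emission_bands={
        Modality.FL440: (_g(12000.0, 515.0, 20.0), _g(3000.0, 560.0, 45.0)),
    },
    absorbance_bands=(_g(0.20, 240.0, 20.0), _g(0.35, 490.0, 18.0)),
)

PURE_WATER = SubstanceModel(name="water")

DEFAULT_SUBSTANCES: dict[str, SubstanceModel] = {
    m.name: m for m in (CHLOROPHYLL, PHYCOCYANIN, TURBIDITY_STANDARD, URANINE, PURE_WATER)
}


# ---------------------------------------------------------------------------
# Instrument blanks


def blank_shape(modality: Modality, grid: WavelengthGrid) -> np.ndarray:
    """Noise-free pure-water spectrum of one channel.

    UV/Vis: the deuterium–tungsten lamp through water.  Fluorescence and
    scatter channels: stray excitation light plus dark counts.
    """
    wl = grid.wavelengths()
    modality = Modality(modality)
    if modality is Modality.UVVIS:
        return (12000.0 * np.exp(-((wl - 240.0) ** 2) / (2 * 45.0 ** 2))
                + 26000.0 * np.exp(-((wl - 620.0) ** 2) / (2 * 230.0 ** 2))
                + 2500.0)
    centers = {Modality.FL440: 440.0, Modality.FL590: 590.0, Modality.SC850: 850.0}
    amp = {Modality.FL440: 3000.0, Modality.FL590: 3000.0, Modality.SC850: 1500.0}
    return amp[modality] * np.exp(-((wl - centers[modality]) ** 2) / (2 * 9.0 ** 2)) + 200.0


def scatter_shape(grid: WavelengthGrid, cal: TurbidityCalibration) -> np.ndarray:
    """Scattered 850 nm LED line, normalized to mean 1 over the FNU band."""
    wl = grid.wavelengths()
    shape = np.exp(-((wl - cal.band_center_nm) ** 2) / (2 * 10.0 ** 2))
    band = cal.band_mask(grid)
    return shape / np.mean(shape[band])


# ---------------------------------------------------------------------------
# Scenario generation


@dataclass
class ScenarioConfig:
    """One simulated measurement: composition, conditions and noise."""

    composition: dict[str, float] = field(default_factory=dict)
    fnu: float = 0.0                       # ambient turbidity on top of substances
    temperature_c: float = 21.3
    noise_sd: float = 20.0                 # additive counts noise
    gain_jitter_sd: float = 0.03           # multiplicative signal jitter between replicates
    shape_jitter: bool = True              # band center/width variability (extract heterogeneity)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, conc in self.composition.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {name!r}")
        if self.fnu < 0:
            raise ValueError("fnu must be >= 0")


def _jitter_bands(bands: Sequence[GaussianComponent], rng: np.random.Generator,
                  enabled: bool) -> list[GaussianComponent]:
    """Band-parameter variability emulating sample heterogeneity."""
    if not enabled:
        return list(bands)
    out = []
    for b in bands:
        out.append(GaussianComponent(
            amplitude=b.amplitude * max(float(rng.normal(1.0, 0.08)), 0.2),
            center_nm=b.center_nm + float(rng.normal(0.0, 2.0)),
            width_nm2=b.width_nm2 * max(float(rng.normal(1.0, 0.10)), 0.3),
        ))
    return out


def generate_bundle(cfg: ScenarioConfig,
                    models: Mapping[str, SubstanceModel] | None = None,
                    cal: TurbidityCalibration | None = None,
                    temp_model: TemperatureModel | None = None,
                    grid: WavelengthGrid | None = None,
                    sample_id: str = "synthetic",
                    label: str | None = None,
                    ) -> MeasurementBundle:
    """Simulate one four-modality measurement with matching blanks.

    The forward model mirrors what the preprocessing chain inverts:
    emission channels record ``blank + g(T)·signal + noise``; the UV/Vis
    channel records ``I0·10^(−g(T)·A_total) + noise`` with A_total the
    substance absorbance plus the turbidity contribution; the scatter
    channel carries the total FNU times the calibration slope.  All
    channels clip at the saturation ceiling.
    """
    models = models if models is not None else DEFAULT_SUBSTANCES
    grid = grid or WavelengthGrid()
    cal = cal or TurbidityCalibration(grid=grid)
    temp_model = temp_model or TemperatureModel()
    rng = np.random.default_rng(cfg.seed)
    wl = grid.wavelengths()

    unknown = set(cfg.composition) - set(models)
    if unknown:
        raise ValueError(f"no substance model for {sorted(unknown)}")

    # total turbidity: ambient + substance particle load
    fnu_total = cfg.fnu + sum(
        conc * models[name].fnu_per_unit for name, conc in cfg.composition.items())

    # per-modality emitted signal (noise-free, reference temperature)
    signals: dict[Modality, np.ndarray] = {
        m: np.zeros_like(wl) for m in (Modality.FL440, Modality.FL590, Modality.SC850)}
    absorbance_true = np.zeros_like(wl)
    for name, conc in cfg.composition.items():
        if conc == 0:
            continue
        model = models[name]
        gain = max(float(rng.normal(1.0, cfg.gain_jitter_sd)), 0.1)
        for modality, bands in model.emission_bands.items():
            for band in _jitter_bands(bands, rng, cfg.shape_jitter):
                signals[Modality(modality)] += conc * gain * band(wl)
        for band in _jitter_bands(model.absorbance_bands, rng, cfg.shape_jitter):
            absorbance_true += conc * gain * band(wl)
    signals[Modality.SC850] = signals[Modality.SC850] + \
        fnu_total * cal.counts_per_fnu * scatter_shape(grid, cal)
    absorbance_observed = absorbance_true + fnu_total * cal.profile

    def finish(values: np.ndarray, modality: Modality, is_blank: bool) -> Spectrum:
        noisy = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
        clipped = np.clip(noisy, 0.0, SATURATION_CEILING)
        return Spectrum(grid=grid, values=clipped, modality=modality,
                        temperature_c=cfg.temperature_c, is_blank=is_blank)

    spectra: dict[Modality, Spectrum] = {}
    blanks: dict[Modality, Spectrum] = {}
    for modality in (Modality.FL440, Modality.FL590, Modality.SC850):
        base = blank_shape(modality, grid)
        g = temp_model.response_factor(modality, cfg.temperature_c)
        blanks[modality] = finish(base, modality, is_blank=True)
        spectra[modality] = finish(base + g * signals[modality], modality, is_blank=False)
    i0 = blank_shape(Modality.UVVIS, grid)
    g_uv = temp_model.response_factor(Modality.UVVIS, cfg.temperature_c)
    blanks[Modality.UVVIS] = finish(i0, Modality.UVVIS, is_blank=True)
    spectra[Modality.UVVIS] = finish(
        i0 * np.power(10.0, -g_uv * absorbance_observed), Modality.UVVIS, is_blank=False)

    return MeasurementBundle(
        sample_id=sample_id, spectra=spectra, blanks=blanks, label=label,
        metadata={
            "composition": dict(cfg.composition),
            "fnu_total": float(fnu_total),
            "temperature_c": cfg.temperature_c,
            "absorbance_true": absorbance_true,
        },
    )


# ---------------------------------------------------------------------------
# Labeled corpora


#: (label, substance, count, concentration range, log-spaced?) per class
CORPUS_DESIGN: tuple[tuple[str, str | None, int, tuple[float, float], bool], ...] = (
    ("blue_algae", "phycocyanin", 22, (10.0, 700.0), True),
    ("green_algae", "chlorophyll", 40, (0.25, 40.0), True),
    ("moderate_turbidity", "turbidity", 12, (2.0, 10.0), False),
    ("high_turbidity_or_foreign", "turbidity", 12, (10.5, 20.0), False),
    ("unknown_substance", "uranine", 22, (0.05, 2.0), True),
    ("no_substance", None, 11, (0.0, 0.0), False),
)


def generate_labeled_set(seed: int,
                         design: Sequence[tuple[str, str | None, int,
                                                tuple[float, float], bool]] = CORPUS_DESIGN,
                         noise_sd: float = 20.0,
                         temperature_c: float = 22.0,
                         ) -> list[MeasurementBundle]:
    """Generate one labeled bundle per design row entry, seeded.

    Concentrations span the stated range (log-spaced for dilution series);
    every bundle carries a small random ambient turbidity and a slight
    temperature jitter around the 22 °C laboratory conditions.
    """
    root = np.random.SeedSequence(seed)
    bundles: list[MeasurementBundle] = []
    for (label, substance, count, (lo, hi), log_spaced), ss in zip(
            design, root.spawn(len(design))):
        if substance is None:
            concs = np.zeros(count)
        elif log_spaced:
            concs = np.geomspace(lo, hi, count)
        else:
            concs = np.linspace(lo, hi, count)
        child_rng = np.random.default_rng(ss)
        for i, conc in enumerate(concs):
            scenario_seed = int(child_rng.integers(0, 2**31 - 1))
            jitter_rng = np.random.default_rng(scenario_seed + 1)
            cfg = ScenarioConfig(
                composition={substance: float(conc)} if substance else {},
                fnu=float(jitter_rng.uniform(0.0, 0.2)),
                temperature_c=temperature_c + float(jitter_rng.normal(0.0, 0.3)),
                noise_sd=noise_sd,
                seed=scenario_seed,
            )
            bundles.append(generate_bundle(
                cfg, sample_id=f"{label}_{i:03d}", label=label))
    return bundles


def generate_training_corpus(seed: int) -> list[MeasurementBundle]:
    """The 119-bundle training corpus across the six expert classes."""
    return generate_labeled_set(seed)


# ---------------------------------------------------------------------------
# Reference library from noiseless mid-range training spectra


#: mid-concentration training sample used to build each reference
LIBRARY_SOURCES: tuple[tuple[str, Modality, str, float], ...] = (
    ("chlorophyll", Modality.FL440, "chlorophyll", 25.0),
    ("chlorophyll", Modality.UVVIS, "chlorophyll", 25.0),
    ("phycocyanin", Modality.FL590, "phycocyanin", 250.0),
    ("turbidity", Modality.SC850, "turbidity", 10.0),
    ("uranine", Modality.FL440, "uranine", 0.3),
)


def make_reference_library(grid: WavelengthGrid | None = None,
                           cal: TurbidityCalibration | None = None,
                           ) -> dict[tuple[str, Modality], ReferenceSpectrum]:
    """Build the designated reference spectra from clean synthetic samples.

    Each reference comes from a noise-free, jitter-free bundle at the
    mid concentration of its dilution series, run through the full
    preprocessing chain and the iterative Gaussian fit — the same path a
    real training spectrum would take.  Deterministic.
    """
    grid = grid or WavelengthGrid()
    cal = cal or TurbidityCalibration(grid=grid)
    library: dict[tuple[str, Modality], ReferenceSpectrum] = {}
    for substance, modality, model_name, conc in LIBRARY_SOURCES:
        cfg = ScenarioConfig(
            composition={model_name: conc}, fnu=0.0, temperature_c=21.3,
            noise_sd=0.0, gain_jitter_sd=0.0, shape_jitter=False, seed=0)
        bundle = generate_bundle(cfg, cal=cal, grid=grid,
                                 sample_id=f"ref_{substance}_{modality.value}")
        pre = preprocess_bundle(bundle, turbidity_cal=cal)
        if modality is Modality.UVVIS:
            source = pre.absorbance
        else:
            source = pre.emissions[modality]
        library[(substance, modality)] = build_reference(
            source, substance=substance, modality=modality)
    return library


# ---------------------------------------------------------------------------
# Worked-example feature vectors (field-campaign results, transcribed)


def generate_worked_example_features() -> list[FeatureVector]:
    """Feature vectors of the published field campaigns.

    Nine lake samples: three from the August campaign and three each from
    the September laboratory and submersible-probe runs.  The 590 nm zeros
    of the September samples are the poor-fit convention at work.
    """
    rows = [
        # (sample_id, r2_440, r2_590, r2_850, r2_uvvis, expected class index)
        ("august_1", 0.7679, 0.9627, 0.9287, 0.4017, 1),
        ("august_2", 0.7202, 0.9605, 0.9512, 0.3394, 1),
        ("august_3", 0.7206, 0.9571, 0.9490, 0.3605, 1),
        ("september_lab_1", 0.8365, 0.0, 0.9553, 0.6750, 2),
        ("september_lab_2", 0.8291, 0.0, 0.9667, 0.6646, 2),
        ("september_lab_3", 0.8654, 0.0, 0.9632, 0.6534, 2),
        ("september_probe_1", 0.8894, 0.0, 0.6294, 0.4553, 2),
        ("september_probe_2", 0.8765, 0.0, 0.5236, 0.5337, 2),
        ("september_probe_3", 0.8840, 0.0, 0.4003, 0.5861, 2),
    ]
    return [
        FeatureVector(
            sample_id=sid,
            r2_by_modality={
                Modality.FL440: r440, Modality.FL590: r590,
                Modality.SC850: r850, Modality.UVVIS: ruv,
            },
            label=CLASS_LABELS[cls - 1],
        )
        for sid, r440, r590, r850, ruv, cls in rows
    ]
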