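"""Raw-spectrum preprocessing.

The chain turns raw detector counts into physically meaningful, denoised
spectra in a fixed order:

1. blank handling — UV/Vis counts become absorbance A = log10(I0/I);
   fluorescence and scatter counts get the pure-water blank subtracted,
2. temperature normalization to the 21.3 °C reference,
3. zero-phase FIR low-pass filtering (30th order, fp = 0.1 fs, fsb = 0.3 fs),
4. turbidity compensation of the UV/Vis absorbance using the scattered-light
   channel as an FNU estimator (valid up to ~20 FNU).

Each step attaches a provenance entry; validity violations (temperature
above 30 °C, turbidity above 20 FNU, saturation) are surfaced as warnings
on the result, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal

from .spectral_io import (
    MeasurementBundle,
    Modality,
    Spectrum,
    WavelengthGrid,
)

#: Reference temperature all spectra are normalized to (°C).
REFERENCE_TEMP_C = 21.3
#: Upper validity bound of the linear thermal correction (°C).
TEMP_VALID_MAX_C = 30.0
#: Upper validity bound of the turbidity compensation (FNU).
TURBIDITY_VALID_MAX_FNU = 20.0


class CalibrationError(ValueError):
    """Blank or calibration data unusable (zeros, negatives, saturation)."""


class FilterDesignError(ValueError):
    pass


class PreprocessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration types


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass FIR specification in fractions of the sampling rate.

    ``order`` taps-minus-one must be even so the filter has a center tap
    (type-I linear phase).  Defaults follow the instrument's smoothing
    setup: 30th order, passband edge 0.1 fs, stopband edge 0.3 fs.
    """

    order: int = 30
    passband_frac: float = 0.1
    stopband_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2 != 0:
            raise FilterDesignError("filter order must be even and >= 2")
        if not (0.0 < self.passband_frac < self.stopband_frac < 0.5):
            raise FilterDesignError(
                "need 0 < passband_frac < stopband_frac < 0.5 (fractions of fs)")


@dataclass(frozen=True)
class TemperatureModel:
    """Multiplicative thermal response, linear in (T - 21.3 °C) per modality.

    The instrument's light sources drift with temperature; ``slope_per_c``
    holds the fractional intensity change per °C for each source.  The
    correction divides measured values by ``1 + slope * (T - Tref)`` so
    that spectra acquired at the reference temperature pass unchanged.
    """

    reference_temp_c: float = REFERENCE_TEMP_C
    slope_per_c: Mapping[Modality, float] = field(
        default_factory=lambda: {
            Modality.UVVIS: -0.0035,
            Modality.FL440: -0.0060,
            Modality.FL590: -0.0050,
            Modality.SC850: -0.0045,
        })
    valid_max_c: float = TEMP_VALID_MAX_C

    def response_factor(self, modality: Modality, temperature_c: float) -> float:
        """Modelled intensity ratio at ``temperature_c`` vs the reference."""
        slope = self.slope_per_c.get(Modality(modality), 0.0)
        factor = 1.0 + slope * (temperature_c - self.reference_temp_c)
        if factor <= 0:
            raise PreprocessingError(
                f"temperature model factor non-positive at {temperature_c} degC")
        return factor


def default_turbidity_profile(grid: WavelengthGrid,
                              amplitude_at_850: float = 0.005) -> np.ndarray:
    """Per-wavelength absorbance contribution of 1 FNU of turbidity.

    Particle scattering losses decrease with wavelength; the default shape
    is proportional to 1/lambda, normalized to ``amplitude_at_850``
    absorbance units at 850 nm.
    """
    wl = grid.wavelengths()
    return amplitude_at_850 * 850.0 / wl


@dataclass
class TurbidityCalibration:
    """Scattered-light-to-FNU calibration plus UV/Vis compensation profile."""

    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    band_center_nm: float = 850.0
    band_halfwidth_nm: float = 10.0
    counts_per_fnu: float = 1500.0
    profile: np.ndarray | None = None    # absorbance per FNU, on `grid`
    valid_max_fnu: float = TURBIDITY_VALID_MAX_FNU

    def __post_init__(self) -> None:
        if self.counts_per_fnu <= 0:
            raise CalibrationError("counts_per_fnu must be > 0")
        if self.profile is None:
            self.profile = default_turbidity_profile(self.grid)
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (len(self.grid),):
            raise CalibrationError("turbidity profile length does not match grid")

    def band_mask(self, grid: WavelengthGrid) -> np.ndarray:
        wl = grid.wavelengths()
        return np.abs(wl - self.band_center_nm) <= self.band_halfwidth_nm


@dataclass
class AbsorbanceSpectrum:
    """Dimensionless absorbance on a wavelength grid (UV/Vis only)."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    temperature_c: float | None = None
    provenance: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (len(self.grid),):
            raise ValueError("absorbance length does not match grid")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths()

    def with_absorbance(self, values: np.ndarray, step: str | None = None
                        ) -> "AbsorbanceSpectrum":
        prov = list(self.provenance) + ([step] if step else [])
        return replace(self, absorbance=np.asarray(values, float), provenance=prov)


# ---------------------------------------------------------------------------
# Blank handling


def compute_absorbance(sample: Spectrum, blank: Spectrum,
                       epsilon_counts: float = 1e-2) -> AbsorbanceSpectrum:
    """Beer–Lambert conversion A(λ) = log10(I0/I) of a UV/Vis pair.

    Sample intensities at or below zero (possible after detector offset
    removal) are clipped to ``epsilon_counts`` before the division and a
    warning is attached; a blank containing non-positive intensities is a
    calibration error.
    """
    if Modality(sample.modality) is not Modality.UVVIS:
        raise PreprocessingError("absorbance is defined for uvvis spectra only")
    if sample.grid != blank.grid:
        raise PreprocessingError("sample and blank are on different grids")
    i0 = blank.values
    if np.any(i0 <= 0):
        raise CalibrationError("blank spectrum contains non-positive intensities")
    warnings = []
    i = sample.values
    if np.any(i <= 0):
        i = np.clip(i, epsilon_counts, None)
        warnings.append("uvvis: non-positive sample intensities clipped before log")
    out = AbsorbanceSpectrum(
        grid=sample.grid,
        absorbance=np.log10(i0 / i),
        temperature_c=sample.temperature_c,
        provenance=list(sample.provenance) + ["absorbance"],
        warnings=warnings,
    )
    return out


def subtract_blank(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Blank subtraction F(λ) = I(λ) − I0(λ) for emission/scatter channels.

    Negative values are preserved — downstream filtering and the optional
    baseline-shift correction handle them.
    """
    if Modality(sample.modality) is Modality.UVVIS:
        raise PreprocessingError("uvvis uses compute_absorbance, not blank subtraction")
    if Modality(sample.modality) is not Modality(blank.modality):
        raise PreprocessingError(
            f"modality mismatch: sample {sample.modality} vs blank {blank.modality}")
    if sample.grid != blank.grid:
        raise PreprocessingError("sample and blank are on different grids")
    return sample.with_values(sample.values - blank.values, step="blank_subtracted")


def correct_baseline_shift(values: np.ndarray) -> np.ndarray:
    """Remove a negative baseline offset by subtracting the 5th percentile.

    Submersible-probe spectra can sit slightly below zero after blank
    subtraction; when the 5th percentile is negative it is treated as the
    offset and removed, otherwise values pass through unchanged.
    """
    values = np.asarray(values, dtype=float)
    p5 = np.percentile(values, 5)
    if p5 < 0:
        return values - p5
    return values


# ---------------------------------------------------------------------------
# Temperature normalization


def temperature_correct(spectrum: Spectrum, model: TemperatureModel) -> Spectrum:
    """Normalize a spectrum to the 21.3 °C reference temperature.

    Divides by the modality-specific thermal response factor.  Above the
    model's 30 °C validity bound the correction is still applied but a
    warning is recorded in the provenance.
    """
    if spectrum.temperature_c is None:
        raise PreprocessingError("spectrum carries no acquisition temperature")
    t = spectrum.temperature_c
    factor = model.response_factor(spectrum.modality, t)
    out = spectrum.with_values(spectrum.values / factor,
                               step=f"temperature_corrected[T={t:g}C]")
    if t > model.valid_max_c:
        out.provenance.append(
            f"warning: temperature {t:g} degC above {model.valid_max_c:g} degC "
            "validity bound; non-linear thermal effects possible")
    return out


def temperature_correct_values(values: np.ndarray, modality: Modality,
                               temperature_c: float, model: TemperatureModel
                               ) -> tuple[np.ndarray, list[str]]:
    """Array-level variant used for absorbance spectra; returns warnings."""
    factor = model.response_factor(modality, temperature_c)
    warnings = []
    if temperature_c > model.valid_max_c:
        warnings.append(
            f"{Modality(modality).value}: temperature {temperature_c:g} degC above "
            f"{model.valid_max_c:g} degC validity bound")
    return np.asarray(values, float) / factor, warnings


# ---------------------------------------------------------------------------
# Zero-phase low-pass filtering


def design_lowpass(spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Windowed-sinc (Hamming) FIR taps for the smoothing filter.

    The cutoff is placed midway between the passband and stopband edges and
    the taps are renormalized to exactly unit DC gain.  ``order + 1``
    symmetric taps are returned (linear phase).
    """
    cutoff = 0.5 * (spec.passband_frac + spec.stopband_frac)
    # firwin takes the cutoff relative to the Nyquist frequency fs/2
    taps = signal.firwin(spec.order + 1, cutoff * 2.0, window="hamming")
    return taps / taps.sum()


def zero_phase_filter_values(values: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward–backward FIR application with odd-symmetric edge extension.

    The effective magnitude response is the squared single-pass magnitude
    and the net phase is zero, so symmetric peaks keep their position.
    """
    values = np.asarray(values, dtype=float)
    padlen = 3 * len(taps)
    if len(values) <= padlen:
        raise PreprocessingError(
            f"spectrum of length {len(values)} too short for zero-phase filtering "
            f"(needs > {padlen} points)")
    return signal.filtfilt(taps, [1.0], values, padtype="odd", padlen=padlen)


def zero_phase_filter(spectrum: Spectrum, taps: np.ndarray) -> Spectrum:
    return spectrum.with_values(
        zero_phase_filter_values(spectrum.values, taps), step="lowpass_filtered")


# ---------------------------------------------------------------------------
# Turbidity estimation and compensation


class SaturationError(RuntimeError):
    """Scattered-light band saturated; the turbidity estimate is unreliable."""


def estimate_turbidity(sc850: Spectrum, cal: TurbidityCalibration) -> float:
    """Turbidity in FNU from a blank-subtracted scattered-light spectrum.

    The mean intensity over the 850 ± halfwidth band divided by the
    calibration slope; floored at zero.
    """
    mask = cal.band_mask(sc850.grid)
    if not mask.any():
        raise CalibrationError("calibration band lies outside the spectrum grid")
    if sc850.saturated:
        band = sc850.values[mask]
        if np.any(band + 1e-9 >= sc850.saturation_ceiling):
            raise SaturationError(
                "scattered-light band saturated; turbidity estimate unreliable")
    fnu = float(np.mean(sc850.values[mask]) / cal.counts_per_fnu)
    return max(fnu, 0.0)


def compensate_turbidity(absorbance: AbsorbanceSpectrum, fnu: float,
                         cal: TurbidityCalibration) -> AbsorbanceSpectrum:
    """Remove the turbidity contribution fnu · profile(λ) from absorbance.

    Above the ~20 FNU validity bound (multiple scattering) the correction
    is still applied but the result is flagged low-confidence.
    """
    if fnu < 0:
        raise PreprocessingError("turbidity must be >= 0 FNU")
    profile = cal.profile
    if absorbance.grid != cal.grid:
        profile = np.interp(absorbance.wavelengths, cal.grid.wavelengths(), profile)
    out = absorbance.with_absorbance(
        absorbance.absorbance - fnu * profile,
        step=f"turbidity_compensated[fnu={fnu:.3g}]")
    out.warnings = list(absorbance.warnings)
    if fnu > cal.valid_max_fnu:
        out.warnings.append(
            f"uvvis: turbidity {fnu:.3g} FNU above {cal.valid_max_fnu:g} FNU "
            "compensation validity bound; low confidence")
    return out


# ---------------------------------------------------------------------------
# Full chain


@dataclass
class PreprocessedBundle:
    """Output of the full preprocessing chain for one sample."""

    sample_id: str
    absorbance: AbsorbanceSpectrum | None
    emissions: dict[Modality, Spectrum]   # fl440 / fl590 / sc850, fully processed
    turbidity_fnu: float | None
    warnings: list[str] = field(default_factory=list)
    label: str | None = None


def preprocess_bundle(bundle: MeasurementBundle,
                      filter_spec: FilterSpec = FilterSpec(),
                      temp_model: TemperatureModel | None = None,
                      turbidity_cal: TurbidityCalibration | None = None,
                      baseline_shift_correction: bool = True,
                      ) -> PreprocessedBundle:
    """Run blank handling → temperature correction → filtering → turbidity
    compensation on every modality present in the bundle.
    """
    temp_model = temp_model or TemperatureModel()
    taps = design_lowpass(filter_spec)
    warnings: list[str] = []

    emissions: dict[Modality, Spectrum] = {}
    for modality in (Modality.FL440, Modality.FL590, Modality.SC850):
        sample = bundle.spectra.get(modality)
        blank = bundle.blanks.get(modality)
        if sample is None or blank is None:
            continue
        if sample.saturated:
            warnings.append(f"{modality.value}: sample spectrum saturated")
        sub = subtract_blank(sample, blank)
        if sample.temperature_c is not None:
            sub = temperature_correct(sub, temp_model)
            warnings.extend(p.removeprefix("warning: ")
                            for p in sub.provenance if p.startswith("warning:"))
        filtered = zero_phase_filter(sub, taps)
        if baseline_shift_correction:
            filtered = filtered.with_values(
                correct_baseline_shift(filtered.values), step="baseline_shift")
        emissions[modality] = filtered

    fnu: float | None = None
    if Modality.SC850 in emissions:
        cal_for_estimate = turbidity_cal or TurbidityCalibration(
            grid=emissions[Modality.SC850].grid)
        try:
            fnu = estimate_turbidity(emissions[Modality.SC850], cal_for_estimate)
        except SaturationError:
            warnings.append("sc850: band saturated; turbidity estimate unreliable")
            fnu = None

    absorbance: AbsorbanceSpectrum | None = None
    sample = bundle.spectra.get(Modality.UVVIS)
    blank = bundle.blanks.get(Modality.UVVIS)
    if sample is not None and blank is not None:
        if sample.saturated:
            warnings.append("uvvis: sample spectrum saturated")
        absorbance = compute_absorbance(sample, blank)
        warnings.extend(absorbance.warnings)
        absorbance.warnings = []
        if sample.temperature_c is not None:
            corrected, tw = temperature_correct_values(
                absorbance.absorbance, Modality.UVVIS, sample.temperature_c, temp_model)
            warnings.extend(tw)
            absorbance = absorbance.with_absorbance(
                corrected, step=f"temperature_corrected[T={sample.temperature_c:g}C]")
        absorbance = absorbance.with_absorbance(
            zero_phase_filter_values(absorbance.absorbance, taps),
            step="lowpass_filtered")
        if fnu is not None and turbidity_cal is not None:
            absorbance = compensate_turbidity(absorbance, fnu, turbidity_cal)
            warnings.extend(absorbance.warnings)
            absorbance.warnings = []

    # deduplicate, preserving order
    seen: set[str] = set()
    warnings = [w for w in warnings if not (w in seen or seen.add(w))]
    return PreprocessedBundle(
        sample_id=bundle.sample_id,
        absorbance=absorbance,
        emissions=emissions,
        turbidity_fnu=fnu,
        warnings=warnings,
        label=bundle.label,
    )
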