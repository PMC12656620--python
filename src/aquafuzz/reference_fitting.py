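"""Gaussian reference spectra and R² conformity features.

Each substance/modality pair gets a *reference spectrum*: a sum of Gaussian
components

    A_ref(λ) = k · Σ_i  a_i · exp(−(λ − λ_i)² / c_i)

built by iteratively fitting and subtracting the tallest remaining peak of
a processed training spectrum until the residual is almost flat.  Unknown
spectra are then scored against the reference over the full wavelength
grid; the coefficient of determination R² of the best scaled fit is the
conformity feature fed to the classifier.  Poor fits (R² < 0) are floored
to zero by convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .preprocessing import AbsorbanceSpectrum, PreprocessedBundle
from .spectral_io import Modality, Spectrum, WavelengthGrid


class EmptyReferenceError(ValueError):
    """No significant peak found: a reference cannot be built."""


class DegenerateReferenceError(ValueError):
    """Reference evaluates to (numerically) zero everywhere."""


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian band: a·exp(−(λ−λ0)²/c) with c in nm² (denominator form)."""

    amplitude: float
    center_nm: float
    width_nm2: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.width_nm2 <= 0:
            raise ValueError("width must be > 0")

    @property
    def sigma_nm(self) -> float:
        """Equivalent standard deviation: c = 2σ²."""
        return float(np.sqrt(self.width_nm2 / 2.0))

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(-((wl - self.center_nm) ** 2) / self.width_nm2)


@dataclass
class ReferenceSpectrum:
    """Sum-of-Gaussians model of one substance in one modality."""

    substance: str
    modality: Modality
    components: list[GaussianComponent]

    def __post_init__(self) -> None:
        if not self.components:
            raise EmptyReferenceError("a reference needs at least one component")
        self.modality = Modality(self.modality)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for comp in self.components:
            out += comp(wl)
        return out


@dataclass
class FitResult:
    """Best least-squares scaling of a spectrum onto a reference."""

    scale: float
    r_squared: float
    residual_rms: float


@dataclass
class FeatureVector:
    """Per-modality R² conformity features of one sample.

    Missing or failed modalities are stored as 0 (the poor-fit convention).
    ``extras`` carries additional scalar features such as the turbidity
    estimate in FNU.
    """

    sample_id: str
    r2_by_modality: dict[Modality, float]
    extras: dict[str, float] = field(default_factory=dict)
    label: str | None = None

    FEATURE_NAMES = {
        Modality.FL440: "r2_440",
        Modality.FL590: "r2_590",
        Modality.SC850: "r2_850",
        Modality.UVVIS: "r2_uvvis",
    }

    def as_dict(self) -> dict[str, float]:
        out = {self.FEATURE_NAMES[m]: self.r2_by_modality.get(m, 0.0)
               for m in (Modality.FL440, Modality.FL590, Modality.SC850, Modality.UVVIS)}
        out.update(self.extras)
        return out


# ---------------------------------------------------------------------------
# Peak detection


def estimate_noise_mad(values: np.ndarray) -> float:
    """Robust noise scale from the MAD of first differences.

    For a smooth signal plus white noise of sd σ the first differences have
    sd σ√2; the MAD is scaled accordingly.
    """
    d = np.diff(np.asarray(values, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def find_significant_peaks(spectrum: Spectrum | AbsorbanceSpectrum | np.ndarray,
                           wavelengths: np.ndarray | None = None,
                           min_prominence: float | None = None,
                           noise_factor: float = 3.0,
                           ) -> list[tuple[float, float]]:
    """Local maxima with prominence above threshold, tallest first.

    The default threshold is ``noise_factor`` times the estimated noise MAD
    (at least a tiny fraction of the dynamic range, so a flat spectrum
    yields no peaks).  Returns (center wavelength nm, height) pairs.
    """
    values, wl = _values_and_wavelengths(spectrum, wavelengths)
    if min_prominence is None:
        scale = float(np.max(np.abs(values))) if values.size else 0.0
        min_prominence = max(noise_factor * estimate_noise_mad(values), 1e-6 * max(scale, 1.0))
    idx, props = signal.find_peaks(values, prominence=min_prominence)
    peaks = [(float(wl[i]), float(values[i])) for i in idx]
    peaks.sort(key=lambda p: p[1], reverse=True)
    return peaks


def _values_and_wavelengths(spectrum, wavelengths):
    if isinstance(spectrum, Spectrum):
        return spectrum.values, spectrum.wavelengths
    if isinstance(spectrum, AbsorbanceSpectrum):
        return spectrum.absorbance, spectrum.wavelengths
    values = np.asarray(spectrum, dtype=float)
    if wavelengths is None:
        raise ValueError("wavelengths required when passing a bare array")
    return values, np.asarray(wavelengths, dtype=float)


# ---------------------------------------------------------------------------
# Iterative peak-fit-subtract reference construction


def _gauss(wl, a, center, width):
    return a * np.exp(-((wl - center) ** 2) / width)


def _fit_single_gaussian(wl: np.ndarray, values: np.ndarray,
                         center0: float, height0: float,
                         step_nm: float) -> GaussianComponent:
    """Least-squares fit of one Gaussian around a detected peak.

    The fit window is ±3σ-equivalent around the peak (σ estimated from the
    half-maximum crossing) to limit coupling between overlapping bands.
    """
    # initial width from half-max crossings
    i0 = int(np.argmin(np.abs(wl - center0)))
    half = height0 / 2.0
    i_left, i_right = i0, i0
    while i_left > 0 and values[i_left] > half:
        i_left -= 1
    while i_right < len(values) - 1 and values[i_right] > half:
        i_right += 1
    fwhm = max((wl[i_right] - wl[i_left]), 2.0 * step_nm)
    sigma0 = fwhm / 2.3548
    width0 = 2.0 * sigma0 ** 2

    window = np.abs(wl - center0) <= 3.0 * sigma0
    if window.sum() < 5:
        window = np.abs(wl - center0) <= 5.0 * step_nm
    try:
        popt, _ = curve_fit(
            _gauss, wl[window], values[window],
            p0=[height0, center0, width0],
            bounds=([1e-12, wl[0], (0.5 * step_nm) ** 2],
                    [np.inf, wl[-1], (wl[-1] - wl[0]) ** 2]),
            maxfev=10_000,
        )
        a, center, width = popt
    except RuntimeError:
        a, center, width = height0, center0, width0
    return GaussianComponent(float(a), float(center), float(width))


@dataclass(frozen=True)
class FlatnessRule:
    """Stop rule for the iterative fit-subtract loop.

    The loop stops when the residual maximum drops below
    ``residual_max_frac`` of the original spectrum maximum, when no peak
    exceeds ``noise_factor`` × noise MAD in prominence, or after
    ``max_components`` iterations.
    """

    residual_max_frac: float = 0.02
    noise_factor: float = 3.0
    #: minimum peak height in noise-MAD units; peak-to-valley prominence of
    #: pure noise reaches ~6 sigma, so significance is judged on height
    height_factor: float = 5.0
    max_components: int = 12


def build_reference(spectrum: Spectrum | AbsorbanceSpectrum | np.ndarray,
                    substance: str,
                    modality: Modality | None = None,
                    wavelengths: np.ndarray | None = None,
                    stop_rule: FlatnessRule = FlatnessRule(),
                    ) -> ReferenceSpectrum:
    """Build a sum-of-Gaussians reference by iterative peak fit-and-subtract.

    Raises :class:`EmptyReferenceError` when the input has no significant
    peak at entry.  Residual RMS is non-increasing across iterations by
    construction: a candidate component is only accepted if subtracting it
    does not increase the residual RMS.
    """
    values, wl = _values_and_wavelengths(spectrum, wavelengths)
    if modality is None:
        if isinstance(spectrum, Spectrum):
            modality = spectrum.modality
        elif isinstance(spectrum, AbsorbanceSpectrum):
            modality = Modality.UVVIS
        else:
            raise ValueError("modality required when passing a bare array")
    step_nm = float(np.median(np.diff(wl)))
    noise = estimate_noise_mad(values)
    original_max = float(np.max(values)) if values.size else 0.0
    min_prom = max(stop_rule.noise_factor * noise, 1e-6 * max(abs(original_max), 1.0))
    min_height = max(stop_rule.height_factor * noise, 1e-6 * max(abs(original_max), 1.0))

    residual = values.astype(float).copy()
    components: list[GaussianComponent] = []
    while len(components) < stop_rule.max_components:
        if float(np.max(residual)) < stop_rule.residual_max_frac * original_max:
            break
        peaks = find_significant_peaks(residual, wl, min_prominence=min_prom)
        if not peaks or peaks[0][1] < min_height:
            break
        center0, height0 = peaks[0]
        comp = _fit_single_gaussian(wl, residual, center0, height0, step_nm)
        new_residual = residual - comp(wl)
        if _rms(new_residual) > _rms(residual):
            break   # fit no longer improves the description
        residual = new_residual
        components.append(comp)
    if not components:
        raise EmptyReferenceError(
            f"no significant peak in {substance}/{Modality(modality).value} spectrum")
    return ReferenceSpectrum(substance=substance, modality=Modality(modality),
                             components=components)


def _rms(values: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(values))))


# ---------------------------------------------------------------------------
# Scoring


def score_against_reference(spectrum: Spectrum | AbsorbanceSpectrum | np.ndarray,
                            ref: ReferenceSpectrum,
                            wavelengths: np.ndarray | None = None,
                            ) -> FitResult:
    """Scale the reference to the spectrum and report the full-grid R².

    The scale k is the closed-form least-squares solution
    k = ⟨s, r⟩ / ⟨r, r⟩; R² = 1 − SS_res/SS_tot is computed over the whole
    wavelength grid and floored at 0 for poor fits.
    """
    values, wl = _values_and_wavelengths(spectrum, wavelengths)
    r = ref.evaluate(wl)
    denom = float(np.dot(r, r))
    if denom <= 0 or float(np.max(np.abs(r))) < 1e-12:
        raise DegenerateReferenceError("reference evaluates to zero on this grid")
    k = float(np.dot(values, r) / denom)
    fitted = k * r
    ss_res = float(np.sum((values - fitted) ** 2))
    ss_tot = float(np.sum((values - np.mean(values)) ** 2))
    if ss_tot <= 0:
        r2 = 1.0 if ss_res == 0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return FitResult(scale=k, r_squared=r2, residual_rms=_rms(values - fitted))


#: Which substance's reference each modality is scored against by default:
#: chlorophyll-type signal in UV/Vis and 440 nm fluorescence, phycocyanin in
#: 590 nm fluorescence, the turbidity scatter shape at 850 nm.
DEFAULT_DESIGNATION: dict[Modality, str] = {
    Modality.UVVIS: "chlorophyll",
    Modality.FL440: "chlorophyll",
    Modality.FL590: "phycocyanin",
    Modality.SC850: "turbidity",
}

#: Additional named conformity features: each scores one modality against a
#: second substance's reference.  The default flags fluorescent foreign
#: substances, which would otherwise be invisible to the pigment-designated
#: features (their poor fits all floor to zero, like pure water's).
SECONDARY_FEATURES: dict[str, tuple[Modality, str]] = {
    "r2_440_foreign": (Modality.FL440, "uranine"),
}


def _modality_data(bundle: PreprocessedBundle, modality: Modality):
    if modality is Modality.UVVIS:
        target = bundle.absorbance
        if target is None:
            return None, None
        return target.absorbance, target.wavelengths
    target = bundle.emissions.get(modality)
    if target is None:
        return None, None
    return target.values, target.wavelengths


def _score_or_zero(bundle: PreprocessedBundle, modality: Modality,
                   ref: ReferenceSpectrum | None) -> float:
    if ref is None:
        return 0.0
    data, wl = _modality_data(bundle, modality)
    if data is None:
        return 0.0
    try:
        return score_against_reference(data, ref, wavelengths=wl).r_squared
    except DegenerateReferenceError:
        return 0.0


def extract_features(bundle: PreprocessedBundle,
                     library: Mapping[tuple[str, Modality], ReferenceSpectrum],
                     designation: Mapping[Modality, str] = DEFAULT_DESIGNATION,
                     secondary: Mapping[str, tuple[Modality, str]] | None = None,
                     ) -> FeatureVector:
    """Score one preprocessed bundle against its designated references.

    Each modality contributes the R² against the reference designated for
    it; a missing modality, missing reference, or degenerate fit is
    recorded as 0.  The turbidity estimate (FNU) and any secondary
    conformity features whose reference exists in the library are carried
    along in ``extras``.
    """
    if not library:
        raise ValueError("empty reference library")
    if secondary is None:
        secondary = SECONDARY_FEATURES
    r2: dict[Modality, float] = {}
    for modality in (Modality.FL440, Modality.FL590, Modality.SC850, Modality.UVVIS):
        substance = designation.get(modality)
        ref = library.get((substance, modality)) if substance else None
        r2[modality] = _score_or_zero(bundle, modality, ref)
    extras = {}
    if bundle.turbidity_fnu is not None:
        extras["fnu"] = float(bundle.turbidity_fnu)
    for name, (modality, substance) in secondary.items():
        ref = library.get((substance, Modality(modality)))
        if ref is not None:
            extras[name] = _score_or_zero(bundle, Modality(modality), ref)
    return FeatureVector(sample_id=bundle.sample_id, r2_by_modality=r2,
                         extras=extras, label=bundle.label)


# ---------------------------------------------------------------------------
# Library serialization


def save_library(library: Mapping[tuple[str, Modality], ReferenceSpectrum],
                 path: str | Path) -> None:
    payload = [
        {
            "substance": ref.substance,
            "modality": ref.modality.value,
            "components": [
                {"amplitude": c.amplitude, "center_nm": c.center_nm,
                 "width_nm2": c.width_nm2}
                for c in ref.components
            ],
        }
        for ref in library.values()
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_library(path: str | Path) -> dict[tuple[str, Modality], ReferenceSpectrum]:
    payload = json.loads(Path(path).read_text())
    library: dict[tuple[str, Modality], ReferenceSpectrum] = {}
    for entry in payload:
        ref = ReferenceSpectrum(
            substance=entry["substance"],
            modality=Modality(entry["modality"]),
            components=[GaussianComponent(c["amplitude"], c["center_nm"], c["width_nm2"])
                        for c in entry["components"]],
        )
        library[(ref.substance, ref.modality)] = ref
    return library
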