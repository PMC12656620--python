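"""Spectrum data model and file I/O.

A :class:`Spectrum` is a vector of detector counts on a uniform wavelength
grid, tagged with the optical modality that produced it (UV/Vis
transmission, fluorescence under 440 nm or 590 nm excitation, or scattered
light under 850 nm excitation).  The instrument emulated throughout this
package covers 225–900 nm at 1.5 nm resolution and clips at roughly
40,000 counts; both numbers are configurable.

Spectra are exchanged as small self-describing CSV files::

    # modality=fl440
    # temperature_c=21.3
    # is_blank=0
    wavelength_nm,intensity_counts
    225.0,103.4
    ...

A :class:`MeasurementBundle` groups the four sample spectra of one water
sample with their matching pure-water blanks.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

#: Detector ceiling in counts; values at or above it are unreliable.
SATURATION_CEILING = 40_000.0

#: Instrument wavelength range and resolution.
DEFAULT_GRID_START_NM = 225.0
DEFAULT_GRID_STOP_NM = 900.0
DEFAULT_GRID_STEP_NM = 1.5


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


class ExtrapolationError(ValueError):
    """Raised when resampling would leave the source wavelength span."""


class Modality(str, enum.Enum):
    """Optical acquisition channel."""

    UVVIS = "uvvis"     #: UV/Vis transmission (deuterium–tungsten source)
    FL440 = "fl440"     #: fluorescence, 440 nm LED excitation
    FL590 = "fl590"     #: fluorescence, 590 nm LED excitation
    SC850 = "sc850"     #: scattered light, 850 nm LED excitation

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Modalities whose preprocessing requires a blank spectrum.
BLANK_REQUIRED = (Modality.UVVIS, Modality.FL440, Modality.FL590, Modality.SC850)


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling in nm."""

    start_nm: float = DEFAULT_GRID_START_NM
    stop_nm: float = DEFAULT_GRID_STOP_NM
    step_nm: float = DEFAULT_GRID_STEP_NM

    def __post_init__(self) -> None:
        if not (self.start_nm < self.stop_nm):
            raise ValueError("start_nm must be < stop_nm")
        if not (self.step_nm > 0):
            raise ValueError("step_nm must be > 0")

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    def wavelengths(self) -> np.ndarray:
        """Grid points in nm (endpoint inclusive)."""
        return self.start_nm + self.step_nm * np.arange(len(self))


@dataclass
class Spectrum:
    """Intensity counts on a wavelength grid.

    ``saturated`` is kept consistent with ``values`` on construction: it is
    set iff any value reaches the saturation ceiling.
    """

    grid: WavelengthGrid
    values: np.ndarray
    modality: Modality
    temperature_c: float | None = None
    is_blank: bool = False
    saturated: bool = False
    saturation_ceiling: float = SATURATION_CEILING
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError(
                f"values length {self.values.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite counts")
        self.modality = Modality(self.modality)
        self.saturated = bool(np.any(self.values >= self.saturation_ceiling))

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths()

    def with_values(self, values: np.ndarray, step: str | None = None) -> "Spectrum":
        """Copy with new values; appends ``step`` to the provenance trail."""
        prov = list(self.provenance) + ([step] if step else [])
        return replace(self, values=np.asarray(values, dtype=float), provenance=prov)


@dataclass
class MeasurementBundle:
    """All spectra of one water sample: four modalities plus blanks."""

    sample_id: str
    spectra: dict[Modality, Spectrum]
    blanks: dict[Modality, Spectrum]
    label: str | None = None          # ground-truth class for synthetic bundles
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CSV dialect


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum in the package CSV dialect (full float precision)."""
    path = Path(path)
    lines = [f"# modality={spectrum.modality.value}"]
    if spectrum.temperature_c is not None:
        lines.append(f"# temperature_c={spectrum.temperature_c!r}")
    lines.append(f"# is_blank={int(spectrum.is_blank)}")
    for step in spectrum.provenance:
        lines.append(f"# step={step}")
    lines.append("wavelength_nm,intensity_counts")
    for wl, v in zip(spectrum.wavelengths, spectrum.values):
        lines.append(f"{float(wl)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path, modality: Modality | None = None,
                  saturation_ceiling: float = SATURATION_CEILING) -> Spectrum:
    """Read a two-column wavelength/intensity CSV with ``#`` header lines.

    Parameters
    ----------
    modality:
        Expected modality; if given it must match the file header (when the
        header is present) and is used when the header is absent.
    """
    path = Path(path)
    header: dict[str, str] = {}
    provenance: list[str] = []
    wavelengths: list[float] = []
    values: list[float] = []
    saw_columns = False
    try:
        text = path.read_text()
    except OSError as exc:
        raise SpectrumFormatError(f"{path}: unreadable file: {exc}") from exc
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                if key.strip() == "step":
                    provenance.append(val.strip())
                else:
                    header[key.strip()] = val.strip()
            continue
        if not saw_columns:
            cols = [c.strip() for c in line.split(",")]
            if cols[:2] != ["wavelength_nm", "intensity_counts"]:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected columns 'wavelength_nm,intensity_counts', got {line!r}"
                )
            saw_columns = True
            continue
        parts = line.split(",")
        if len(parts) < 2:
            raise SpectrumFormatError(f"{path}:{lineno}: missing intensity column in {line!r}")
        try:
            wavelengths.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: non-numeric entry in {line!r}") from exc
    if not saw_columns or not wavelengths:
        raise SpectrumFormatError(f"{path}: no data rows found")
    wl = np.asarray(wavelengths)
    diffs = np.diff(wl)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0))
        raise SpectrumFormatError(
            f"{path}: wavelengths not strictly increasing at data row {bad + 2} "
            f"({wl[bad]!r} -> {wl[bad + 1]!r})"
        )
    step = float(np.median(diffs))
    if not np.allclose(diffs, step, rtol=0, atol=1e-6 * step):
        raise SpectrumFormatError(f"{path}: wavelength grid is not uniform")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), step)
    file_modality = header.get("modality")
    if modality is not None:
        modality = Modality(modality)
        if file_modality is not None and Modality(file_modality) is not modality:
            raise SpectrumFormatError(
                f"{path}: header modality {file_modality!r} != requested {modality.value!r}"
            )
    elif file_modality is not None:
        modality = Modality(file_modality)
    else:
        raise SpectrumFormatError(f"{path}: modality neither in header nor supplied")
    temp = header.get("temperature_c")
    return Spectrum(
        grid=grid,
        values=np.asarray(values),
        modality=modality,
        temperature_c=float(temp) if temp is not None else None,
        is_blank=bool(int(header.get("is_blank", "0"))),
        saturation_ceiling=saturation_ceiling,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Resampling


def resample(spectrum: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    The target grid must lie inside the source wavelength span; modality and
    metadata flags are preserved.
    """
    src = spectrum.wavelengths
    tol = 1e-9 * max(abs(src[0]), abs(src[-1]), 1.0)
    if grid.start_nm < src[0] - tol or grid.stop_nm > src[-1] + tol:
        raise ExtrapolationError(
            f"target grid {grid.start_nm}-{grid.stop_nm} nm exceeds source span "
            f"{src[0]}-{src[-1]} nm"
        )
    new_values = np.interp(grid.wavelengths(), src, spectrum.values)
    out = replace(spectrum, grid=grid, values=new_values)
    return out


# ---------------------------------------------------------------------------
# Bundle validation


@dataclass
class ValidationIssue:
    severity: str            # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def warnings(self) -> list[str]:
        return [i.message for i in self.issues if i.severity == "warning"]

    @property
    def errors(self) -> list[str]:
        return [i.message for i in self.issues if i.severity == "error"]


def validate_bundle(bundle: MeasurementBundle) -> ValidationReport:
    """Report missing blanks, grid mismatches and saturation.

    Missing blanks and grid mismatches are fatal (``ok`` is False);
    saturation is a warning only, since the downstream pipeline can still
    run on a clipped spectrum.
    """
    report = ValidationReport()
    for modality, spec in bundle.spectra.items():
        if modality in BLANK_REQUIRED:
            blank = bundle.blanks.get(modality)
            if blank is None:
                report.issues.append(ValidationIssue(
                    "error", f"{modality.value}: blank spectrum missing"))
            elif blank.grid != spec.grid:
                report.issues.append(ValidationIssue(
                    "error", f"{modality.value}: blank grid differs from sample grid"))
        if spec.saturated:
            report.issues.append(ValidationIssue(
                "warning", f"{modality.value}: sample spectrum saturated "
                           f"(>= {spec.saturation_ceiling:g} counts)"))
    for modality, blank in bundle.blanks.items():
        if blank.saturated:
            report.issues.append(ValidationIssue(
                "warning", f"{modality.value}: blank spectrum saturated"))
    return report


# ---------------------------------------------------------------------------
# Bundle manifests (JSON listing one file per modality)


def write_bundle(bundle: MeasurementBundle, directory: str | Path) -> Path:
    """Write a bundle as per-modality CSV files plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"sample_id": bundle.sample_id, "spectra": {}, "blanks": {}}
    if bundle.label is not None:
        manifest["label"] = bundle.label
    for kind, mapping in (("spectra", bundle.spectra), ("blanks", bundle.blanks)):
        for modality, spec in mapping.items():
            name = f"{bundle.sample_id}_{kind}_{modality.value}.csv"
            write_spectrum(spec, directory / name)
            manifest[kind][modality.value] = name
    manifest_path = directory / f"{bundle.sample_id}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path


def read_bundle(manifest_path: str | Path) -> MeasurementBundle:
    """Load a bundle from its JSON manifest."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    spectra = {Modality(m): read_spectrum(base / fn)
               for m, fn in manifest.get("spectra", {}).items()}
    blanks = {Modality(m): read_spectrum(base / fn)
              for m, fn in manifest.get("blanks", {}).items()}
    return MeasurementBundle(
        sample_id=manifest["sample_id"], spectra=spectra, blanks=blanks,
        label=manifest.get("label"),
    )
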