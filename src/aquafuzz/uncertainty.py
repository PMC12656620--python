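"""GUM-style measurement-uncertainty combination.

The expanded uncertainty U = k·√(Σ u_i²) of the R² conformity features sets
the fuzziness scope (the c parameter) of the classifier's membership
functions, so classes are never sharper than the measurement itself.

The instrument-specific budgets behind the default expanded uncertainties
(5.90 % of the R² scale for UV/Vis, 7.11 % for fluorescence and scattered
light) are configuration constants; only the combination rules live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .spectral_io import Modality

#: Default expanded uncertainty of the R² feature, as a fraction of the R² scale.
DEFAULT_EXPANDED_U: dict[Modality, float] = {
    Modality.UVVIS: 0.0590,
    Modality.FL440: 0.0711,
    Modality.FL590: 0.0711,
    Modality.SC850: 0.0711,
}

#: GUM convention: coverage factor 2 for ~95 % coverage.
DEFAULT_COVERAGE_FACTOR = 2.0


def combine(components: Iterable[float]) -> float:
    """Root-sum-of-squares of independent standard uncertainties."""
    total = 0.0
    for u in components:
        if u < 0:
            raise ValueError(f"standard uncertainty must be >= 0, got {u}")
        total += u * u
    return math.sqrt(total)


def expand(u_c: float, k_cov: float = DEFAULT_COVERAGE_FACTOR) -> float:
    """Expanded uncertainty U = k · u_c."""
    if u_c < 0:
        raise ValueError("combined uncertainty must be >= 0")
    if k_cov <= 0:
        raise ValueError("coverage factor must be > 0")
    return k_cov * u_c


@dataclass
class UncertaintyBudget:
    """Named standard-uncertainty components plus a coverage factor."""

    components: list[tuple[str, float]] = field(default_factory=list)
    coverage_factor: float = DEFAULT_COVERAGE_FACTOR

    @property
    def combined(self) -> float:
        return combine(u for _, u in self.components)

    @property
    def expanded(self) -> float:
        return expand(self.combined, self.coverage_factor)


def default_feature_uncertainty(modality: Modality,
                                overrides: Mapping[Modality, float] | None = None
                                ) -> float:
    """Expanded uncertainty U of the R² feature for one modality.

    Defaults to 0.0590 for UV/Vis and 0.0711 for the fluorescence and
    scattered-light channels; values may be overridden per modality via
    configuration.
    """
    modality = Modality(modality)
    table = dict(DEFAULT_EXPANDED_U)
    if overrides:
        table.update({Modality(m): float(v) for m, v in overrides.items()})
    try:
        return table[modality]
    except KeyError:  # pragma: no cover - Modality() already validates
        raise ValueError(f"no uncertainty configured for modality {modality}")
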