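"""End-to-end orchestration: preprocess → extract features → classify.

``run_training`` turns a labeled corpus of measurement bundles into a
fuzzy-classifier model file; ``run_assessment`` produces one report row per
sample with its R² features, per-class memberships, assignment, advisory
flags and accumulated warnings.  Both are deterministic for fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .fuzzy_classifier import (
    CLASS_LABELS,
    ClassificationResult,
    FuzzyClassifier,
    TrainingError,
    train,
)
from .preprocessing import (
    FilterSpec,
    PreprocessedBundle,
    TemperatureModel,
    TurbidityCalibration,
    preprocess_bundle,
)
from .reference_fitting import (
    DEFAULT_DESIGNATION,
    FeatureVector,
    ReferenceSpectrum,
    extract_features,
)
from .spectral_io import MeasurementBundle, Modality, WavelengthGrid
from .uncertainty import DEFAULT_EXPANDED_U, default_feature_uncertainty

logger = logging.getLogger("aquafuzz")

#: Expanded uncertainty of the turbidity estimate, in FNU, used when the
#: turbidity estimate serves as the fifth classifier dimension.
DEFAULT_FNU_EXPANDED_U = 0.5

#: Canonical feature order of the full classifier: the four conformity
#: features, the turbidity estimate, and the foreign-substance conformity.
FULL_FEATURE_ORDER = ("r2_440", "r2_590", "r2_850", "r2_uvvis", "fnu", "r2_440_foreign")
#: The four conformity features alone (used when no turbidity estimate exists).
R2_FEATURE_ORDER = ("r2_440", "r2_590", "r2_850", "r2_uvvis")


@dataclass
class PipelineConfig:
    """Everything the assessment pipeline needs, in one place."""

    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    temp_model: TemperatureModel = field(default_factory=TemperatureModel)
    turbidity_cal: TurbidityCalibration | None = None
    library: Mapping[tuple[str, Modality], ReferenceSpectrum] | None = None
    designation: Mapping[Modality, str] = field(
        default_factory=lambda: dict(DEFAULT_DESIGNATION))
    expanded_u_overrides: Mapping[Modality, float] | None = None
    fnu_expanded_u: float = DEFAULT_FNU_EXPANDED_U
    include_turbidity_feature: bool = True
    #: membership threshold above which a non-assigned class triggers an advisory
    advisory_threshold: float = 0.4

    def __post_init__(self) -> None:
        if self.turbidity_cal is None:
            self.turbidity_cal = TurbidityCalibration(grid=self.grid)

    @property
    def feature_order(self) -> tuple[str, ...]:
        return FULL_FEATURE_ORDER if self.include_turbidity_feature else R2_FEATURE_ORDER

    def expanded_u_by_feature(self) -> dict[str, float]:
        u = {
            "r2_440": default_feature_uncertainty(Modality.FL440, self.expanded_u_overrides),
            "r2_590": default_feature_uncertainty(Modality.FL590, self.expanded_u_overrides),
            "r2_850": default_feature_uncertainty(Modality.SC850, self.expanded_u_overrides),
            "r2_uvvis": default_feature_uncertainty(Modality.UVVIS, self.expanded_u_overrides),
        }
        if self.include_turbidity_feature:
            u["fnu"] = self.fnu_expanded_u
            u["r2_440_foreign"] = default_feature_uncertainty(
                Modality.FL440, self.expanded_u_overrides)
        return u


def compute_features(bundles: Sequence[MeasurementBundle],
                     config: PipelineConfig) -> list[FeatureVector]:
    """Preprocess and score every bundle against the reference library."""
    if config.library is None:
        raise ValueError("pipeline config carries no reference library")
    features = []
    for bundle in bundles:
        pre = preprocess_bundle(
            bundle, filter_spec=config.filter_spec, temp_model=config.temp_model,
            turbidity_cal=config.turbidity_cal)
        fv = extract_features(pre, config.library, config.designation)
        fv.extras.setdefault("fnu", 0.0)
        fv.extras["_warnings"] = pre.warnings  # type: ignore[assignment]
        features.append(fv)
        logger.debug("features %s: %s", bundle.sample_id, fv.as_dict())
    return features


def _feature_row(fv: FeatureVector, order: Sequence[str]) -> dict[str, float]:
    full = fv.as_dict()
    return {name: float(full.get(name, 0.0)) for name in order}


def run_training(bundles: Sequence[MeasurementBundle],
                 config: PipelineConfig,
                 model_path: str | Path | None = None,
                 ) -> FuzzyClassifier:
    """Learning phase: features from a labeled corpus → fuzzy classifier.

    Class membership functions are derived automatically from the feature
    distribution within each expert class; the expanded measurement
    uncertainties enter as the minimum fuzziness scope.
    """
    labeled = [b for b in bundles if b.label]
    if not labeled:
        raise TrainingError("no labeled bundles in the corpus")
    labels = [b.label for b in labeled]
    present = [lbl for lbl in CLASS_LABELS if lbl in set(labels)]
    extra = set(labels) - set(CLASS_LABELS)
    if extra:
        raise TrainingError(f"unknown class labels: {sorted(extra)}")
    if len(present) < 2:
        raise TrainingError("training requires at least 2 distinct classes")
    features = compute_features(labeled, config)
    order = config.feature_order
    clf = train(
        features=[_feature_row(fv, order) for fv in features],
        labels=labels,
        feature_order=order,
        expanded_u=config.expanded_u_by_feature(),
        class_order=present,
    )
    for cls in clf.classes:
        logger.info("class %-26s n=%d  %s", cls.label, labels.count(cls.label),
                    "  ".join(f"{n}: x0={p.x0:.3f} c=({p.c_l:.3f},{p.c_r:.3f})"
                              for n, p in zip(order, cls.dims)))
    if model_path is not None:
        from .fuzzy_classifier import save_model
        save_model(clf, model_path)
        logger.info("model written to %s", model_path)
    return clf


def run_assessment(bundles: Sequence[MeasurementBundle],
                   config: PipelineConfig,
                   clf: FuzzyClassifier) -> pd.DataFrame:
    """Working phase: one report row per sample.

    Columns: features, per-class memberships ``mu_<label>``, the assigned
    class, an advisory column listing non-assigned classes whose
    membership exceeds the advisory threshold, and stage warnings
    (saturation, temperature/turbidity validity) joined with ``;``.
    """
    features = compute_features(bundles, config)
    rows = []
    for fv in features:
        warnings = list(fv.extras.pop("_warnings", []))
        row = _feature_row(fv, clf.feature_order)
        result = clf.classify(row)
        advisories = [
            label for label, mu in result.memberships.items()
            if label != result.assigned and mu > config.advisory_threshold]
        out = {"sample_id": fv.sample_id, **row}
        out.update({f"mu_{label}": mu for label, mu in result.memberships.items()})
        out["assigned"] = result.assigned
        out["assigned_index"] = result.assigned_index
        out["tie"] = result.tie
        out["advisories"] = ";".join(advisories)
        out["warnings"] = ";".join(warnings)
        if fv.label is not None:
            out["true_label"] = fv.label
        rows.append(out)
    return pd.DataFrame(rows)


def classify_feature_table(clf: FuzzyClassifier,
                           features: Sequence[FeatureVector] | pd.DataFrame,
                           ) -> pd.DataFrame:
    """Classify pre-computed feature vectors (no spectra involved).

    Accepts either :class:`FeatureVector` objects or a DataFrame whose
    columns cover the classifier's feature order.  Used to evaluate
    externally tabulated features, e.g. published campaign results.
    """
    if isinstance(features, pd.DataFrame):
        records = features.to_dict("records")
        ids = features.get("sample_id", pd.Series(range(len(features)))).tolist()
    else:
        records = [_feature_row(fv, clf.feature_order) for fv in features]
        ids = [fv.sample_id for fv in features]
    rows = []
    for sid, rec in zip(ids, records):
        result = clf.classify({k: rec[k] for k in clf.feature_order})
        row = {"sample_id": sid}
        row.update({f"mu_{label}": mu for label, mu in result.memberships.items()})
        row["assigned"] = result.assigned
        row["assigned_index"] = result.assigned_index
        rows.append(row)
    return pd.DataFrame(rows)
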