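"""Fuzzy pattern classification with Aizerman potential membership functions.

Each class is a multidimensional fuzzy set: one one-dimensional membership
function per feature, combined by a compensatory aggregation (here the
N-fold arithmetic mean).  The one-dimensional functions follow the
Bocklisch form of the Aizerman potential function

    μ(x) = a / (1 + (1/b_s − 1) · (|x − x0| / c_s)^{d_s}),

with side s = l for x < x0 and s = r otherwise: a is the maximum
membership at the representative value x0, b the fuzziness (the membership
reached at distance c from x0), c the scope of uncertainty, and d the
slope of the flanks.

Training derives the class parameters from labeled feature vectors: x0 is
the class mean per dimension and the scopes c_l/r cover the observed
spread *plus* the expanded measurement uncertainty U of that feature, so a
class is never narrower than the measurement is trustworthy.  New samples
get a membership to every class; the highest wins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

#: Training defaults for the per-object membership functions.
DEFAULT_A = 1.0
DEFAULT_B = 0.5
DEFAULT_D = 2.0

#: The six water-assessment classes, in their canonical order.
CLASS_LABELS = (
    "blue_algae",                   # Class 1: cyanobacteria (phycocyanin marker)
    "green_algae",                  # Class 2: chlorophyll-dominated signal
    "moderate_turbidity",           # Class 3: 2-10 FNU particle load
    "high_turbidity_or_foreign",    # Class 4: >10 FNU and/or foreign substances
    "unknown_substance",            # Class 5: fluorescent foreign substance
    "no_substance",                 # Class 6: nothing detectable
)


class ModelFormatError(ValueError):
    """Classifier model file malformed or inconsistent."""


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class MembershipParams:
    """One-dimensional Aizerman membership function parameters."""

    x0: float
    a: float = DEFAULT_A
    b_l: float = DEFAULT_B
    b_r: float = DEFAULT_B
    c_l: float = 1.0
    c_r: float = 1.0
    d_l: float = DEFAULT_D
    d_r: float = DEFAULT_D

    def __post_init__(self) -> None:
        if not (0 < self.b_l <= 1 and 0 < self.b_r <= 1):
            raise ValueError("fuzziness b must be in (0, 1]")
        if self.c_l <= 0 or self.c_r <= 0:
            raise ValueError("scope c must be > 0")
        if self.d_l <= 0 or self.d_r <= 0:
            raise ValueError("slope d must be > 0")
        if self.a <= 0:
            raise ValueError("max membership a must be > 0")


def aizerman_membership(x: float, p: MembershipParams) -> float:
    """Evaluate the side-specific Aizerman potential function at x.

    μ(x0) = a exactly; μ decreases strictly with |x − x0| and stays
    positive for all finite x.  At x = x0 ± c the membership equals b·a.
    """
    if x < p.x0:
        b, c, d = p.b_l, p.c_l, p.d_l
    else:
        b, c, d = p.b_r, p.c_r, p.d_r
    return p.a / (1.0 + (1.0 / b - 1.0) * (abs(x - p.x0) / c) ** d)


def aggregate(memberships: Sequence[float]) -> float:
    """Compensatory N-fold aggregation: the arithmetic mean.

    Idempotent (all-equal inputs map to themselves) and bounded by the
    minimum and maximum of its inputs.
    """
    if len(memberships) == 0:
        raise ValueError("cannot aggregate an empty membership list")
    return float(np.mean(memberships))


@dataclass
class FuzzyClass:
    """One labeled class: a membership function per feature dimension."""

    label: str
    dims: list[MembershipParams]

    def membership(self, x: Sequence[float]) -> float:
        if len(x) != len(self.dims):
            raise ValueError(
                f"class {self.label!r} has {len(self.dims)} dims, got {len(x)} features")
        return aggregate([aizerman_membership(xi, p) for xi, p in zip(x, self.dims)])


@dataclass
class ClassificationResult:
    """Memberships to every class plus the argmax assignment."""

    memberships: dict[str, float]
    assigned: str
    tie: bool = False

    @property
    def assigned_index(self) -> int:
        """1-based index of the assigned class in the classifier order."""
        return list(self.memberships).index(self.assigned) + 1


@dataclass
class FuzzyClassifier:
    """Ordered set of fuzzy pattern classes over a common feature order."""

    classes: list[FuzzyClass]
    feature_order: list[str]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise TrainingError("a classifier needs at least 2 classes")
        for cls in self.classes:
            if len(cls.dims) != len(self.feature_order):
                raise ModelFormatError(
                    f"class {cls.label!r} has {len(cls.dims)} dims but the "
                    f"feature order has {len(self.feature_order)}")

    def classify(self, features: Mapping[str, float]) -> ClassificationResult:
        """Evaluate all class memberships and assign the maximum.

        Exact ties are broken toward the earlier class in the classifier
        order and reported via ``tie``.
        """
        missing = [f for f in self.feature_order if f not in features]
        if missing:
            raise ValueError(f"feature vector missing dimensions: {missing}")
        x = [float(features[f]) for f in self.feature_order]
        memberships = {cls.label: cls.membership(x) for cls in self.classes}
        best = max(memberships.values())
        winners = [label for label, mu in memberships.items() if mu == best]
        return ClassificationResult(
            memberships=memberships, assigned=winners[0], tie=len(winners) > 1)


def classify(clf: FuzzyClassifier, features: Mapping[str, float]) -> ClassificationResult:
    return clf.classify(features)


# ---------------------------------------------------------------------------
# Training


def train(features: Sequence[Mapping[str, float]],
          labels: Sequence[str],
          feature_order: Sequence[str],
          expanded_u: Mapping[str, float],
          class_order: Sequence[str] | None = None,
          a: float = DEFAULT_A, b: float = DEFAULT_B, d: float = DEFAULT_D,
          ) -> FuzzyClassifier:
    """Derive class membership functions from labeled feature vectors.

    Per class and dimension: x0 is the mean of the member values and the
    scopes extend from x0 to the extreme member value plus the expanded
    uncertainty U of that dimension — c_l = (x0 − min) + U and
    c_r = (max − x0) + U — so even a singleton class keeps a scope of at
    least U.  b and d use the supplied defaults on both sides.
    """
    if len(features) != len(labels):
        raise TrainingError("features and labels differ in length")
    if len(features) == 0:
        raise TrainingError("empty training set")
    for name in feature_order:
        if name not in expanded_u:
            raise TrainingError(f"no expanded uncertainty supplied for {name!r}")
    if class_order is None:
        class_order = list(dict.fromkeys(labels))
    by_label: dict[str, list[Mapping[str, float]]] = {lbl: [] for lbl in class_order}
    for fv, lbl in zip(features, labels):
        if lbl not in by_label:
            raise TrainingError(f"label {lbl!r} not in class order {list(class_order)}")
        by_label[lbl].append(fv)
    classes: list[FuzzyClass] = []
    for lbl in class_order:
        members = by_label[lbl]
        if not members:
            raise TrainingError(f"class {lbl!r} has no training objects")
        dims = []
        for name in feature_order:
            vals = np.array([float(fv[name]) for fv in members])
            x0 = float(np.mean(vals))
            u = float(expanded_u[name])
            dims.append(MembershipParams(
                x0=x0, a=a, b_l=b, b_r=b,
                c_l=(x0 - float(np.min(vals))) + u,
                c_r=(float(np.max(vals)) - x0) + u,
                d_l=d, d_r=d))
        classes.append(FuzzyClass(label=lbl, dims=dims))
    return FuzzyClassifier(classes=classes, feature_order=list(feature_order))


# ---------------------------------------------------------------------------
# Model persistence (JSON)

_PARAM_KEYS = ("x0", "a", "b_l", "b_r", "c_l", "c_r", "d_l", "d_r")


def save_model(clf: FuzzyClassifier, path: str | Path) -> None:
    payload = {
        "feature_order": clf.feature_order,
        "classes": [
            {
                "label": cls.label,
                "dims": [{k: getattr(p, k) for k in _PARAM_KEYS} for p in cls.dims],
            }
            for cls in clf.classes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> FuzzyClassifier:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON: {exc}") from exc
    try:
        feature_order = list(payload["feature_order"])
        classes = [
            FuzzyClass(
                label=entry["label"],
                dims=[MembershipParams(**{k: float(dim[k]) for k in _PARAM_KEYS})
                      for dim in entry["dims"]],
            )
            for entry in payload["classes"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: malformed model file: {exc}") from exc
    return FuzzyClassifier(classes=classes, feature_order=feature_order)
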