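"""Placental-transfer models and classification.

The endpoint is log FM, the logarithm of the fetus-to-mother blood
concentration ratio at equilibrium. Three published linear models are
evaluated on descriptor vectors:

* ``EQ1`` — drug-likeness (Lipinski flag), heteroatom count with hydrogens
  (nHet), Caco-2 permeability, steady-state volume of distribution and the
  unbound plasma fraction in percent;
* ``EQ2`` — the Takaku model on MW, topological polar surface area and the
  maximum E-state descriptor Hmax;
* ``EQ3`` — the modified Wang model on the autocorrelation descriptor
  AATSC1c and the information-content index ZMIC1, in non-normalized
  variable form.

Compounds are then binned by the Di Filippo thresholds: log FM > −0.52
crosses the placenta easily, log FM < −0.82 does not cross, anything in
between (boundaries included) is dubious.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .descriptors import DescriptorVector
from .errors import ValidationError

__all__ = [
    "ModelCoefficients", "PermeabilityPrediction", "EQ1", "EQ2", "EQ3",
    "MODELS", "CROSSING_THRESHOLD", "NON_CROSSING_THRESHOLD",
    "predict", "predict_eq1", "predict_eq2", "predict_eq3",
    "classify", "predict_all", "applicability_report",
]

CROSSING_THRESHOLD = -0.52
NON_CROSSING_THRESHOLD = -0.82


@dataclass(frozen=True)
class ModelCoefficients:
    """Intercept plus named coefficients; every name must resolve to a
    :class:`DescriptorVector` field (or synthetic table column)."""

    model_id: str
    intercept: float
    coefficients: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def evaluate(self, d: DescriptorVector) -> float:
        values = d.require(*self.descriptor_names)
        return self.intercept + sum(
            c * v for c, v in zip(self.coefficients.values(), values)
        )


EQ1 = ModelCoefficients(
    "eq1",
    intercept=0.193,
    coefficients={
        "Lipinski": 0.492,
        "nHet": 0.0410,
        "caco2": 0.268,
        "logVDss": -0.172,
        "Fu": 0.00526,
    },
    se={
        "intercept": 0.447,
        "Lipinski": 0.085,
        "nHet": 0.0141,
        "caco2": 0.103,
        "logVDss": 0.080,
        "Fu": 0.00132,
    },
)

EQ2 = ModelCoefficients(
    "eq2",
    intercept=0.0283,
    coefficients={"MW": -0.00238, "TPSA": 0.00238, "Hmax": 0.380},
)

EQ3 = ModelCoefficients(
    "eq3",
    intercept=0.100,
    coefficients={"AATSC1c": -20.84, "ZMIC1": -0.0132},
)

MODELS = {"eq1": EQ1, "eq2": EQ2, "eq3": EQ3}


def predict(coeffs: ModelCoefficients, d: DescriptorVector) -> float:
    """Evaluate a linear log FM model on one descriptor vector."""
    return coeffs.evaluate(d)


def predict_eq1(d: DescriptorVector) -> float:
    return EQ1.evaluate(d)


def predict_eq2(d: DescriptorVector) -> float:
    return EQ2.evaluate(d)


def predict_eq3(d: DescriptorVector) -> float:
    return EQ3.evaluate(d)


def classify(logfm: float,
             crossing: float = CROSSING_THRESHOLD,
             non_crossing: float = NON_CROSSING_THRESHOLD) -> str:
    """Di Filippo class of one log FM value.

    ``crossing`` above the upper threshold, ``non-crossing`` below the
    lower one, ``dubious`` in between; both boundary values are assigned to
    ``dubious`` (the outer classes are defined by strict inequalities).
    """
    if not math.isfinite(logfm):
        raise ValidationError(f"log FM must be finite, got {logfm!r}")
    if logfm > crossing:
        return "crossing"
    if logfm < non_crossing:
        return "non-crossing"
    return "dubious"


@dataclass
class PermeabilityPrediction:
    """Per-model log FM values and crossing classes for one compound."""

    compound_id: str
    logFM: dict[str, float]
    crossing_class: dict[str, str]


def predict_all(d: DescriptorVector, models: dict[str, ModelCoefficients] | None = None,
                crossing: float = CROSSING_THRESHOLD,
                non_crossing: float = NON_CROSSING_THRESHOLD) -> PermeabilityPrediction:
    models = models or MODELS
    logfm = {mid: m.evaluate(d) for mid, m in models.items()}
    cls = {mid: classify(v, crossing, non_crossing) for mid, v in logfm.items()}
    return PermeabilityPrediction(d.compound_id, logfm, cls)


def applicability_report(query: DescriptorVector,
                         reference: list[DescriptorVector],
                         descriptor_names: tuple[str, ...] | None = None) -> dict:
    """Descriptor-range applicability check against a reference set.

    For each model descriptor, flags whether the query value falls in the
    closed interval [min, max] spanned by the reference compounds, and
    reports the in-range fraction. Missing query values are reported as
    out-of-range with flag ``None`` excluded from the fraction denominator
    only when missing in the whole reference too.
    """
    if not reference:
        raise ValidationError("reference set is empty")
    names = descriptor_names or EQ1.descriptor_names
    flags: dict[str, bool] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for name in names:
        ref_vals = [v for v in (r.get(name) for r in reference) if v is not None]
        if not ref_vals:
            raise ValidationError(f"no reference values for descriptor {name!r}")
        lo, hi = min(ref_vals), max(ref_vals)
        ranges[name] = (lo, hi)
        (qv,) = query.require(name)
        flags[name] = lo <= qv <= hi
    frac = sum(flags.values()) / len(flags)
    return {"flags": flags, "ranges": ranges, "fraction_in_range": frac}
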