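"""Converted-score formulas placing every predictor on a common scale.

Raw outputs of the eleven predictors live on incompatible scales (SIFT is
small-is-damaging, FATHMM is negative-is-damaging, conservation scores are
unbounded).  The dbNSFP v2.3 conversion rules rescale each so that larger
always means more deleterious; most converted scales are confined to [0,1].
Each method also carries a default deleterious threshold on the converted
scale; a variant is called deleterious when its converted score strictly
exceeds the threshold.

Conversion rules (S_o = original score, S_c = converted score):

==================  =====================================================
identity            S_c = S_o (PhyloP, GERP++ RS, SiPhy, PolyPhen-2
                    HDIV/HVAR, LR score)
sift                S_c = 1 - S_o
lrt                 S_c = 1 - S_o * 0.5 if omega < 1, else S_o * 0.5
mutation_taster     S_c = S_o if class in {A, D}, else 1 - S_o
mutation_assessor   S_c = (S_o - (-5.545)) / (5.975 - (-5.545))
fathmm              S_c = 1 - (S_o - (-16.13)) / (10.64 - (-16.13))
radial_svm          S_c = (1 + S_o / 3.03993691875303) * 0.5 if class D,
                    else (1 - S_o / -2.00575697514507) * 0.5
==================  =====================================================
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import Dataset

__all__ = [
    "Conversion",
    "Call",
    "MethodSpec",
    "ConvertedScore",
    "ConversionError",
    "convert",
    "invert",
    "convert_dataset",
    "classify",
    "default_registry",
    "registry_from_config",
    "registry_to_config",
]

# Rescaling constants from the dbNSFP v2.3 conversion formulas.
MA_LO, MA_HI = -5.545, 5.975
FATHMM_LO, FATHMM_HI = -16.13, 10.64
RSVM_POS, RSVM_NEG = 3.03993691875303, -2.00575697514507


class Conversion(str, enum.Enum):
    IDENTITY = "identity"
    SIFT = "sift"
    LRT = "lrt"
    MUTATION_TASTER = "mutation_taster"
    MUTATION_ASSESSOR = "mutation_assessor"
    FATHMM = "fathmm"
    RADIAL_SVM = "radial_svm"


class Call(str, enum.Enum):
    DELETERIOUS = "deleterious"
    BENIGN = "benign"
    UNSCORED = "unscored"


class ConversionError(ValueError):
    """Missing/invalid auxiliary datum, or out-of-range raw in strict mode."""


@dataclass(frozen=True)
class MethodSpec:
    """A predictor: its conversion rule and default deleterious threshold.

    ``params`` holds the original-scale bounds the rule references (empty for
    rules with hard-coded constants).  ``bounded01`` says whether converted
    scores are confined to [0,1]; ``raw_range`` is the admissible original
    range used by the clamp/strict policy (None = unbounded).
    """

    name: str
    conversion: Conversion
    default_threshold: float
    bounded01: bool
    raw_range: tuple[float, float] | None = None
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bounded01 and not (0.0 <= self.default_threshold <= 1.0):
            raise ValueError(
                f"{self.name}: default threshold outside converted range [0,1]"
            )


@dataclass(frozen=True)
class ConvertedScore:
    method: str
    value: float | None
    present: bool


def _clamp(spec: MethodSpec, raw: float, strict: bool) -> float:
    if spec.raw_range is None:
        return raw
    lo, hi = spec.raw_range
    if lo <= raw <= hi:
        return raw
    if strict:
        raise ConversionError(
            f"{spec.name}: raw score {raw} outside original range [{lo}, {hi}]"
        )
    warnings.warn(
        f"{spec.name}: raw score {raw} outside [{lo}, {hi}]; clamped",
        stacklevel=3,
    )
    return min(max(raw, lo), hi)


def convert(
    spec: MethodSpec, raw: float | None, aux=None, *, strict: bool = False
) -> ConvertedScore:
    """Apply the method's conversion rule to one raw score.

    ``aux`` carries the LRT omega<1 boolean or the MutationTaster /
    RadialSVM prediction-class letter where the rule requires one.  Raw
    values outside a bounded method's original range are clamped to the
    bound (with a warning) unless ``strict``, which rejects instead.
    """
    if raw is None:
        return ConvertedScore(spec.name, None, False)
    raw = _clamp(spec, float(raw), strict)
    c = spec.conversion
    if c is Conversion.IDENTITY:
        value = raw
    elif c is Conversion.SIFT:
        value = 1.0 - raw
    elif c is Conversion.LRT:
        if not isinstance(aux, bool):
            raise ConversionError(f"{spec.name}: omega<1 flag required, got {aux!r}")
        value = 1.0 - raw * 0.5 if aux else raw * 0.5
    elif c is Conversion.MUTATION_TASTER:
        if aux not in ("A", "D", "N", "P"):
            raise ConversionError(
                f"{spec.name}: prediction class must be A/D/N/P, got {aux!r}"
            )
        value = raw if aux in ("A", "D") else 1.0 - raw
    elif c is Conversion.MUTATION_ASSESSOR:
        value = (raw - MA_LO) / (MA_HI - MA_LO)
    elif c is Conversion.FATHMM:
        value = 1.0 - (raw - FATHMM_LO) / (FATHMM_HI - FATHMM_LO)
    elif c is Conversion.RADIAL_SVM:
        if aux not in ("D", "N", "T"):
            raise ConversionError(
                f"{spec.name}: prediction class must be D or N/T, got {aux!r}"
            )
        if aux == "D":
            value = (1.0 + raw / RSVM_POS) * 0.5
        else:
            value = (1.0 - raw / RSVM_NEG) * 0.5
    else:  # pragma: no cover
        raise AssertionError(c)
    return ConvertedScore(spec.name, value, True)


def invert(spec: MethodSpec, converted: float) -> tuple[float, object]:
    """Map a converted-scale value back to (raw score, auxiliary datum).

    Right-inverse of :func:`convert`: feeding the returned pair through
    ``convert`` recovers ``converted`` exactly (up to float rounding).  Used
    by the synthetic generator, which simulates on the converted scale but
    emits raw-scale panels so the full conversion path is exercised.
    """
    c = spec.conversion
    if c is Conversion.IDENTITY:
        return converted, None
    if c is Conversion.SIFT:
        return 1.0 - converted, None
    if c is Conversion.LRT:
        # converted >= 0.5 is reachable only through the omega<1 branch
        if converted >= 0.5:
            return 2.0 * (1.0 - converted), True
        return 2.0 * converted, False
    if c is Conversion.MUTATION_TASTER:
        if converted >= 0.5:
            return converted, "D"
        return 1.0 - converted, "N"
    if c is Conversion.MUTATION_ASSESSOR:
        return MA_LO + converted * (MA_HI - MA_LO), None
    if c is Conversion.FATHMM:
        return FATHMM_LO + (1.0 - converted) * (FATHMM_HI - FATHMM_LO), None
    if c is Conversion.RADIAL_SVM:
        if converted >= 0.5:
            return (2.0 * converted - 1.0) * RSVM_POS, "D"
        return (1.0 - 2.0 * converted) * RSVM_NEG, "N"
    raise AssertionError(c)  # pragma: no cover


def convert_dataset(
    ds: Dataset, registry: tuple[MethodSpec, ...], *, strict: bool = False
) -> pd.DataFrame:
    """Elementwise conversion of a whole dataset.

    Returns a (records x methods) DataFrame of converted scores with NaN for
    absent raw scores; the row index follows record order.  Conversion
    errors are re-raised with the offending variant named.
    """
    names = [s.name for s in registry]
    scored = {m for r in ds.records for m in r.raw_scores}
    unregistered = scored - set(names)
    if unregistered:
        raise ConversionError(f"unregistered method(s): {sorted(unregistered)}")
    out = np.full((len(ds.records), len(registry)), np.nan)
    for j, spec in enumerate(registry):
        for i, rec in enumerate(ds.records):
            raw = rec.raw_scores.get(spec.name)
            if raw is None:
                continue
            try:
                cs = convert(spec, raw, rec.aux.get(spec.name), strict=strict)
            except ConversionError as e:
                raise ConversionError(f"variant {rec.variant_id!r}: {e}") from e
            out[i, j] = cs.value
    return pd.DataFrame(out, columns=names)


def classify(score: ConvertedScore, threshold: float) -> Call:
    """Deleterious iff converted value strictly exceeds the threshold.

    Ties classify as benign (thresholds are stated as strict '>'); absent
    scores are 'unscored'.
    """
    if not score.present or score.value is None:
        return Call.UNSCORED
    return Call.DELETERIOUS if score.value > threshold else Call.BENIGN


def default_registry() -> tuple[MethodSpec, ...]:
    """The shipped registry of eleven predictors (twelve score columns).

    Default deleterious thresholds are on the converted scale: conservation
    scores (PhyloP >1.6, GERP++ RS >4.4, SiPhy >12.17) pass through
    unchanged; every other method is bounded in [0,1] after conversion.
    """
    return (
        MethodSpec("PhyloP", Conversion.IDENTITY, 1.6, bounded01=False),
        MethodSpec("GERP_RS", Conversion.IDENTITY, 4.4, bounded01=False),
        MethodSpec("SiPhy", Conversion.IDENTITY, 12.17, bounded01=False),
        MethodSpec("SIFT", Conversion.SIFT, 0.95, bounded01=True,
                   raw_range=(0.0, 1.0)),
        MethodSpec("PolyPhen2_HDIV", Conversion.IDENTITY, 0.5, bounded01=True,
                   raw_range=(0.0, 1.0)),
        MethodSpec("PolyPhen2_HVAR", Conversion.IDENTITY, 0.5, bounded01=True,
                   raw_range=(0.0, 1.0)),
        MethodSpec("LRT", Conversion.LRT, 0.999, bounded01=True,
                   raw_range=(0.0, 1.0)),
        MethodSpec("MutationTaster", Conversion.MUTATION_TASTER, 0.5,
                   bounded01=True, raw_range=(0.0, 1.0)),
        MethodSpec("MutationAssessor", Conversion.MUTATION_ASSESSOR, 0.65,
                   bounded01=True, raw_range=(MA_LO, MA_HI),
                   params={"lower": MA_LO, "upper": MA_HI}),
        MethodSpec("FATHMM", Conversion.FATHMM, 0.453, bounded01=True,
                   raw_range=(FATHMM_LO, FATHMM_HI),
                   params={"lower": FATHMM_LO, "upper": FATHMM_HI}),
        MethodSpec("RadialSVM", Conversion.RADIAL_SVM, 0.5, bounded01=True,
                   params={"pos_divisor": RSVM_POS, "neg_divisor": RSVM_NEG}),
        MethodSpec("LR", Conversion.IDENTITY, 0.5, bounded01=True,
                   raw_range=(0.0, 1.0)),
    )


def registry_to_config(registry: tuple[MethodSpec, ...]) -> list[dict]:
    return [
        {
            "name": s.name,
            "conversion": s.conversion.value,
            "default_threshold": s.default_threshold,
            "bounded01": s.bounded01,
            "raw_range": list(s.raw_range) if s.raw_range else None,
            "params": dict(s.params),
        }
        for s in registry
    ]


def registry_from_config(entries: list[dict]) -> tuple[MethodSpec, ...]:
    """Build a registry from a parsed config (e.g. YAML) list of entries."""
    out = []
    for e in entries:
        out.append(
            MethodSpec(
                name=e["name"],
                conversion=Conversion(e["conversion"]),
                default_threshold=float(e["default_threshold"]),
                bounded01=bool(e["bounded01"]),
                raw_range=tuple(e["raw_range"]) if e.get("raw_range") else None,
                params=dict(e.get("params", {})),
            )
        )
    return tuple(out)
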