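"""Risk-score computation for LIBRA, MoPaRDS and pPREDICT.

Each scale is a registry of dichotomous (or banded) risk factors; a
participant's total is the sum of per-factor point contributions. MoPaRDS
and pPREDICT award one point per satisfied factor (8 and 14 possible points
respectively); LIBRA uses published weights, with age-by-sex and education
contributing banded points. Totals at or above the scale's cutoff
(LIBRA 4.2, MoPaRDS 4, pPREDICT 4) flag high risk.

Missing inputs are handled by a ``missing_policy``:

``error``
    raise :class:`MissingDataError` on the first factor with missing input;
``omit_factor`` (default)
    skip the factor and record it in ``profile.omitted`` — the published
    precedent when a cohort lacks some scale components;
``impute_absent``
    treat missing inputs as factor-absent (zero points).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .records import MALE, FEMALE, ParticipantRecord
from .registry import FactorDef, ScaleRegistry, SCALES, default_registry

MISSING_POLICIES = ("error", "omit_factor", "impute_absent")


class MissingDataError(ValueError):
    """A required scoring input is missing under the ``error`` policy."""


class UnknownScaleError(ValueError):
    pass


@dataclass
class FactorProfile:
    """Per-factor point contributions for one participant on one scale."""

    scale: str
    contributions: dict[str, float] = field(default_factory=dict)
    omitted: list[str] = field(default_factory=list)


@dataclass
class ScoreResult:
    """Scale total with its factor profile and high/low risk classification."""

    scale: str
    total: float
    profile: FactorProfile
    risk_class: str  # "high" | "low"
    cutoff_used: float


def _compare(value, op: str, cutoff) -> bool:
    if op == "ge":
        return value >= cutoff
    if op == "gt":
        return value > cutoff
    if op == "le":
        return value <= cutoff
    if op == "lt":
        return value < cutoff
    if op == "eq":
        return value == cutoff
    if op == "flag":
        return bool(value)
    raise ValueError(f"unknown comparison operator {op!r}")


def evaluate_factor(record: ParticipantRecord, factor: FactorDef) -> Optional[float]:
    """Points this factor contributes, or ``None`` if an input is missing."""
    if factor.op == "age_sex_band":
        age = getattr(record, factor.field)
        sex = getattr(record, factor.sex_field)
        if age is None or sex is None:
            return None
        for band in factor.bands:
            if band["min"] <= age < band["max"]:
                return float(band[MALE] if sex == MALE else band[FEMALE])
        return None  # outside all bands (age <= 0 rejected upstream)
    if factor.op == "band":
        value = getattr(record, factor.field)
        if value is None:
            return None
        for band in factor.bands:
            if band["min"] <= value < band["max"]:
                return float(band["points"])
        return None
    if factor.op == "any_of":
        hits, saw_value = [], False
        for term in factor.terms:
            value = getattr(record, term["field"])
            if value is None:
                continue
            saw_value = True
            hits.append(_compare(value, term["op"], term.get("cutoff")))
        if not saw_value:
            return None  # every input missing; "and/or" tolerates partial data
        return factor.points if any(hits) else 0.0
    if factor.op == "count_ge":
        values = [getattr(record, f) for f in factor.fields]
        if any(v is None for v in values):
            return None
        count = sum(bool(v) for v in values)
        return factor.points if count >= factor.cutoff else 0.0
    value = getattr(record, factor.field)
    if value is None:
        return None
    return factor.points if _compare(value, factor.op, factor.cutoff) else 0.0


def score_scale(
    record: ParticipantRecord,
    scale: str,
    missing_policy: str = "omit_factor",
    registry: Optional[dict[str, ScaleRegistry]] = None,
    cutoff: Optional[float] = None,
) -> ScoreResult:
    """Score one participant on one scale.

    Parameters
    ----------
    record
        Validated participant record.
    scale
        ``"libra"``, ``"mopards"`` or ``"ppredict"``.
    missing_policy
        One of :data:`MISSING_POLICIES`; see module docstring.
    registry
        Alternative registry mapping; defaults to the packaged registry.
    cutoff
        Override the registry's high-risk cutoff.
    """
    if scale not in SCALES:
        raise UnknownScaleError(f"unknown scale {scale!r}; expected one of {SCALES}")
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    reg = (registry or default_registry())[scale]
    profile = FactorProfile(scale=scale)
    total = 0.0
    for factor in reg.factors:
        points = evaluate_factor(record, factor)
        if points is None:
            if missing_policy == "error":
                raise MissingDataError(
                    f"{record.participant_id}: factor {factor.name!r} of {scale} "
                    f"needs {factor.input_fields()}"
                )
            if missing_policy == "omit_factor":
                profile.omitted.append(factor.name)
                continue
            points = 0.0  # impute_absent
        profile.contributions[factor.name] = points
        total += points
    used_cutoff = reg.high_risk_cutoff if cutoff is None else cutoff
    risk = "high" if total >= used_cutoff else "low"
    return ScoreResult(scale=scale, total=total, profile=profile,
                       risk_class=risk, cutoff_used=used_cutoff)


def libra_score(record: ParticipantRecord, missing_policy: str = "omit_factor",
                **kwargs) -> ScoreResult:
    """Weighted LIBRA total (9-factor registry; max 27.1 points)."""
    return score_scale(record, "libra", missing_policy, **kwargs)


def mopards_score(record: ParticipantRecord, missing_policy: str = "omit_factor",
                  **kwargs) -> ScoreResult:
    """MoPaRDS total: one point per satisfied factor, 0–8."""
    return score_scale(record, "mopards", missing_policy, **kwargs)


def ppredict_score(record: ParticipantRecord, missing_policy: str = "omit_factor",
                   **kwargs) -> ScoreResult:
    """pPREDICT total: one point per satisfied factor, 0–14."""
    return score_scale(record, "ppredict", missing_policy, **kwargs)


def libra_age_sex_points(age: float, sex: str,
                         registry: Optional[dict[str, ScaleRegistry]] = None) -> float:
    """LIBRA age-by-sex band points (risk rises with age, higher for women)."""
    if age <= 0:
        raise ValueError("age must be positive")
    if sex not in (MALE, FEMALE):
        raise ValueError(f"sex must be {MALE!r} or {FEMALE!r}")
    factor = (registry or default_registry())["libra"]["age_by_sex"]
    rec = ParticipantRecord(participant_id="_", age=age, sex=sex)
    points = evaluate_factor(rec, factor)
    assert points is not None
    return points


def vascular_burden(record: ParticipantRecord,
                    missing_policy: str = "omit_factor") -> Optional[int]:
    """Count of the five vascular comorbidity flags (CAD, stroke/TIA,
    hypercholesterolemia, hypertension, diabetes); pPREDICT awards its
    vascular point when the count is >= 2.

    Returns ``None`` when a flag is missing under ``omit_factor``.
    """
    flags = (record.coronary_artery_disease, record.ischemic_stroke_tia,
             record.hypercholesterolemia, record.hypertension, record.diabetes)
    if any(v is None for v in flags):
        if missing_policy == "error":
            raise MissingDataError(f"{record.participant_id}: vascular flags incomplete")
        if missing_policy == "omit_factor":
            return None
        flags = tuple(bool(v) for v in flags)
    return sum(bool(v) for v in flags)


def validate_for_scale(record: ParticipantRecord, scale: str,
                       registry: Optional[dict[str, ScaleRegistry]] = None) -> list[str]:
    """Names of the scale's factors whose inputs are missing on this record.

    An empty list means the record is fully scorable for that scale.
    """
    if scale not in SCALES:
        raise UnknownScaleError(f"unknown scale {scale!r}; expected one of {SCALES}")
    reg = (registry or default_registry())[scale]
    return [f.name for f in reg.factors if evaluate_factor(record, f) is None]
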