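"""Participant-level data model.

A :class:`ParticipantRecord` holds one participant's baseline demographic,
clinical and questionnaire fields in their native units; a
:class:`NeuropsychAssessment` holds the five neuropsychological test scores
for one visit. Missing values are represented as ``None`` and are always
distinguishable from zero — a participant with ``gds15=0`` answered the
questionnaire, one with ``gds15=None`` did not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

WHITE_NON_HISPANIC = "white_non_hispanic"
NONWHITE_OR_HISPANIC = "nonwhite_or_hispanic"
RACE_ETHNICITY_LEVELS = (WHITE_NON_HISPANIC, NONWHITE_OR_HISPANIC)

BASELINE = "baseline"
YEAR5 = "year5"
VISITS = (BASELINE, YEAR5)

MONTHS_PER_YEAR = 12.0


class RecordValidationError(ValueError):
    """A field value violates its documented range or enumeration."""


def symptom_months_to_years(months: float) -> float:
    """Convert a symptom-duration measurement in months to years."""
    return months / MONTHS_PER_YEAR


def _check_range(name: str, value, lo=None, hi=None) -> None:
    if value is None:
        return
    if not math.isfinite(float(value)):
        raise RecordValidationError(f"{name} must be finite, got {value!r}")
    if lo is not None and value < lo:
        raise RecordValidationError(f"{name}={value!r} below minimum {lo}")
    if hi is not None and value > hi:
        raise RecordValidationError(f"{name}={value!r} above maximum {hi}")


def _check_enum(name: str, value, levels) -> None:
    if value is not None and value not in levels:
        raise RecordValidationError(f"{name}={value!r} not one of {levels}")


@dataclass
class ParticipantRecord:
    """One participant's raw baseline fields; ``None`` marks missing data.

    Units: ``age``, ``education`` and ``disease_duration`` in years,
    ``symptom_duration`` in months, ``bmi`` in kg/m², ``orthostatic_sbp_drop``
    in mmHg (supine-to-standing systolic fall, positive = pressure drop).
    Questionnaire totals are in their native ranges (MoCA 0–30, GDS-15 0–15,
    STAI-S 20–80, ESS 0–24, RBDSQ 0–13); UPDRS entries are item or part
    totals.
    """

    participant_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    race_ethnicity: Optional[str] = None
    education: Optional[float] = None
    moca: Optional[int] = None
    bmi: Optional[float] = None
    disease_duration: Optional[float] = None
    symptom_duration: Optional[float] = None
    updrs3_total: Optional[int] = None
    updrs1_2_hallucinations: Optional[int] = None
    updrs2_12_walking: Optional[int] = None
    updrs2_13_freezing: Optional[int] = None
    bilateral_onset: Optional[bool] = None
    orthostatic_sbp_drop: Optional[float] = None
    rbdsq: Optional[int] = None
    gds15: Optional[int] = None
    stai_state: Optional[int] = None
    ess: Optional[int] = None
    pase: Optional[float] = None
    hypertension: Optional[bool] = None
    hypercholesterolemia: Optional[bool] = None
    diabetes: Optional[bool] = None
    coronary_artery_disease: Optional[bool] = None
    ischemic_stroke_tia: Optional[bool] = None

    def validate(self) -> "ParticipantRecord":
        """Raise :class:`RecordValidationError` on out-of-range fields."""
        if not self.participant_id:
            raise RecordValidationError("participant_id must be non-empty")
        if self.age is not None and self.age <= 0:
            raise RecordValidationError(f"age must be positive, got {self.age}")
        _check_enum("sex", self.sex, SEXES)
        _check_enum("race_ethnicity", self.race_ethnicity, RACE_ETHNICITY_LEVELS)
        _check_range("education", self.education, 0)
        _check_range("moca", self.moca, 0, 30)
        _check_range("bmi", self.bmi, 0)
        _check_range("disease_duration", self.disease_duration, 0)
        _check_range("symptom_duration", self.symptom_duration, 0)
        _check_range("updrs3_total", self.updrs3_total, 0)
        _check_range("updrs1_2_hallucinations", self.updrs1_2_hallucinations, 0)
        _check_range("updrs2_12_walking", self.updrs2_12_walking, 0)
        _check_range("updrs2_13_freezing", self.updrs2_13_freezing, 0)
        _check_range("rbdsq", self.rbdsq, 0, 13)
        _check_range("gds15", self.gds15, 0, 15)
        _check_range("stai_state", self.stai_state, 20, 80)
        _check_range("ess", self.ess, 0, 24)
        _check_range("pase", self.pase, 0)
        return self

    def is_missing(self, field_name: str) -> bool:
        return getattr(self, field_name) is None

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass
class NeuropsychAssessment:
    """The five-test neuropsychological battery at one visit.

    ``jlo_raw`` — Benton Judgment of Line Orientation (0–30, visuospatial);
    ``sdmt_raw`` — Symbol Digit Modalities Test (executive);
    ``semantic_fluency_raw`` — animal fluency count (language);
    ``hvlt_dr_t`` — Hopkins Verbal Learning Test delayed-recall T-score
    (memory; mean 50, SD 10);
    ``lns_scaled`` — WAIS-IV Letter-Number Sequencing scaled score
    (attention/working memory; mean 10, SD 3).
    """

    visit: str = BASELINE
    jlo_raw: Optional[float] = None
    sdmt_raw: Optional[float] = None
    semantic_fluency_raw: Optional[float] = None
    hvlt_dr_t: Optional[float] = None
    lns_scaled: Optional[float] = None

    TESTS = ("jlo", "sdmt", "semantic_fluency", "hvlt_dr", "lns")

    def validate(self) -> "NeuropsychAssessment":
        _check_enum("visit", self.visit, VISITS)
        _check_range("jlo_raw", self.jlo_raw, 0, 30)
        _check_range("sdmt_raw", self.sdmt_raw, 0)
        _check_range("semantic_fluency_raw", self.semantic_fluency_raw, 0)
        _check_range("hvlt_dr_t", self.hvlt_dr_t, 0)
        _check_range("lns_scaled", self.lns_scaled, 0)
        return self

    def is_complete(self) -> bool:
        return None not in (
            self.jlo_raw,
            self.sdmt_raw,
            self.semantic_fluency_raw,
            self.hvlt_dr_t,
            self.lns_scaled,
        )
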