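"""Composite cognitive score (CCS) and 5-year trajectory classification.

Each of the five battery tests is converted to a z-score — T-scores via
(T − 50)/10, scaled scores via (s − 10)/3, raw scores via (x − μ)/σ against
a normative stratum — and the CCS is the arithmetic mean of the available
z-scores. A participant declines when the CCS drops by at least the
threshold (default 0.5 SD, i.e. 0.5 composite z-units) from baseline to the
5-year visit; otherwise they maintain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .normative import NormativeReference, NormativeError, Stratum
from .records import NeuropsychAssessment, ParticipantRecord

DECLINE = "decline"
MAINTAIN = "maintain"

DEFAULT_DECLINE_THRESHOLD = 0.5

T_SCORE = "t_score"
SCALED_SCORE = "scaled_score"
RAW_NORMATIVE = "raw_normative"

COMPOSITE_POLICIES = ("require_all", "mean_available")


class CompositeError(ValueError):
    """CCS cannot be computed under the chosen policy."""


@dataclass
class CompositeResult:
    """Baseline and follow-up composites with the trajectory call."""

    ccs_baseline: float
    ccs_followup: float
    ccs_change: float  # followup - baseline; negative = worsening
    trajectory: str
    n_tests_baseline: int
    n_tests_followup: int


def standardize_score(kind: str, value: float,
                      reference: Optional[Stratum] = None) -> float:
    """Convert one test score to a z-score.

    T-scores have population mean 50 and SD 10; scaled scores mean 10 and
    SD 3; raw scores use the supplied normative stratum's mean/SD.
    """
    if kind == T_SCORE:
        return (value - 50.0) / 10.0
    if kind == SCALED_SCORE:
        return (value - 10.0) / 3.0
    if kind == RAW_NORMATIVE:
        if reference is None:
            raise NormativeError("raw_normative standardization needs a stratum")
        if reference.sd <= 0:
            raise NormativeError(f"stratum SD must be positive, got {reference.sd}")
        return (value - reference.mean) / reference.sd
    raise ValueError(f"unknown score kind {kind!r}")


def battery_z_scores(assessment: NeuropsychAssessment,
                     record: ParticipantRecord,
                     reference: NormativeReference) -> dict[str, Optional[float]]:
    """z-scores for the five tests; ``None`` where the score is missing."""
    def raw(test: str, value):
        if value is None:
            return None
        stratum = reference.lookup(test, record.age, record.education, record.sex)
        return standardize_score(RAW_NORMATIVE, value, stratum)

    return {
        "jlo": raw("jlo", assessment.jlo_raw),
        "sdmt": raw("sdmt", assessment.sdmt_raw),
        "semantic_fluency": raw("semantic_fluency", assessment.semantic_fluency_raw),
        "hvlt_dr": None if assessment.hvlt_dr_t is None
                   else standardize_score(T_SCORE, assessment.hvlt_dr_t),
        "lns": None if assessment.lns_scaled is None
               else standardize_score(SCALED_SCORE, assessment.lns_scaled),
    }


def compute_ccs(z_scores: Sequence[Optional[float]],
                policy: str = "require_all") -> tuple[float, int]:
    """Mean of the battery z-scores.

    Returns ``(ccs, n_tests_used)``. Under ``require_all`` every one of the
    five tests must be present; ``mean_available`` averages whatever is
    there (at least one).
    """
    if policy not in COMPOSITE_POLICIES:
        raise ValueError(f"policy must be one of {COMPOSITE_POLICIES}")
    present = [z for z in z_scores if z is not None]
    if policy == "require_all":
        if len(z_scores) != 5 or len(present) != 5:
            raise CompositeError(
                f"require_all needs all 5 test z-scores, got {len(present)} of {len(z_scores)}")
    if not present:
        raise CompositeError("no z-scores available to average")
    return sum(present) / len(present), len(present)


def classify_trajectory(ccs_baseline: float, ccs_followup: float,
                        threshold: float = DEFAULT_DECLINE_THRESHOLD) -> str:
    """Decline iff the baseline-to-follow-up drop is >= threshold (z-units).

    A drop of exactly the threshold counts as decline.
    """
    if ccs_baseline is None or ccs_followup is None:
        raise CompositeError("both visit composites are required")
    return DECLINE if (ccs_baseline - ccs_followup) >= threshold else MAINTAIN


def composite_for_participant(record: ParticipantRecord,
                              baseline: NeuropsychAssessment,
                              followup: NeuropsychAssessment,
                              reference: NormativeReference,
                              policy: str = "require_all",
                              threshold: float = DEFAULT_DECLINE_THRESHOLD,
                              ) -> CompositeResult:
    """Full pipeline for one participant: z-scores, CCS at both visits,
    change and trajectory."""
    z_bl = battery_z_scores(baseline, record, reference)
    z_fu = battery_z_scores(followup, record, reference)
    ccs_bl, n_bl = compute_ccs(list(z_bl.values()), policy)
    ccs_fu, n_fu = compute_ccs(list(z_fu.values()), policy)
    return CompositeResult(
        ccs_baseline=ccs_bl,
        ccs_followup=ccs_fu,
        ccs_change=ccs_fu - ccs_bl,
        trajectory=classify_trajectory(ccs_bl, ccs_fu, threshold),
        n_tests_baseline=n_bl,
        n_tests_followup=n_fu,
    )
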