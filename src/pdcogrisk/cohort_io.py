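"""Reading and writing cohort tables.

The interchange format is a UTF-8 CSV with a header row and one participant
per row. Canonical column names are listed in :data:`CANONICAL_COLUMNS`; a
``schema`` mapping lets cohorts with different variable names declare which
of their columns plays each canonical role. Unparseable numeric cells
become missing values with a logged warning; a missing required column or a
duplicate participant id is an error.
"""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd

from .records import (BASELINE, YEAR5, NeuropsychAssessment, ParticipantRecord,
                      RACE_ETHNICITY_LEVELS, SEXES)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """The input table does not provide a required column."""


class CohortValidationError(ValueError):
    """Structural problem with the cohort (e.g. duplicate participant ids)."""


# canonical column -> (record attribute, parser kind)
_RECORD_COLUMNS = {
    "participant_id": ("participant_id", "str"),
    "age": ("age", "float"),
    "sex": ("sex", "sex"),
    "race_ethnicity": ("race_ethnicity", "race"),
    "education_years": ("education", "float"),
    "moca": ("moca", "int"),
    "bmi": ("bmi", "float"),
    "disease_duration_years": ("disease_duration", "float"),
    "updrs3_total": ("updrs3_total", "int"),
    "updrs1_2": ("updrs1_2_hallucinations", "int"),
    "updrs2_12": ("updrs2_12_walking", "int"),
    "updrs2_13": ("updrs2_13_freezing", "int"),
    "bilateral_onset": ("bilateral_onset", "bool"),
    "orthostatic_sbp_drop": ("orthostatic_sbp_drop", "float"),
    "rbdsq": ("rbdsq", "int"),
    "gds15": ("gds15", "int"),
    "stai_state": ("stai_state", "int"),
    "ess": ("ess", "int"),
    "pase": ("pase", "float"),
    "htn": ("hypertension", "bool"),
    "hld": ("hypercholesterolemia", "bool"),
    "dm": ("diabetes", "bool"),
    "cad": ("coronary_artery_disease", "bool"),
    "stroke_tia": ("ischemic_stroke_tia", "bool"),
}

_NEUROPSYCH_COLUMNS = {
    BASELINE: {
        "jlo_raw_bl": "jlo_raw",
        "sdmt_raw_bl": "sdmt_raw",
        "sf_raw_bl": "semantic_fluency_raw",
        "hvlt_dr_t_bl": "hvlt_dr_t",
        "lns_scaled_bl": "lns_scaled",
    },
    YEAR5: {
        "jlo_raw_y5": "jlo_raw",
        "sdmt_raw_y5": "sdmt_raw",
        "sf_raw_y5": "semantic_fluency_raw",
        "hvlt_dr_t_y5": "hvlt_dr_t",
        "lns_scaled_y5": "lns_scaled",
    },
}

_OPTIONAL_COLUMNS = {"symptom_duration_months": ("symptom_duration", "float")}

CANONICAL_COLUMNS = (
    list(_RECORD_COLUMNS)
    + list(_NEUROPSYCH_COLUMNS[BASELINE])
    + list(_NEUROPSYCH_COLUMNS[YEAR5])
)

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", "0.0"}


def _parse_cell(raw, kind: str, column: str, row_id: str):
    """Parse one CSV cell; unparseable values become None with a warning."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None  # blank cell: silent missing
    if text.upper() in {"NA", "NAN", "NONE", "NULL", "."}:
        logger.warning("row %s: %s=%r treated as missing", row_id, column, text)
        return None
    try:
        if kind == "str":
            return text
        if kind == "float":
            return float(text)
        if kind == "int":
            value = float(text)
            if value != int(value):
                raise ValueError("non-integer")
            return int(value)
        if kind == "bool":
            low = text.lower()
            if low in _TRUE:
                return True
            if low in _FALSE:
                return False
            raise ValueError("not a boolean")
        if kind == "sex":
            low = text.lower()
            if low in SEXES:
                return low
            if low in {"m", "1"}:
                return "male"
            if low in {"f", "2"}:
                return "female"
            raise ValueError("not a sex category")
        if kind == "race":
            low = text.lower()
            if low in RACE_ETHNICITY_LEVELS:
                return low
            raise ValueError("not a race/ethnicity category")
    except ValueError:
        logger.warning("row %s: cannot parse %s=%r as %s; treating as missing",
                       row_id, column, text, kind)
        return None
    raise ValueError(f"unknown parser kind {kind!r}")


def read_cohort(path, schema: Optional[dict[str, str]] = None,
                ) -> list[tuple[ParticipantRecord, NeuropsychAssessment, NeuropsychAssessment]]:
    """Read a cohort CSV into (record, baseline battery, year-5 battery) tuples.

    ``schema`` maps canonical column names to the file's actual column names
    (identity for unmentioned columns). Row order and count are preserved.
    """
    schema = schema or {}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {canon: schema.get(canon, canon) for canon in CANONICAL_COLUMNS}
    missing = [canon for canon, actual in colmap.items() if actual not in df.columns]
    if missing:
        raise SchemaError(f"required column(s) missing from {path}: {missing}")
    for canon, (attr, kind) in _OPTIONAL_COLUMNS.items():
        actual = schema.get(canon, canon)
        if actual in df.columns:
            colmap[canon] = actual

    out = []
    seen_ids: set[str] = set()
    for idx, row in df.iterrows():
        pid = _parse_cell(row[colmap["participant_id"]], "str",
                          "participant_id", str(idx))
        if pid is None:
            raise CohortValidationError(f"row {idx}: empty participant_id")
        if pid in seen_ids:
            raise CohortValidationError(f"duplicate participant_id {pid!r}")
        seen_ids.add(pid)

        fields = {"participant_id": pid}
        for canon, (attr, kind) in _RECORD_COLUMNS.items():
            if attr == "participant_id":
                continue
            fields[attr] = _parse_cell(row[colmap[canon]], kind, canon, pid)
        for canon, (attr, kind) in _OPTIONAL_COLUMNS.items():
            if canon in colmap:
                fields[attr] = _parse_cell(row[colmap[canon]], kind, canon, pid)
        record = ParticipantRecord(**fields).validate()

        visits = {}
        for visit, cols in _NEUROPSYCH_COLUMNS.items():
            kwargs = {attr: _parse_cell(row[colmap[canon]], "float", canon, pid)
                      for canon, attr in cols.items()}
            visits[visit] = NeuropsychAssessment(visit=visit, **kwargs).validate()
        out.append((record, visits[BASELINE], visits[YEAR5]))
    return out


def cohort_to_frame(cohort) -> pd.DataFrame:
    """Serialize (record, baseline, year5) tuples to a canonical DataFrame."""
    rows = []
    for record, bl, y5 in cohort:
        row = {}
        for canon, (attr, _kind) in _RECORD_COLUMNS.items():
            row[canon] = getattr(record, attr)
        if record.symptom_duration is not None:
            row["symptom_duration_months"] = record.symptom_duration
        for visit, cols in _NEUROPSYCH_COLUMNS.items():
            assessment = bl if visit == BASELINE else y5
            for canon, attr in cols.items():
                row[canon] = getattr(assessment, attr)
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("bilateral_onset", "htn", "hld", "dm", "cad", "stroke_tia"):
        df[col] = df[col].map(lambda v: None if v is None else int(bool(v)))
    return df


def write_cohort(cohort, path) -> None:
    """Write tuples back to canonical CSV (round-trips with read_cohort)."""
    cohort_to_frame(cohort).to_csv(path, index=False)
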