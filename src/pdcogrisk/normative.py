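"""Normative references for raw-score neuropsychological tests.

JLO, SDMT and semantic fluency are recorded as raw scores and need an
external normative mean/SD (from testing manuals or normative studies) to
become z-scores. A :class:`NormativeReference` holds, per test, a list of
strata keyed by half-open age intervals ``[age_min, age_max)`` with optional
education-range and sex restrictions. HVLT-DR T-scores and LNS scaled scores
carry their own normative metric and need no reference here.

Real manual norms are never packaged; a clearly-labelled synthetic
single-stratum reference ships for simulation and testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

RAW_TESTS = ("jlo", "sdmt", "semantic_fluency")


class NormativeError(ValueError):
    """Missing or malformed normative stratum."""


@dataclass(frozen=True)
class Stratum:
    """One normative cell: raw-score mean and SD for a demographic slice."""

    age_min: float
    age_max: float
    mean: float
    sd: float
    education_min: Optional[float] = None
    education_max: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self):
        if self.sd <= 0:
            raise NormativeError(f"stratum SD must be positive, got {self.sd}")
        if self.age_min >= self.age_max:
            raise NormativeError("empty age interval")

    def matches(self, age: float, education: Optional[float] = None,
                sex: Optional[str] = None) -> bool:
        if not (self.age_min <= age < self.age_max):
            return False
        if self.education_min is not None and (education is None or education < self.education_min):
            return False
        if self.education_max is not None and (education is None or education >= self.education_max):
            return False
        if self.sex is not None and sex != self.sex:
            return False
        return True


class NormativeReference:
    """Per-test stratified normative tables."""

    def __init__(self, tables: dict[str, list[Stratum]]):
        unknown = set(tables) - set(RAW_TESTS)
        if unknown:
            raise NormativeError(f"unknown tests in normative reference: {sorted(unknown)}")
        self.tables = {t: list(strata) for t, strata in tables.items()}
        for test, strata in self.tables.items():
            self._check_overlap(test, strata)

    @staticmethod
    def _check_overlap(test: str, strata: list[Stratum]) -> None:
        # strata with identical education/sex restrictions must not overlap in age
        for i, a in enumerate(strata):
            for b in strata[i + 1:]:
                same_slice = (a.education_min, a.education_max, a.sex) == \
                             (b.education_min, b.education_max, b.sex)
                if same_slice and a.age_min < b.age_max and b.age_min < a.age_max:
                    raise NormativeError(f"{test}: overlapping age strata {a} / {b}")

    def lookup(self, test: str, age: float, education: Optional[float] = None,
               sex: Optional[str] = None) -> Stratum:
        """The stratum covering this participant; raises if none does."""
        if test not in self.tables:
            raise NormativeError(f"no normative table for test {test!r}")
        for stratum in self.tables[test]:
            if stratum.matches(age, education, sex):
                return stratum
        raise NormativeError(f"{test}: no stratum covers age={age}, "
                             f"education={education}, sex={sex}")

    @classmethod
    def from_dict(cls, config: dict) -> "NormativeReference":
        tables = {}
        for test, rows in config.items():
            tables[test] = [Stratum(
                age_min=float(r["age_min"]), age_max=float(r["age_max"]),
                mean=float(r["mean"]), sd=float(r["sd"]),
                education_min=r.get("education_min"),
                education_max=r.get("education_max"),
                sex=r.get("sex"),
            ) for r in rows]
        return cls(tables)

    @classmethod
    def from_yaml(cls, path: str) -> "NormativeReference":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out: dict[str, list[dict]] = {}
        for test, strata in self.tables.items():
            rows = []
            for s in strata:
                row = {"age_min": s.age_min, "age_max": s.age_max,
                       "mean": s.mean, "sd": s.sd}
                if s.education_min is not None:
                    row["education_min"] = s.education_min
                if s.education_max is not None:
                    row["education_max"] = s.education_max
                if s.sex is not None:
                    row["sex"] = s.sex
                rows.append(row)
            out[test] = rows
        return out


def synthetic_reference() -> NormativeReference:
    """The packaged synthetic single-stratum reference (simulation/tests)."""
    text = resources.files("pdcogrisk.data").joinpath("normative_synthetic.yaml").read_text()
    return NormativeReference.from_dict(yaml.safe_load(text))
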