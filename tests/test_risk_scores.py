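"""LIBRA / MoPaRDS / pPREDICT scoring: published weights, cutoffs, policies."""

import numpy as np
import pytest

from pdcogrisk import (libra_age_sex_points, libra_score, mopards_score,
                       ppredict_score, score_scale, validate_for_scale,
                       vascular_burden)
from pdcogrisk.scores import MissingDataError, UnknownScaleError

from conftest import complete_record, random_record, record_values
from oracles import brute_force_total, load_registry_yaml


# ---------------------------------------------------------------------------
# LIBRA

@pytest.mark.parametrize("age,sex,expected", [
    (60, "male", 0.0), (60, "female", 0.0),
    (65, "male", 0.4), (67, "female", 2.1),
    (72, "female", 6.2), (72, "male", 5.2),
    (77, "female", 9.2), (83, "male", 11.2),
    (87, "female", 15.3), (90, "male", 16.4), (101, "female", 17.6),
])
def test_libra_age_sex_bands(age, sex, expected):
    assert libra_age_sex_points(age, sex) == pytest.approx(expected)


def test_libra_worked_examples():
    # all factors absent
    low = libra_score(complete_record(age=60, sex="male", education=16))
    assert low.total == pytest.approx(0.0)
    assert low.risk_class == "low"
    # 72 y female with depression: 6.2 + 2.1
    dep = libra_score(complete_record(age=72, sex="female", gds15=6))
    assert dep.total == pytest.approx(8.3)
    assert dep.risk_class == "high"
    assert dep.profile.contributions["age_by_sex"] == pytest.approx(6.2)
    assert dep.profile.contributions["depression"] == pytest.approx(2.1)
    # 64 y male, low education, obese, hypertensive: 2.7 + 1.6 + 1.6
    multi = libra_score(complete_record(age=64, sex="male", education=6.0,
                                        bmi=31.0, hypertension=True))
    assert multi.total == pytest.approx(5.9)
    assert multi.risk_class == "high"


def test_libra_education_bands():
    assert libra_score(complete_record(education=13)).total == 0.0
    assert libra_score(complete_record(education=12)).total == pytest.approx(1.4)
    assert libra_score(complete_record(education=8)).total == pytest.approx(1.4)
    assert libra_score(complete_record(education=7)).total == pytest.approx(2.7)


def test_libra_cutoff_is_4_2():
    result = libra_score(complete_record(age=72, sex="female"))  # 6.2 points
    assert result.cutoff_used == pytest.approx(4.2)
    assert result.risk_class == "high"
    assert libra_score(complete_record(age=67, sex="female", bmi=31)).total \
        == pytest.approx(3.7)  # 2.1 + 1.6 < 4.2 -> low
    assert libra_score(complete_record(age=67, sex="female", bmi=31)).risk_class == "low"


# ---------------------------------------------------------------------------
# MoPaRDS / pPREDICT

def test_mopards_worked_examples():
    # male sex is itself a factor, so the zero profile is female
    assert mopards_score(complete_record(sex="female")).total == 0
    allpos = complete_record(
        age=75, sex="male", moca=22, orthostatic_sbp_drop=15.0,
        bilateral_onset=True, updrs2_12_walking=2, rbdsq=8,
        updrs1_2_hallucinations=1)
    result = mopards_score(allpos)
    assert result.total == 8
    assert result.risk_class == "high"
    three = mopards_score(complete_record(age=71, sex="male", moca=24))
    assert three.total == 3
    assert three.risk_class == "low"


def test_ppredict_worked_examples():
    assert ppredict_score(complete_record(sex="female")).total == 0
    allpos = complete_record(
        age=70, sex="male", race_ethnicity="nonwhite_or_hispanic",
        education=10, moca=24, disease_duration=6.0, rbdsq=6,
        updrs3_total=40, gds15=9, stai_state=60, ess=12, bmi=28,
        pase=50.0, hypertension=True, diabetes=True)
    result = ppredict_score(allpos)
    assert result.total == 14
    assert result.risk_class == "high"
    four = ppredict_score(complete_record(age=66, sex="male", ess=12,
                                          updrs3_total=35))
    assert four.total == 4
    assert four.risk_class == "high"


@pytest.mark.parametrize("flags,count,indicator", [
    ({}, 0, 0),
    ({"hypertension": True, "diabetes": True}, 2, 1),
    ({"hypertension": True, "hypercholesterolemia": True, "diabetes": True,
      "coronary_artery_disease": True, "ischemic_stroke_tia": True}, 5, 1),
])
def test_vascular_burden_and_indicator(flags, count, indicator):
    record = complete_record(**flags)
    assert vascular_burden(record) == count
    contribution = ppredict_score(record).profile.contributions["vascular_risk"]
    assert contribution == indicator


# every dichotomous factor exactly at its printed cutoff scores per the
# printed inequality symbol: (field override, scale, factor, at-cutoff point,
# just-inside-no-point override)
BOUNDARY_TABLE = [
    ({"rbdsq": 5}, "ppredict", "rbd", 1, {"rbdsq": 4}),          # >= 5
    ({"rbdsq": 5}, "mopards", "rbd", 0, None),                   # > 5: 5 scores 0
    ({"rbdsq": 6}, "mopards", "rbd", 1, {"rbdsq": 5}),
    ({"age": 65}, "ppredict", "older_age", 1, {"age": 64.9}),    # >= 65
    ({"age": 70}, "mopards", "older_age", 1, {"age": 69.9}),     # >= 70
    ({"moca": 26}, "mopards", "cognitive_impairment", 0, None),  # < 26
    ({"moca": 25}, "mopards", "cognitive_impairment", 1, {"moca": 26}),
    ({"moca": 25}, "ppredict", "lower_moca", 1, {"moca": 26}),
    ({"gds15": 5}, "ppredict", "depression", 0, None),           # >= 8
    ({"gds15": 8}, "ppredict", "depression", 1, {"gds15": 7}),
    ({"stai_state": 54}, "ppredict", "anxiety", 1, {"stai_state": 53}),
    ({"ess": 11}, "ppredict", "excessive_daytime_sleepiness", 1, {"ess": 10}),
    ({"bmi": 25.0}, "ppredict", "obesity", 1, {"bmi": 24.9}),    # >= 25
    ({"pase": 90.0}, "ppredict", "low_physical_activity", 1, {"pase": 90.1}),  # <= 90
    ({"education": 12.0}, "ppredict", "lower_education", 1, {"education": 12.5}),
    ({"disease_duration": 5.0}, "ppredict", "longer_disease_duration", 1,
     {"disease_duration": 4.9}),
    ({"updrs3_total": 32}, "ppredict", "moderate_severe_motor", 1,
     {"updrs3_total": 31}),
    ({"orthostatic_sbp_drop": 10.0}, "mopards", "orthostatic_hypotension", 0, None),  # > 10
    ({"orthostatic_sbp_drop": 10.1}, "mopards", "orthostatic_hypotension", 1, None),
    ({"updrs2_12_walking": 1}, "mopards", "falls_freezing", 0, None),  # 2.12 > 1
    ({"updrs2_12_walking": 2}, "mopards", "falls_freezing", 1, None),
    ({"updrs2_13_freezing": 1}, "mopards", "falls_freezing", 1,
     {"updrs2_13_freezing": 0}),                                  # 2.13 > 0
    ({"updrs1_2_hallucinations": 1}, "mopards", "hallucinations", 1,
     {"updrs1_2_hallucinations": 0}),
]


@pytest.mark.parametrize("override,scale,factor,expected,inside", BOUNDARY_TABLE)
def test_threshold_boundaries_match_printed_inequalities(override, scale,
                                                         factor, expected,
                                                         inside):
    result = score_scale(complete_record(**override), scale)
    assert result.profile.contributions[factor] == expected
    if inside is not None:
        other = score_scale(complete_record(**inside), scale)
        assert other.profile.contributions[factor] == 1 - expected


def test_libra_pase_direction_awards_inactivity():
    # points go to the inactive participant (PASE <= 90), consistent with
    # the pPREDICT cell and the activity-cutoff rationale
    inactive = libra_score(complete_record(pase=90.0))
    active = libra_score(complete_record(pase=90.1))
    assert inactive.profile.contributions["physical_inactivity"] == pytest.approx(1.1)
    assert active.profile.contributions["physical_inactivity"] == 0.0


# ---------------------------------------------------------------------------
# bounds, monotonicity, conservation, missing policies

def test_score_bounds_match_registry(registry):
    assert registry["mopards"].max_total() == 8
    assert registry["ppredict"].max_total() == 14
    # 17.6 + 2.7 + 2.1 + 1.6 + 1.1 + 1.6 + 1.4 + 1.3 + 1.0
    assert registry["libra"].max_total() == pytest.approx(30.4)


def test_monotone_in_any_single_factor():
    base = complete_record()
    bumps = dict(age=75.0, sex="male", education=5.0, moca=20, bmi=33.0,
                 disease_duration=8.0, updrs3_total=40, rbdsq=9, gds15=10,
                 stai_state=60, ess=14, pase=30.0, hypertension=True,
                 diabetes=True, updrs1_2_hallucinations=2,
                 updrs2_13_freezing=1, bilateral_onset=True,
                 orthostatic_sbp_drop=20.0,
                 race_ethnicity="nonwhite_or_hispanic")
    for scale in ("libra", "mopards", "ppredict"):
        base_total = score_scale(base, scale).total
        for field, value in bumps.items():
            bumped = complete_record(**{field: value})
            assert score_scale(bumped, scale).total >= base_total - 1e-12, \
                (scale, field)


def test_totals_conserve_contributions(registry):
    rng = np.random.default_rng(5)
    for _ in range(100):
        rec = random_record(rng)
        for scale in ("libra", "mopards", "ppredict"):
            res = score_scale(rec, scale)
            assert res.total == pytest.approx(sum(res.profile.contributions.values()))
            assert 0 <= res.total <= registry[scale].max_total() + 1e-9
            if scale != "libra":
                assert all(c in (0.0, 1.0)
                           for c in res.profile.contributions.values())


def test_brute_force_oracle_equivalence(registry_path):
    raw = load_registry_yaml(registry_path)
    rng = np.random.default_rng(17)
    for i in range(1000):
        rec = random_record(rng, missing_rate=0.1 if i % 2 else 0.0)
        values = record_values(rec)
        for scale in ("libra", "mopards", "ppredict"):
            expected = brute_force_total(raw, scale, values)
            got = score_scale(rec, scale, missing_policy="omit_factor").total
            assert got == pytest.approx(expected), (scale, values)


def test_missing_policies():
    rec = complete_record(pase=None)
    with pytest.raises(MissingDataError):
        ppredict_score(rec, missing_policy="error")
    omitted = ppredict_score(rec, missing_policy="omit_factor")
    assert omitted.profile.omitted == ["low_physical_activity"]
    assert "low_physical_activity" not in omitted.profile.contributions
    imputed = ppredict_score(rec, missing_policy="impute_absent")
    assert imputed.profile.contributions["low_physical_activity"] == 0.0
    assert not imputed.profile.omitted


def test_validate_for_scale(registry):
    assert validate_for_scale(complete_record(), "ppredict") == []
    assert validate_for_scale(complete_record(pase=None), "ppredict") \
        == ["low_physical_activity"]
    # PASE is not a MoPaRDS input
    assert validate_for_scale(complete_record(pase=None), "mopards") == []
    with pytest.raises(UnknownScaleError):
        validate_for_scale(complete_record(), "caide")
    # returned names always belong to the scale's own registry
    rec = complete_record(pase=None, moca=None, rbdsq=None, hypertension=None)
    for scale in ("libra", "mopards", "ppredict"):
        missing = validate_for_scale(rec, scale)
        assert set(missing) <= set(registry[scale].factor_names())
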