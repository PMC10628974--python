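import numpy as np
import pytest

from pdcogrisk import (NormativeReference, ParticipantRecord, SimulationConfig,
                       default_registry, generate_cohort, synthetic_reference)
from pdcogrisk.registry import SCALES


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def registry_path():
    from importlib import resources
    with resources.as_file(
            resources.files("pdcogrisk.data").joinpath("registry.yaml")) as p:
        yield str(p)


@pytest.fixture(scope="session")
def reference() -> NormativeReference:
    return synthetic_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-participant synthetic cohort shared across evaluation tests."""
    return generate_cohort(SimulationConfig(n=40, seed=11))


def complete_record(**overrides) -> ParticipantRecord:
    """A fully-populated low-risk participant; override fields per test."""
    base = dict(
        participant_id="P001", age=60.0, sex="male",
        race_ethnicity="white_non_hispanic", education=16.0, moca=28,
        bmi=24.0, disease_duration=1.0, symptom_duration=12.0,
        updrs3_total=15, updrs1_2_hallucinations=0, updrs2_12_walking=0,
        updrs2_13_freezing=0, bilateral_onset=False,
        orthostatic_sbp_drop=2.0, rbdsq=2, gds15=1, stai_state=30, ess=4,
        pase=200.0, hypertension=False, hypercholesterolemia=False,
        diabetes=False, coronary_artery_disease=False,
        ischemic_stroke_tia=False,
    )
    base.update(overrides)
    return ParticipantRecord(**base).validate()


def random_record(rng: np.random.Generator, missing_rate: float = 0.0
                  ) -> ParticipantRecord:
    """Random record spanning the full field ranges, optionally with holes."""
    rec = ParticipantRecord(
        participant_id=f"R{rng.integers(1e9)}",
        age=float(rng.uniform(35, 95)),
        sex=str(rng.choice(["male", "female"])),
        race_ethnicity=str(rng.choice(["white_non_hispanic", "nonwhite_or_hispanic"])),
        education=float(rng.uniform(0, 24)),
        moca=int(rng.integers(0, 31)),
        bmi=float(rng.uniform(16, 45)),
        disease_duration=float(rng.uniform(0, 20)),
        updrs3_total=int(rng.integers(0, 80)),
        updrs1_2_hallucinations=int(rng.integers(0, 4)),
        updrs2_12_walking=int(rng.integers(0, 4)),
        updrs2_13_freezing=int(rng.integers(0, 4)),
        bilateral_onset=bool(rng.random() < 0.5),
        orthostatic_sbp_drop=float(rng.uniform(-10, 30)),
        rbdsq=int(rng.integers(0, 14)),
        gds15=int(rng.integers(0, 16)),
        stai_state=int(rng.integers(20, 81)),
        ess=int(rng.integers(0, 25)),
        pase=float(rng.uniform(0, 400)),
        hypertension=bool(rng.random() < 0.4),
        hypercholesterolemia=bool(rng.random() < 0.4),
        diabetes=bool(rng.random() < 0.2),
        coronary_artery_disease=bool(rng.random() < 0.15),
        ischemic_stroke_tia=bool(rng.random() < 0.1),
    )
    if missing_rate > 0:
        for name in ParticipantRecord.field_names():
            if name != "participant_id" and rng.random() < missing_rate:
                setattr(rec, name, None)
    return rec


def record_values(rec: ParticipantRecord) -> dict:
    """Field dict for the brute-force oracle (its own access path)."""
    return {name: getattr(rec, name) for name in ParticipantRecord.field_names()}
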