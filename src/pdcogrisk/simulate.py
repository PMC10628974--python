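"""Synthetic PPMI-like cohort generation.

The generator emulates a de novo Parkinson's disease cohort: marginal
distributions of the baseline variables follow the published cohort table
(age 60.8 ± 9.8 y, 66.1% male, ESS 5.7 ± 3.2, ...), cognitive decline over
five years is planted through a latent logistic propensity over a small set
of risk factors, and the five neuropsychological tests are emitted as raw
scores by inverting the packaged synthetic normative reference so the full
raw → z → CCS path is exercised downstream.

Continuous variables use moment-matched truncated normals: the underlying
location/scale are solved numerically so the *truncated* distribution has
the configured mean and SD (naive truncation at hard floors such as ESS ≥ 0
would otherwise inflate the mean). Symptom duration is log-normal with
matched mean/SD, reflecting its strong right skew. Decline is planted at
the latent level — a logistic model over standardized risk factors — rather
than by thresholding any score, so the generator does not trivially encode
any of the three scorers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from typing import Optional

import numpy as np
import yaml
from scipy import optimize, stats
from scipy.special import expit

from .normative import NormativeReference, synthetic_reference
from .records import (FEMALE, MALE, NONWHITE_OR_HISPANIC, WHITE_NON_HISPANIC,
                      BASELINE, YEAR5, NeuropsychAssessment, ParticipantRecord)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# moment-matched truncated normal

@lru_cache(maxsize=256)
def _match_truncnorm(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Underlying (loc, scale) whose [lo, hi]-truncation has the target moments."""
    if not (lo < mean < hi):
        raise SimulationError(f"target mean {mean} outside truncation bounds [{lo}, {hi}]")
    if sd <= 0:
        raise SimulationError("target sd must be positive")

    def moments(params):
        loc, log_scale = params
        scale = math.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success or max(abs(r) for r in sol.fun) > 1e-6:
        raise SimulationError(
            f"cannot match truncated normal to mean={mean}, sd={sd} on [{lo}, {hi}]")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def truncated_normal_ppf(u: np.ndarray, mean: float, sd: float,
                         lo: float, hi: float) -> np.ndarray:
    """Quantile function of the moment-matched truncated normal."""
    loc, scale = _match_truncnorm(mean, sd, lo, hi)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def expected_auc_binormal(effect_size: float) -> float:
    """Closed-form binormal AUC, Φ(δ/√2), for unit-variance score
    distributions separated by ``effect_size`` z-units. Used as an
    independent oracle when validating the empirical AUC on simulated
    scores."""
    if not math.isfinite(effect_size):
        raise ValueError("effect_size must be finite")
    return float(stats.norm.cdf(effect_size / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# configuration

#: (mean, sd, lower, upper, integer?) for each truncated-normal variable
_DEFAULT_MARGINALS: dict[str, tuple[float, float, float, float, bool]] = {
    "age": (60.8, 9.8, 30.0, 95.0, False),
    "education": (15.7, 2.9, 0.0, 30.0, False),
    "moca": (27.0, 2.3, 0.0, 30.0, True),
    "bmi": (27.1, 4.5, 15.0, 60.0, False),
    "updrs3_total": (20.0, 8.5, 0.0, 108.0, True),
    "rbdsq": (3.1, 2.5, 0.0, 13.0, True),
    "pase": (178.7, 105.4, 0.0, 600.0, False),
    "gds15": (5.2, 1.5, 0.0, 15.0, True),
    "stai_state": (47.2, 5.4, 20.0, 80.0, True),
    "ess": (5.7, 3.2, 0.0, 24.0, True),
    # supine-to-standing systolic drop; not in the cohort table, chosen so
    # roughly one in six participants crosses the >10 mmHg threshold
    "orthostatic_sbp_drop": (2.0, 8.0, -30.0, 60.0, False),
}

_DEFAULT_BINARY = {
    "male": 0.661,
    "nonwhite_hispanic": 0.085,
    "hallucinations": 0.05,     # UPDRS 1.2 > 0
    "freezing": 0.07,           # UPDRS 2.13 > 0
    "bilateral_onset": 0.15,
    "hypertension": 0.35,
    "hypercholesterolemia": 0.35,
    "diabetes": 0.08,
    "coronary_artery_disease": 0.06,
    "ischemic_stroke_tia": 0.03,
}

#: log-odds of decline per SD of the continuous factors (or per level of the
#: binary ones). The strongest loadings mirror the factors reported to
#: separate decliners from maintainers (older age, daytime sleepiness, motor
#: severity, RBD symptoms, male sex, hallucinations); smaller loadings are
#: spread across the remaining risk-relevant variables — negative where a
#: LOWER value marks risk (MoCA, education, PASE) — so discrimination arises
#: from many weak associations rather than a few strong ones, as in real
#: cohorts.
_DEFAULT_EFFECTS = {
    "age": 0.7,
    "ess": 0.7,
    "updrs3_total": 0.5,
    "rbdsq": 0.5,
    "male": 0.5,
    "hallucinations": 0.9,
    "moca": -0.35,
    "education": -0.2,
    "gds15": 0.2,
    "stai_state": 0.2,
    "bmi": 0.25,
    "pase": -0.3,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the published cohort."""

    n: int = 307
    seed: int = 0
    marginals: dict = dc_field(default_factory=lambda: dict(_DEFAULT_MARGINALS))
    binary_probs: dict = dc_field(default_factory=lambda: dict(_DEFAULT_BINARY))
    #: Gaussian-copula correlations between continuous variables; empty
    #: (independence) by default since the source table reports no covariances.
    correlations: dict = dc_field(default_factory=dict)
    effect_logodds: dict = dc_field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    base_decline_rate: float = 44.0 / 307.0
    decline_shift: float = 0.8      # z-units removed from decliners' year-5 CCS
    noise_sd: float = 0.15          # SD of test-retest noise on the CCS change
    symptom_duration_mean: float = 61.7   # months
    symptom_duration_sd: float = 56.7
    ccs_mean: float = 0.13
    ccs_latent_sd: float = 0.556    # latent cognition SD; with per-test scatter
    test_scatter_sd: float = 0.5    # this yields measured CCS SD ~ 0.6
    updrs2_12_probs: tuple = (0.70, 0.26, 0.04)   # P(item = 0, 1, 2)

    def validate(self) -> "SimulationConfig":
        if self.n < 2:
            raise SimulationError("n must be at least 2")
        for name, p in self.binary_probs.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"binary probability {name}={p} outside [0, 1]")
        if not 0.0 <= self.base_decline_rate <= 1.0:
            raise SimulationError("base_decline_rate must lie in [0, 1]")
        if self.noise_sd < 0 or self.test_scatter_sd < 0:
            raise SimulationError("noise SDs must be non-negative")
        for name, spec in self.marginals.items():
            mean, sd, lo, hi = spec[:4]
            if not (lo < mean < hi):
                raise SimulationError(f"{name}: mean {mean} outside bounds [{lo}, {hi}]")
        return self

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "SimulationConfig":
        """Load a config YAML (any subset of fields) over the defaults."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in {**raw, **overrides}.items():
            if not hasattr(cfg, key):
                raise SimulationError(f"unknown config field {key!r}")
            if key == "marginals":
                merged = dict(_DEFAULT_MARGINALS)
                for name, spec in value.items():
                    merged[name] = tuple(spec)
                value = merged
            elif key in ("binary_probs", "effect_logodds"):
                value = {**getattr(cfg, key), **value}
            setattr(cfg, key, value)
        return cfg.validate()


@dataclass
class GeneratedCohort:
    """Generator output: participant tuples plus the planted decline labels."""

    participants: list
    planted_decline: np.ndarray
    propensity: np.ndarray
    config: SimulationConfig

    def to_frame(self):
        from .cohort_io import cohort_to_frame
        return cohort_to_frame(self.participants)


# ---------------------------------------------------------------------------
# generation

def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) == target on this cohort."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    return float(optimize.brentq(lambda b: expit(b + eta).mean() - target, -30, 30))


def generate_cohort(config: Optional[SimulationConfig] = None,
                    reference: Optional[NormativeReference] = None,
                    ) -> GeneratedCohort:
    """Draw a synthetic cohort; bit-reproducible for a fixed config/seed."""
    cfg = (config or SimulationConfig()).validate()
    ref = reference or synthetic_reference()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    # --- continuous marginals through a Gaussian copula --------------------
    names = list(cfg.marginals)
    p = len(names)
    corr = np.eye(p)
    for (a, b), rho in cfg.correlations.items():
        if a in names and b in names:
            i, j = names.index(a), names.index(b)
            corr[i, j] = corr[j, i] = rho
    chol = np.linalg.cholesky(corr)
    z_latent = rng.standard_normal((n, p)) @ chol.T
    u = stats.norm.cdf(z_latent)
    cont: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        mean, sd, lo, hi, is_int = cfg.marginals[name]
        x = truncated_normal_ppf(u[:, j], mean, sd, lo, hi)
        if is_int:
            x = np.clip(np.rint(x), lo, hi)
        cont[name] = x

    # --- binary and categorical fields --------------------------------------
    bern = {name: rng.random(n) < prob for name, prob in cfg.binary_probs.items()}
    updrs2_12 = rng.choice(len(cfg.updrs2_12_probs), size=n, p=cfg.updrs2_12_probs)
    updrs1_2 = bern["hallucinations"].astype(int)
    updrs2_13 = bern["freezing"].astype(int)

    # --- disease duration (log-normal months) -------------------------------
    mu, sigma = _lognormal_params(cfg.symptom_duration_mean, cfg.symptom_duration_sd)
    symptom_months = rng.lognormal(mu, sigma, size=n)
    disease_years = symptom_months / 12.0

    # --- planted decline propensity -----------------------------------------
    eta = np.zeros(n)
    for name, beta in cfg.effect_logodds.items():
        if beta == 0:
            continue
        if name in cont:
            mean, sd = cfg.marginals[name][:2]
            eta += beta * (cont[name] - mean) / sd
        elif name in bern:
            prob = cfg.binary_probs[name]
            eta += beta * (bern[name].astype(float) - prob)
        else:
            raise SimulationError(f"effect_logodds names unknown factor {name!r}")
    b0 = _solve_intercept(eta, cfg.base_decline_rate)
    propensity = expit(b0 + eta) if np.isfinite(b0) else np.full(n, float(b0 > 0))
    decline = rng.random(n) < propensity

    # --- cognition: latent baseline, planted follow-up drop ------------------
    g = rng.normal(cfg.ccs_mean, cfg.ccs_latent_sd, size=n)
    z_bl = g[:, None] + rng.normal(0.0, cfg.test_scatter_sd, size=(n, 5))
    # per-test retest noise scaled so the CCS-level change noise has sd noise_sd
    retest = rng.normal(0.0, cfg.noise_sd * math.sqrt(5.0), size=(n, 5))
    z_y5 = z_bl - cfg.decline_shift * decline[:, None] + retest

    def raw_battery(z: np.ndarray, i: int, visit: str,
                    age: float, education: float, sex: str) -> NeuropsychAssessment:
        jlo = ref.lookup("jlo", age, education, sex)
        sdmt = ref.lookup("sdmt", age, education, sex)
        sf = ref.lookup("semantic_fluency", age, education, sex)
        return NeuropsychAssessment(
            visit=visit,
            jlo_raw=float(np.clip(np.rint(jlo.mean + jlo.sd * z[i, 0]), 0, 30)),
            sdmt_raw=float(max(0.0, np.rint(sdmt.mean + sdmt.sd * z[i, 1]))),
            semantic_fluency_raw=float(max(0.0, np.rint(sf.mean + sf.sd * z[i, 2]))),
            hvlt_dr_t=float(50.0 + 10.0 * z[i, 3]),
            lns_scaled=float(10.0 + 3.0 * z[i, 4]),
        )

    participants = []
    for i in range(n):
        sex = MALE if bern["male"][i] else FEMALE
        record = ParticipantRecord(
            participant_id=f"SYN{i:05d}",
            age=float(cont["age"][i]),
            sex=sex,
            race_ethnicity=NONWHITE_OR_HISPANIC if bern["nonwhite_hispanic"][i]
                           else WHITE_NON_HISPANIC,
            education=float(cont["education"][i]),
            moca=int(cont["moca"][i]),
            bmi=float(cont["bmi"][i]),
            disease_duration=float(disease_years[i]),
            symptom_duration=float(symptom_months[i]),
            updrs3_total=int(cont["updrs3_total"][i]),
            updrs1_2_hallucinations=int(updrs1_2[i]),
            updrs2_12_walking=int(updrs2_12[i]),
            updrs2_13_freezing=int(updrs2_13[i]),
            bilateral_onset=bool(bern["bilateral_onset"][i]),
            orthostatic_sbp_drop=float(cont["orthostatic_sbp_drop"][i]),
            rbdsq=int(cont["rbdsq"][i]),
            gds15=int(cont["gds15"][i]),
            stai_state=int(cont["stai_state"][i]),
            ess=int(cont["ess"][i]),
            pase=float(cont["pase"][i]),
            hypertension=bool(bern["hypertension"][i]),
            hypercholesterolemia=bool(bern["hypercholesterolemia"][i]),
            diabetes=bool(bern["diabetes"][i]),
            coronary_artery_disease=bool(bern["coronary_artery_disease"][i]),
            ischemic_stroke_tia=bool(bern["ischemic_stroke_tia"][i]),
        ).validate()
        baseline = raw_battery(z_bl, i, BASELINE, record.age, record.education, sex)
        year5 = raw_battery(z_y5, i, YEAR5, record.age, record.education, sex)
        participants.append((record, baseline, year5))

    return GeneratedCohort(participants=participants,
                           planted_decline=decline,
                           propensity=propensity,
                           config=cfg)
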