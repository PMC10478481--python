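"""Synthetic two-wave cohort generator and NCEP-ATPIII MetS classifier.

The real input to the analysis is a large two-wave population cohort (the
Lifelines study in the northern Netherlands) in which metabolic syndrome
(MetS) status is observed at a baseline wave (T1) and a follow-up wave (T4)
roughly four years later, together with sex, years of education and four
categorical modifiable factors (smoking, alcohol use, diet quality, health
literacy).  That dataset is access-restricted, so this module generates a
structurally equivalent cohort with a fully known ground-truth model:

* baseline MetS status follows a logistic model in age, sex, education and
  the modifiable factors;
* between the two waves each participant follows a time-homogeneous
  two-state Markov process with a constant personal incidence hazard
  ``lambda = exp(eta_inc)`` and recovery hazard ``mu = exp(eta_rec)``, so the
  transition probabilities over the follow-up gap are exact closed forms
  rather than a discretized approximation.

Because the generating hazards are known analytically, estimator recovery
can be tested against truth rather than against another estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import MEDIATOR_CATEGORIES, MEDIATORS, Stratum

# ---------------------------------------------------------------------------
# NCEP-ATPIII classification
# ---------------------------------------------------------------------------

WAIST_THRESHOLD_CM = {"male": 102.0, "female": 88.0}
HDL_THRESHOLD_MMOL_L = {"male": 1.0, "female": 1.3}
SBP_THRESHOLD = 130.0
DBP_THRESHOLD = 85.0
TRIGLYCERIDE_THRESHOLD_MMOL_L = 1.7
GLUCOSE_THRESHOLD_MMOL_L = 5.6


@dataclass
class MetSComponents:
    """The five measured components entering the NCEP-ATPIII definition.

    Concentrations are in mmol/L, pressures in mmHg, waist in cm.  The
    medication booleans capture pharmacological control of a component,
    which counts as meeting the criterion regardless of the measured value.
    """

    waist_cm: float
    sbp_mmHg: float
    dbp_mmHg: float
    triglycerides_mmol_l: float
    hdl_mmol_l: float
    glucose_mmol_l: float
    bp_medication: bool = False
    lipid_medication: bool = False
    triglyceride_medication: bool = False
    glucose_medication: bool = False
    t2d_diagnosis: bool = False

    def validate(self) -> None:
        for name in (
            "waist_cm",
            "sbp_mmHg",
            "dbp_mmHg",
            "triglycerides_mmol_l",
            "hdl_mmol_l",
            "glucose_mmol_l",
        ):
            value = getattr(self, name)
            if value is None or not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a finite positive number, got {value!r}")


def criterion_indicators(components: MetSComponents, sex: str) -> tuple[bool, bool, bool, bool, bool]:
    """The five NCEP-ATPIII criterion indicators, in definition order:
    abdominal obesity, elevated blood pressure, elevated triglycerides,
    low HDL cholesterol, elevated fasting glucose."""
    if sex not in WAIST_THRESHOLD_CM:
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    components.validate()
    c = components
    return (
        c.waist_cm >= WAIST_THRESHOLD_CM[sex],
        c.sbp_mmHg >= SBP_THRESHOLD or c.dbp_mmHg >= DBP_THRESHOLD or c.bp_medication,
        c.triglycerides_mmol_l >= TRIGLYCERIDE_THRESHOLD_MMOL_L or c.triglyceride_medication,
        c.hdl_mmol_l < HDL_THRESHOLD_MMOL_L[sex] or c.lipid_medication,
        c.glucose_mmol_l >= GLUCOSE_THRESHOLD_MMOL_L or c.t2d_diagnosis or c.glucose_medication,
    )


def classify_mets(components: MetSComponents, sex: str) -> bool:
    """MetS is present when at least three of the five criteria are met."""
    return sum(criterion_indicators(components, sex)) >= 3


# ---------------------------------------------------------------------------
# Ground-truth hazard / prevalence models
# ---------------------------------------------------------------------------


@dataclass
class LinearModel:
    """A linear predictor on the log-hazard (transitions) or log-odds
    (baseline prevalence) scale.

    The age term is ``age_slope * (age - 18)`` unless ``age_steps`` is given,
    in which case age contributes a piecewise-constant offset looked up from
    ``(edges, values)`` — used to generate cohorts whose true hazards are
    constant within each estimation age group.

    Mediator coefficients are keyed ``factor -> category -> coefficient``;
    omitted categories (typically the reference) contribute zero.
    """

    intercept: float
    age_slope: float = 0.0
    sex_male: float = 0.0
    edu_low: float = 0.0
    mediators: dict = field(default_factory=dict)
    age_steps: Optional[tuple[tuple[float, ...], tuple[float, ...]]] = None

    def age_term(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if self.age_steps is None:
            return self.age_slope * (age - 18.0)
        edges, values = self.age_steps
        idx = np.clip(np.searchsorted(edges, age, side="right") - 1, 0, len(values) - 1)
        return np.asarray(values, dtype=float)[idx]

    def linear_predictor(self, df: pd.DataFrame, age_col: str) -> np.ndarray:
        eta = self.intercept + self.age_term(df[age_col].to_numpy())
        eta = eta + self.sex_male * (df["sex"] == "male").to_numpy(dtype=float)
        eta = eta + self.edu_low * (df["edu_years"] == 10).to_numpy(dtype=float)
        for factor, coefs in self.mediators.items():
            col = df[factor]
            for category, coef in coefs.items():
                eta = eta + coef * (col == category).to_numpy(dtype=float)
        return eta


def _table2_distributions() -> dict:
    """Observed distribution of the modifiable factors by education level.

    Percentages as published for the n = 93,249 estimation sample; each
    column is renormalized to sum to one (the published high-education
    alcohol column sums to 111.8%, beyond rounding error, so renormalization
    is applied uniformly and the raw values are kept here verbatim)."""
    raw = {
        "smoking": {
            "low": {"never": 37.5, "former": 38.9, "current": 23.7},
            "high": {"never": 63.4, "former": 24.8, "current": 11.8},
        },
        "health_literacy": {
            "low": {"low": 32.4, "high": 67.6},
            "high": {"low": 8.5, "high": 91.5},
        },
        "alcohol": {
            "low": {"none": 23.3, "moderate": 40.9, "problematic": 35.8},
            "high": {"none": 11.8, "moderate": 59.6, "problematic": 40.4},
        },
        "diet": {
            "low": {"healthy": 8.5, "moderate": 80.3, "unhealthy": 11.3},
            "high": {"healthy": 13.0, "moderate": 81.6, "unhealthy": 5.4},
        },
    }
    out: dict = {}
    for factor, by_edu in raw.items():
        out[factor] = {}
        for edu, cats in by_edu.items():
            total = sum(cats.values())
            out[factor][edu] = {
                cat: round(v / total, 12)
                for cat, v in cats.items()
            }
    return out


def default_mediator_distributions() -> dict:
    return _table2_distributions()


def default_baseline_model() -> LinearModel:
    # Tuned so that mean baseline prevalence over uniform ages 18-61 is
    # roughly 14% (the at-risk split of the estimation sample) and rises
    # steeply with age.
    return LinearModel(
        intercept=-3.9,
        age_slope=0.062,
        sex_male=0.30,
        edu_low=0.25,
        mediators={
            "smoking": {"former": 0.15, "current": 0.35},
            "alcohol": {"moderate": -0.05, "problematic": 0.15},
            "diet": {"moderate": 0.15, "unhealthy": 0.35},
            "health_literacy": {"low": 0.20},
        },
    )


def default_incidence_model() -> LinearModel:
    # Incidence hazard rising with age, higher for men, the low educated and
    # adverse behaviours; ~0.01/yr for a favourable 40-year-old profile.
    return LinearModel(
        intercept=-5.3,
        age_slope=0.030,
        sex_male=0.25,
        edu_low=0.20,
        mediators={
            "smoking": {"former": 0.10, "current": 0.30},
            "alcohol": {"moderate": -0.05, "problematic": 0.15},
            "diet": {"moderate": 0.10, "unhealthy": 0.25},
            "health_literacy": {"low": 0.15},
        },
    )


def default_recovery_model() -> LinearModel:
    # Recovery hazard declining with age and lower for disadvantaged groups;
    # ~0.15/yr at age 40.
    return LinearModel(
        intercept=-1.45,
        age_slope=-0.020,
        sex_male=-0.15,
        edu_low=-0.15,
        mediators={
            "smoking": {"former": -0.10, "current": -0.25},
            "alcohol": {"moderate": 0.05, "problematic": -0.10},
            "diet": {"moderate": -0.10, "unhealthy": -0.20},
            "health_literacy": {"low": -0.10},
        },
    )


@dataclass
class GeneratorConfig:
    """Full specification of the synthetic-cohort generating process."""

    n_participants: int = 93_249
    seed: int = 0
    female_fraction: float = 0.589
    low_education_fraction: float = 0.5
    mediator_distributions: dict = field(default_factory=default_mediator_distributions)
    baseline_model: LinearModel = field(default_factory=default_baseline_model)
    incidence_model: LinearModel = field(default_factory=default_incidence_model)
    recovery_model: LinearModel = field(default_factory=default_recovery_model)
    followup_years_mean: float = 4.0
    followup_years_sd: float = 1.0
    followup_years_min: float = 1.0
    followup_years_max: float = 8.0
    age_min: float = 18.0
    age_max: float = 61.0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must be in [0,1]")
        for factor in MEDIATORS:
            if factor not in self.mediator_distributions:
                raise ValueError(f"missing mediator distribution for {factor!r}")
            for edu in ("low", "high"):
                dist = self.mediator_distributions[factor][edu]
                cats = MEDIATOR_CATEGORIES[factor]
                if set(dist) != set(cats):
                    raise ValueError(
                        f"{factor}/{edu}: categories {sorted(dist)} != {sorted(cats)}"
                    )
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"{factor}/{edu}: probabilities sum to {total}, not 1"
                    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "id",
    "sex",
    "edu_years",
    "age_t1",
    "age_t4",
    "mets_t1",
    "mets_t4",
    "smoking",
    "alcohol",
    "diet",
    "health_literacy",
]


def two_state_transition_probabilities(
    lam: np.ndarray, mu: np.ndarray, dt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact transition probabilities of the two-state Markov process.

    Returns ``(p01, p11)``: the probability of being in the MetS state at the
    end of an interval of length ``dt`` given a healthy (``p01``) or MetS
    (``p11``) start, for constant hazards ``lam`` (incidence) and ``mu``
    (recovery).  The stationary weight is ``lam/(lam+mu)``; both
    probabilities relax toward it at rate ``lam+mu``."""
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    dt = np.asarray(dt, dtype=float)
    total = lam + mu
    decay = np.exp(-total * dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(total > 0, lam / np.where(total > 0, total, 1.0), 0.0)
    p01 = pi * (1.0 - decay)
    p11 = pi + (1.0 - pi) * decay
    # total == 0: frozen process
    p01 = np.where(total > 0, p01, 0.0)
    p11 = np.where(total > 0, p11, 1.0)
    return p01, p11


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a complete two-wave cohort table.

    Deterministic for a given ``config.seed``.  Columns follow
    ``COHORT_COLUMNS``; ``mets_t1``/``mets_t4`` are 0/1 integers."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    edu_years = np.where(rng.random(n) < config.low_education_fraction, 10, 16)
    age_t1 = rng.uniform(config.age_min, config.age_max, size=n)

    gap = rng.normal(config.followup_years_mean, config.followup_years_sd, size=n)
    gap = np.clip(gap, config.followup_years_min, config.followup_years_max)
    age_t4 = age_t1 + gap

    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "sex": sex,
            "edu_years": edu_years.astype(np.int64),
            "age_t1": age_t1,
            "age_t4": age_t4,
        }
    )

    # Mediators drawn per education level from the configured categorical
    # distributions.
    for factor in MEDIATORS:
        cats = list(MEDIATOR_CATEGORIES[factor])
        col = np.empty(n, dtype=object)
        for edu, years in (("low", 10), ("high", 16)):
            mask = df["edu_years"].to_numpy() == years
            probs = np.array(
                [config.mediator_distributions[factor][edu][c] for c in cats]
            )
            probs = probs / probs.sum()
            col[mask] = rng.choice(cats, size=int(mask.sum()), p=probs)
        df[factor] = col

    # Baseline state from the logistic prevalence model.
    eta0 = config.baseline_model.linear_predictor(df, "age_t1")
    p0 = 1.0 / (1.0 + np.exp(-eta0))
    df["mets_t1"] = (rng.random(n) < p0).astype(np.int64)

    # Follow-up state from the exact two-state solution with constant
    # per-person hazards evaluated at the baseline age.
    lam = np.exp(config.incidence_model.linear_predictor(df, "age_t1"))
    mu = np.exp(config.recovery_model.linear_predictor(df, "age_t1"))
    p01, p11 = two_state_transition_probabilities(lam, mu, gap)
    p_mets_t4 = np.where(df["mets_t1"].to_numpy() == 1, p11, p01)
    df["mets_t4"] = (rng.random(n) < p_mets_t4).astype(np.int64)

    return df[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# Component-level realism (optional)
# ---------------------------------------------------------------------------

# (mean, sd) of plausible adult values for each continuous component, used to
# draw measurement vectors consistent with a target classification.
_COMPONENT_SCALES = {
    "waist_cm": (95.0, 12.0),
    "sbp_mmHg": (125.0, 15.0),
    "dbp_mmHg": (78.0, 10.0),
    "triglycerides_mmol_l": (1.4, 0.6),
    "hdl_mmol_l": (1.4, 0.35),
    "glucose_mmol_l": (5.2, 0.7),
}


def generate_components(target_mets: bool, sex: str, rng: np.random.Generator) -> MetSComponents:
    """Draw a component vector whose classification equals ``target_mets``.

    Draws noisy measurements, then rejection-samples (with a deterministic
    fallback adjustment) until the NCEP-ATPIII classification matches."""
    for _ in range(200):
        values = {}
        for name, (mean, sd) in _COMPONENT_SCALES.items():
            v = rng.normal(mean, sd)
            values[name] = max(v, 0.05 * mean)
        comp = MetSComponents(**values)
        if classify_mets(comp, sex) == target_mets:
            return comp
    # Deterministic fallback: force a vector clearly on the requested side.
    if target_mets:
        return MetSComponents(
            waist_cm=WAIST_THRESHOLD_CM[sex] + 10.0,
            sbp_mmHg=145.0,
            dbp_mmHg=92.0,
            triglycerides_mmol_l=2.2,
            hdl_mmol_l=HDL_THRESHOLD_MMOL_L[sex] - 0.2,
            glucose_mmol_l=6.2,
        )
    return MetSComponents(
        waist_cm=WAIST_THRESHOLD_CM[sex] - 15.0,
        sbp_mmHg=112.0,
        dbp_mmHg=72.0,
        triglycerides_mmol_l=1.0,
        hdl_mmol_l=HDL_THRESHOLD_MMOL_L[sex] + 0.4,
        glucose_mmol_l=4.8,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} missing columns: {missing}")
    for col in ("mets_t1", "mets_t4"):
        df[col] = df[col].astype(np.int64)
    bad = df["age_t4"] <= df["age_t1"]
    if bad.any():
        raise ValueError(
            f"cohort CSV {path}: {int(bad.sum())} rows violate age_t4 > age_t1"
        )
    return df


def _model_to_dict(model: LinearModel) -> dict:
    d = {
        "intercept": model.intercept,
        "age_slope": model.age_slope,
        "sex_male": model.sex_male,
        "edu_low": model.edu_low,
        "mediators": model.mediators,
    }
    if model.age_steps is not None:
        d["age_steps"] = {
            "edges": list(model.age_steps[0]),
            "values": list(model.age_steps[1]),
        }
    return d


def _model_from_dict(d: dict) -> LinearModel:
    age_steps = None
    if "age_steps" in d and d["age_steps"] is not None:
        age_steps = (
            tuple(d["age_steps"]["edges"]),
            tuple(d["age_steps"]["values"]),
        )
    return LinearModel(
        intercept=float(d["intercept"]),
        age_slope=float(d.get("age_slope", 0.0)),
        sex_male=float(d.get("sex_male", 0.0)),
        edu_low=float(d.get("edu_low", 0.0)),
        mediators=d.get("mediators", {}) or {},
        age_steps=age_steps,
    )


def config_to_yaml(config: GeneratorConfig) -> str:
    d = {
        "n_participants": config.n_participants,
        "seed": config.seed,
        "female_fraction": config.female_fraction,
        "low_education_fraction": config.low_education_fraction,
        "mediator_distributions": config.mediator_distributions,
        "baseline_model": _model_to_dict(config.baseline_model),
        "incidence_model": _model_to_dict(config.incidence_model),
        "recovery_model": _model_to_dict(config.recovery_model),
        "followup_years_mean": config.followup_years_mean,
        "followup_years_sd": config.followup_years_sd,
        "followup_years_min": config.followup_years_min,
        "followup_years_max": config.followup_years_max,
        "age_min": config.age_min,
        "age_max": config.age_max,
    }
    return yaml.safe_dump(d, sort_keys=False)


def config_from_yaml(text: str) -> GeneratorConfig:
    d = yaml.safe_load(text)
    kwargs = dict(d)
    for key in ("baseline_model", "incidence_model", "recovery_model"):
        if key in kwargs:
            kwargs[key] = _model_from_dict(kwargs[key])
    config = GeneratorConfig(**kwargs)
    config.validate()
    return config
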