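"""Shared domain types for the MetS life-course microsimulation.

The model distinguishes four population strata (sex x educational level) and
two health states (free of metabolic syndrome / having metabolic syndrome).
Transition rates between the states are age-dependent hazards, estimated per
5-year age group and later smoothed into continuous-age curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

AGE_MIN = 18.0
AGE_MAX = 65.0
SPAN_YEARS = AGE_MAX - AGE_MIN  # 47 years of simulated life course

SEXES = ("female", "male")
EDUCATIONS = ("low", "high")

# Education coded in years of schooling: the minimal labour-market starting
# qualification versus a university degree.
EDUCATION_YEARS = {"low": 10, "high": 16}

# Half-open 5-year age bins on [18, 65).  47 is not divisible by 5; the
# remainder forms the first, two-year bin.
AGE_BIN_EDGES = (18.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0, 65.0)

HEALTHY = 0
METS = 1

MEDIATORS = ("smoking", "alcohol", "diet", "health_literacy")

MEDIATOR_CATEGORIES = {
    "smoking": ("never", "former", "current"),
    "alcohol": ("none", "moderate", "problematic"),
    "diet": ("healthy", "moderate", "unhealthy"),
    "health_literacy": ("high", "low"),
}


def age_bins() -> list[tuple[float, float]]:
    """The ten half-open [lo, hi) age groups used for rate estimation."""
    return [
        (AGE_BIN_EDGES[i], AGE_BIN_EDGES[i + 1])
        for i in range(len(AGE_BIN_EDGES) - 1)
    ]


def bin_midpoint(age_lo: float, age_hi: float) -> float:
    return 0.5 * (age_lo + age_hi)


def bin_of_age(age: float) -> tuple[float, float]:
    """Return the [lo, hi) bin containing ``age``; the last bin is closed above."""
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}]")
    for lo, hi in age_bins():
        if lo <= age < hi:
            return lo, hi
    return AGE_BIN_EDGES[-2], AGE_BIN_EDGES[-1]


@dataclass(frozen=True)
class Stratum:
    """One of the four sex-by-education population groups."""

    sex: str
    education: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.education not in EDUCATIONS:
            raise ValueError(
                f"education must be one of {EDUCATIONS}, got {self.education!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.education}"


def all_strata() -> list[Stratum]:
    return [Stratum(sex, edu) for sex in SEXES for edu in EDUCATIONS]


@dataclass
class AgeGroupRate:
    """An annualized transition hazard for one stratum, kind and age group.

    ``flag`` records estimation caveats: ``"corrected"`` marks a degenerate
    cell (no or only transitions) whose probability received an Agresti-style
    +0.5 continuity correction before annualization.
    """

    stratum: Stratum
    kind: str  # "incidence" | "recovery"
    age_lo: float
    age_hi: float
    rate_per_year: float
    se: float
    n_at_risk: Optional[int] = None
    flag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("incidence", "recovery"):
            raise ValueError(f"kind must be incidence or recovery, got {self.kind!r}")
        if not (AGE_MIN <= self.age_lo < self.age_hi <= AGE_MAX):
            raise ValueError(
                f"invalid age bin [{self.age_lo}, {self.age_hi}) for {self.stratum}"
            )
        if self.rate_per_year < 0:
            raise ValueError(f"rate_per_year must be nonnegative, got {self.rate_per_year}")
        if self.se < 0:
            raise ValueError(f"se must be nonnegative, got {self.se}")

    @property
    def midpoint(self) -> float:
        return bin_midpoint(self.age_lo, self.age_hi)


@dataclass
class PrevalenceAt18:
    """Probability of already having MetS on entry into the simulation."""

    stratum: Stratum
    probability: float
    se: float
    flag: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability must be in [0,1], got {self.probability}")
        if self.se < 0:
            raise ValueError(f"se must be nonnegative, got {self.se}")


@dataclass
class IntervalProbability:
    """Interval transition probability for one age-group cell, before
    conversion to an annual hazard."""

    stratum: Stratum
    kind: str
    age_lo: float
    age_hi: float
    probability: float
    se: float
    mean_followup: float
    n_at_risk: int
    flag: Optional[str] = None

    @property
    def midpoint(self) -> float:
        return bin_midpoint(self.age_lo, self.age_hi)
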