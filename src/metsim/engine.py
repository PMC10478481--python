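"""Continuous-time two-state microsimulation engine.

Each simulated individual starts at age 18 in the MetS state with the
stratum's entry prevalence, then alternates between the healthy and MetS
states under age-dependent incidence and recovery hazards until age 65.
Mortality is not modelled; every life course spans exactly 47 years.

Event times are drawn by thinning (Lewis-Shedler rejection): candidate
events arrive as a homogeneous Poisson process at an upper bound of the
current state's hazard over the remaining age range, and each candidate is
accepted with probability hazard(candidate age) / bound.  The bound is the
running maximum of the curve on a 0.1-year grid times a 1.001 safety factor,
so acceptance is exact for the smooth curve families used here.

Every individual owns a counter-based random stream (Philox keyed by the
master seed, stratum and individual index), so results are reproducible and
independent of cohort size or simulation order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AGE_MAX, AGE_MIN, HEALTHY, METS, Stratum, all_strata
from .curves import RateCurve, evaluate

_GRID_STEP = 0.1
_SAFETY = 1.001


class CurveSampler:
    """Precomputed hazard evaluations and remaining-range upper bounds.

    ``bound(age)`` returns an upper bound of the hazard on [age, 65]
    (suffix maximum over the evaluation grid with a safety factor).
    ``bound_override`` forces a fixed bound — used for common-random-number
    couplings where two scenarios must share their candidate streams."""

    def __init__(self, curve: RateCurve, bound_override: Optional[float] = None):
        self.curve = curve
        self._grid = np.arange(AGE_MIN, AGE_MAX + _GRID_STEP / 2, _GRID_STEP)
        values = np.asarray(evaluate(curve, np.clip(self._grid, AGE_MIN, AGE_MAX)))
        suffix = np.maximum.accumulate(values[::-1])[::-1] * _SAFETY
        self._suffix_max = suffix.tolist()  # python floats: faster scalar lookup
        self._last_idx = len(self._suffix_max) - 1
        self._override = bound_override
        if bound_override is not None and bound_override < values.max():
            raise ValueError(
                f"bound_override {bound_override} below curve maximum {values.max():.6g}"
            )
        # Scalar fast path for the simulation inner loop.
        if curve.form == "poly4":
            c0, c1, c2, c3, c4 = (float(p) for p in curve.params)

            def hazard(age: float) -> float:
                h = c0 + age * (c1 + age * (c2 + age * (c3 + age * c4)))
                return h if h > 0.0 else 0.0

        else:
            L, k, a0 = (float(p) for p in curve.params)

            def hazard(age: float) -> float:
                x = k * (age - a0)
                if x < -500.0:
                    x = -500.0
                elif x > 500.0:
                    x = 500.0
                return L / (1.0 + math.exp(-x))

        self.hazard = hazard

    def bound(self, age: float) -> float:
        if self._override is not None:
            return self._override
        idx = int((age - AGE_MIN) * 10.0)
        if idx < 0:
            idx = 0
        elif idx > self._last_idx:
            idx = self._last_idx
        return self._suffix_max[idx]


@dataclass
class LifeCourse:
    """One simulated trajectory: the initial state at 18 and the ages of the
    subsequent state switches.  States strictly alternate, so the switch ages
    determine the full episode sequence."""

    id: int
    stratum: Stratum
    first_state: int
    transition_ages: tuple = ()

    def __post_init__(self) -> None:
        ages = self.transition_ages
        if any(not (AGE_MIN < a < AGE_MAX) for a in ages):
            raise ValueError("transition ages must lie strictly inside (18, 65)")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("transition ages must be strictly increasing")

    @property
    def episodes(self) -> list[tuple[int, float]]:
        """Ordered (state, start_age) pairs; episodes are half-open
        [start, next_start), the last ending at 65."""
        states = [self.first_state]
        starts = [AGE_MIN]
        for a in self.transition_ages:
            states.append(1 - states[-1])
            starts.append(a)
        return list(zip(states, starts))

    def episode_spans(self) -> list[tuple[int, float, float]]:
        eps = self.episodes
        out = []
        for i, (state, start) in enumerate(eps):
            end = eps[i + 1][1] if i + 1 < len(eps) else AGE_MAX
            out.append((state, start, end))
        return out

    def state_at(self, age: float) -> int:
        if not (AGE_MIN <= age < AGE_MAX):
            raise ValueError(f"age {age} outside [18, 65)")
        state = self.first_state
        for a in self.transition_ages:
            if a <= age:
                state = 1 - state
            else:
                break
        return state

    def mets_occupancy(self) -> float:
        """Total years spent in the MetS state over [18, 65]."""
        return sum(
            end - start for state, start, end in self.episode_spans() if state == METS
        )

    def ever_mets(self) -> bool:
        return self.first_state == METS or len(self.transition_ages) > 0

    def first_onset_age(self) -> Optional[float]:
        """Age of the first healthy->MetS switch; None if the individual
        started with MetS or never developed it."""
        if self.first_state == METS:
            return None
        if not self.transition_ages:
            return None
        return self.transition_ages[0]


def simulate_individual(
    ident: int,
    stratum: Stratum,
    incidence: CurveSampler,
    recovery: CurveSampler,
    init_prob: float,
    rng: np.random.Generator,
) -> LifeCourse:
    """Simulate one life course by thinning.

    The candidate clock runs at the current state's remaining-range hazard
    bound; a candidate at age t is accepted as a transition with probability
    hazard(t)/bound.  A zero bound means no further event is possible."""
    return _simulate_one(ident, stratum, incidence, recovery, init_prob, rng)


@dataclass
class SimulationSpec:
    """Inputs of one microsimulation run."""

    curves: dict  # {(stratum_label, kind): RateCurve}
    init_probs: dict  # {stratum_label: probability of MetS at 18}
    n_per_group: int
    seed: int

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        for stratum in all_strata():
            for kind in ("incidence", "recovery"):
                if (stratum.label, kind) not in self.curves:
                    raise ValueError(f"missing curve for {stratum.label} {kind}")
            if stratum.label not in self.init_probs:
                raise ValueError(f"missing init_prob for {stratum.label}")


def _philox_rng(seed: int, stream: int) -> np.random.Generator:
    # 128-bit Philox key partitioned as (seed | stream); streams are
    # independent for distinct (seed, stream) pairs.
    key = (int(seed) << 64) + int(stream)
    return np.random.Generator(np.random.Philox(key=key))


def simulate_stratum(
    stratum: Stratum,
    incidence_curve: RateCurve,
    recovery_curve: RateCurve,
    init_prob: float,
    n: int,
    seed: int,
    stratum_index: Optional[int] = None,
    id_offset: int = 0,
    bound_override: Optional[float] = None,
) -> list[LifeCourse]:
    """Simulate ``n`` life courses for one stratum.

    Individual ``i`` uses the Philox stream ``stratum_index * 2^40 + i`` under
    the master ``seed``, so trajectories do not depend on ``n`` or on which
    other strata are simulated."""
    if stratum_index is None:
        stratum_index = all_strata().index(stratum)
    inc = CurveSampler(incidence_curve, bound_override)
    rec = CurveSampler(recovery_curve, bound_override)
    out = []
    for i in range(n):
        rng = _philox_rng(seed, (stratum_index << 40) + i)
        lc = _simulate_one(id_offset + i, stratum, inc, rec, init_prob, rng)
        out.append(lc)
    return out


def _simulate_one(
    ident: int,
    stratum: Stratum,
    incidence: CurveSampler,
    recovery: CurveSampler,
    init_prob: float,
    rng: np.random.Generator,
) -> LifeCourse:
    u = rng.random
    first_state = METS if u() < init_prob else HEALTHY
    state = first_state
    age = AGE_MIN
    transitions: list[float] = []
    log = math.log
    samplers = (incidence, recovery)  # indexed by current state
    while True:
        sampler = samplers[state]
        bound = sampler.bound(age)
        if bound <= 0.0:
            break
        age = age - log(1.0 - u()) / bound
        if age >= AGE_MAX:
            break
        h = sampler.hazard(age)
        if h > bound:
            raise RuntimeError(
                f"hazard {h:.6g} exceeds bound {bound:.6g} at age {age:.3f}; "
                "bound computation is inconsistent with the curve"
            )
        if u() * bound < h:
            transitions.append(age)
            state = 1 - state
    return LifeCourse(ident, stratum, first_state, tuple(transitions))


def simulate_cohort(spec: SimulationSpec) -> list[LifeCourse]:
    """Simulate ``n_per_group`` life courses for each of the four strata."""
    spec.validate()
    out: list[LifeCourse] = []
    for idx, stratum in enumerate(all_strata()):
        out.extend(
            simulate_stratum(
                stratum,
                spec.curves[(stratum.label, "incidence")],
                spec.curves[(stratum.label, "recovery")],
                spec.init_probs[stratum.label],
                spec.n_per_group,
                spec.seed,
                stratum_index=idx,
                id_offset=idx * spec.n_per_group,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def life_courses_to_frame(lcs: Sequence[LifeCourse]) -> pd.DataFrame:
    """Long-format episode table: id, sex, edu, state, start_age, end_age."""
    rows = []
    for lc in lcs:
        for state, start, end in lc.episode_spans():
            rows.append(
                {
                    "id": lc.id,
                    "sex": lc.stratum.sex,
                    "edu": lc.stratum.education,
                    "state": "mets" if state == METS else "healthy",
                    "start_age": start,
                    "end_age": end,
                }
            )
    return pd.DataFrame(rows)


def write_life_courses_csv(lcs: Sequence[LifeCourse], path) -> None:
    life_courses_to_frame(lcs).to_csv(path, index=False)


def read_life_courses_csv(path) -> list[LifeCourse]:
    df = pd.read_csv(path)
    out = []
    for ident, group in df.groupby("id", sort=True):
        group = group.sort_values("start_age")
        stratum = Stratum(group["sex"].iloc[0], group["edu"].iloc[0])
        first_state = METS if group["state"].iloc[0] == "mets" else HEALTHY
        transitions = tuple(group["start_age"].to_numpy()[1:])
        out.append(LifeCourse(int(ident), stratum, first_state, transitions))
    return out


def life_courses_to_json(lcs: Sequence[LifeCourse]) -> str:
    doc = [
        {
            "id": lc.id,
            "sex": lc.stratum.sex,
            "edu": lc.stratum.education,
            "first_state": "mets" if lc.first_state == METS else "healthy",
            "transition_ages": list(lc.transition_ages),
        }
        for lc in lcs
    ]
    return json.dumps(doc)


def life_courses_from_json(text: str) -> list[LifeCourse]:
    doc = json.loads(text)
    return [
        LifeCourse(
            d["id"],
            Stratum(d["sex"], d["edu"]),
            METS if d["first_state"] == "mets" else HEALTHY,
            tuple(d["transition_ages"]),
        )
        for d in doc
    ]
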