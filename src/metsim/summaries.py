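"""Life-course summary measures and the short-episode sensitivity transform.

Three measures characterize each stratum's simulated cohort:

* life-course prevalence — the proportion who *ever* occupy the MetS state
  between 18 and 65 (including those entering at 18 with MetS);
* mean age of onset — the mean age of the first healthy-to-MetS transition,
  excluding individuals who entered the simulation with MetS and those who
  never develop it;
* mean duration — the mean total years spent with MetS among individuals
  who ever had it (censored at 65).

The sensitivity transform removes state episodes shorter than a threshold
(default 6 months): such blips are treated as temporary fluctuations above
the diagnostic cut-offs rather than true transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import AGE_MAX, AGE_MIN, HEALTHY, METS, SPAN_YEARS, Stratum
from .engine import LifeCourse


@dataclass
class SummaryStats:
    stratum: Optional[Stratum]
    n: int
    life_course_prevalence: float
    mean_age_onset: Optional[float]
    mean_duration: Optional[float]
    age_grid: Optional[np.ndarray] = None
    age_prevalence: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {
            "stratum": self.stratum.label if self.stratum else None,
            "n": self.n,
            "life_course_prevalence": self.life_course_prevalence,
            "mean_age_onset": self.mean_age_onset,
            "mean_duration": self.mean_duration,
        }
        if self.age_grid is not None:
            d["age_grid"] = list(map(float, self.age_grid))
            d["age_prevalence"] = list(map(float, self.age_prevalence))
        return d


def life_course_prevalence(lcs: Sequence[LifeCourse]) -> float:
    """Fraction of individuals whose trajectory contains a MetS episode."""
    if not lcs:
        raise ValueError("empty life-course list")
    return sum(lc.ever_mets() for lc in lcs) / len(lcs)


def mean_age_of_onset(lcs: Sequence[LifeCourse]) -> Optional[float]:
    """Mean first-onset age among those entering healthy who develop MetS."""
    if not lcs:
        raise ValueError("empty life-course list")
    onsets = [a for lc in lcs if (a := lc.first_onset_age()) is not None]
    if not onsets:
        warnings.warn("no eligible individuals for mean age of onset")
        return None
    return float(np.mean(onsets))


def mean_duration(lcs: Sequence[LifeCourse]) -> Optional[float]:
    """Mean total MetS-years among individuals who ever had MetS."""
    if not lcs:
        raise ValueError("empty life-course list")
    durations = [lc.mets_occupancy() for lc in lcs if lc.ever_mets()]
    if not durations:
        warnings.warn("no individuals ever had MetS; mean duration undefined")
        return None
    return float(np.mean(durations))


def age_specific_prevalence(
    lcs: Sequence[LifeCourse], grid: Sequence[float]
) -> np.ndarray:
    """Cross-sectional MetS prevalence at each grid age.

    Episodes are half-open [start, next start), so the state at a grid age is
    the state of the covering episode."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < AGE_MIN or grid.max() >= AGE_MAX:
        raise ValueError("grid ages must lie in [18, 65)")
    counts = np.zeros(len(grid))
    for lc in lcs:
        # vectorized: state flips at each transition age <= grid age
        n_before = np.searchsorted(np.asarray(lc.transition_ages), grid, side="right")
        states = (lc.first_state + n_before) % 2
        counts += states == METS
    return counts / len(lcs)


def summarize(
    lcs: Sequence[LifeCourse],
    stratum: Optional[Stratum] = None,
    grid: Optional[Sequence[float]] = None,
) -> SummaryStats:
    if stratum is not None:
        lcs = [lc for lc in lcs if lc.stratum == stratum]
    prev_grid = None
    if grid is not None:
        prev_grid = age_specific_prevalence(lcs, grid)
    return SummaryStats(
        stratum=stratum,
        n=len(lcs),
        life_course_prevalence=life_course_prevalence(lcs),
        mean_age_onset=mean_age_of_onset(lcs),
        mean_duration=mean_duration(lcs),
        age_grid=np.asarray(grid, dtype=float) if grid is not None else None,
        age_prevalence=prev_grid,
    )


# ---------------------------------------------------------------------------
# Sensitivity transform: merging short episodes
# ---------------------------------------------------------------------------


def merge_short_episodes(lc: LifeCourse, min_duration: float = 0.5) -> LifeCourse:
    """Remove episodes shorter than ``min_duration`` years.

    Scanning forward from age 18, an episode shorter than the threshold is
    absorbed into the preceding retained episode (the state that held before
    the blip persists through it).  Short episodes at the very start, before
    any valid episode exists, are absorbed forward into the first episode of
    sufficient duration.  Adjacent same-state episodes are then coalesced.

    If no episode reaches the threshold, the whole life course collapses to
    a single episode of the state with the larger total occupancy, with a
    warning.  Total duration is conserved at 47 years; applying the
    transform twice equals applying it once."""
    if min_duration < 0:
        raise ValueError("min_duration must be nonnegative")
    spans = lc.episode_spans()
    if min_duration == 0:
        return lc

    valid = [(state, end - start >= min_duration) for state, start, end in spans]
    if not any(v for _, v in valid):
        occupancy = lc.mets_occupancy()
        majority = METS if occupancy >= SPAN_YEARS / 2 else HEALTHY
        warnings.warn(
            f"no episode reaches {min_duration} years; collapsing to the "
            "majority state"
        )
        return LifeCourse(lc.id, lc.stratum, majority, ())

    # Assign each span the state it ends up with: a short span takes the
    # state of the nearest preceding valid span, or of the first valid span
    # for leading blips.
    first_valid = next(i for i, (_, v) in enumerate(valid) if v)
    assigned = []
    current = spans[first_valid][0]
    for i, (state, start, end) in enumerate(spans):
        if valid[i][1]:
            current = state
            assigned.append(state)
        elif i < first_valid:
            assigned.append(spans[first_valid][0])
        else:
            assigned.append(current)

    # Coalesce consecutive same-state spans into episodes.
    first_state = assigned[0]
    transitions = [
        spans[i][1]
        for i in range(1, len(spans))
        if assigned[i] != assigned[i - 1]
    ]
    return LifeCourse(lc.id, lc.stratum, first_state, tuple(transitions))


def merge_cohort(lcs: Sequence[LifeCourse], min_duration: float = 0.5) -> list[LifeCourse]:
    return [merge_short_episodes(lc, min_duration) for lc in lcs]
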