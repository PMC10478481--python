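"""Ensemble confidence intervals for the life-course summary measures.

Sampling uncertainty in the estimated age-group rates is propagated by an
ensemble: each replicate draws a fresh rate for every age-group cell from
``Normal(estimate, se)`` (truncated below at 0, since hazards cannot be
negative), refits the continuous-age curves, re-simulates a smaller cohort,
and recomputes the three summary measures per stratum.  The 2.5th and 97.5th
percentiles across replicates bound the 95% interval.  The entry prevalence
at 18 is perturbed the same way (truncated to [0, 1]).

The interval brackets an independent ensemble, not the main run, so the
main-run point estimate is not guaranteed to lie inside — only
``lower <= upper`` is structural.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .core import AgeGroupRate, PrevalenceAt18, all_strata
from .curves import fit_curve
from .engine import SimulationSpec, simulate_cohort
from .summaries import summarize

logger = logging.getLogger(__name__)

MEASURES = ("life_course_prevalence", "mean_age_onset", "mean_duration")


@dataclass
class EnsembleSpec:
    base_rates: dict  # {"incidence": [AgeGroupRate], "recovery": [AgeGroupRate]}
    init_probs: Sequence[PrevalenceAt18]
    n_reps: int = 1000
    n_individuals_per_rep: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be at least 2")
        if self.n_individuals_per_rep % 4 != 0:
            raise ValueError("n_individuals_per_rep must be divisible by 4")
        for kind in ("incidence", "recovery"):
            if kind not in self.base_rates:
                raise ValueError(f"base_rates missing kind {kind!r}")


@dataclass
class IntervalEstimate:
    point: Optional[float]
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")


def draw_rate_set(
    base: Sequence[AgeGroupRate], rng: np.random.Generator
) -> list[AgeGroupRate]:
    """Independent Normal(estimate, se) redraw of each age-group rate,
    truncated below at 0."""
    out = []
    for r in base:
        draw = rng.normal(r.rate_per_year, r.se) if r.se > 0 else r.rate_per_year
        out.append(replace(r, rate_per_year=max(0.0, float(draw))))
    return out


def draw_init_probs(
    base: Sequence[PrevalenceAt18], rng: np.random.Generator
) -> dict[str, float]:
    out = {}
    for p in base:
        draw = rng.normal(p.probability, p.se) if p.se > 0 else p.probability
        out[p.stratum.label] = float(np.clip(draw, 0.0, 1.0))
    return out


def _fit_rep_curves(rates_by_kind: dict) -> dict:
    curves = {}
    for kind, rates in rates_by_kind.items():
        for stratum in all_strata():
            points = [r for r in rates if r.stratum == stratum]
            points.sort(key=lambda r: r.age_lo)
            curves[(stratum.label, kind)] = fit_curve(points)
    return curves


def run_ensemble(
    spec: EnsembleSpec,
    points: Optional[dict] = None,
) -> dict:
    """Run the replicate ensemble and return
    ``{(stratum_label, measure): IntervalEstimate}``.

    ``points`` optionally supplies main-run point estimates keyed the same
    way.  A replicate whose curve fit fails is redrawn once with fresh
    perturbations; if the redraw also fails the replicate is skipped and
    counted in the log."""
    spec.validate()
    n_per_group = spec.n_individuals_per_rep // 4
    samples: dict[tuple, list] = {
        (s.label, m): [] for s in all_strata() for m in MEASURES
    }
    skipped = 0
    for rep in range(spec.n_reps):
        result = None
        for attempt in range(2):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(rep, attempt))
            )
            try:
                rates = {
                    kind: draw_rate_set(spec.base_rates[kind], rng)
                    for kind in ("incidence", "recovery")
                }
                curves = _fit_rep_curves(rates)
                init_probs = draw_init_probs(spec.init_probs, rng)
                # Philox stream namespace: keep replicate seeds disjoint from
                # the main run by offsetting with the replicate index + 1.
                sim_seed = (spec.seed << 20) + rep + 1
                sim = SimulationSpec(curves, init_probs, n_per_group, sim_seed)
                lcs = simulate_cohort(sim)
                result = {
                    stratum.label: summarize(lcs, stratum=stratum)
                    for stratum in all_strata()
                }
                break
            except (RuntimeError, ValueError):
                continue
        if result is None:
            skipped += 1
            continue
        for stratum in all_strata():
            stats = result[stratum.label]
            samples[(stratum.label, "life_course_prevalence")].append(
                stats.life_course_prevalence
            )
            samples[(stratum.label, "mean_age_onset")].append(
                stats.mean_age_onset if stats.mean_age_onset is not None else np.nan
            )
            samples[(stratum.label, "mean_duration")].append(
                stats.mean_duration if stats.mean_duration is not None else np.nan
            )
    if skipped:
        logger.warning("ensemble: %d of %d replicates skipped", skipped, spec.n_reps)

    intervals = {}
    for key, values in samples.items():
        arr = np.asarray(values, dtype=float)
        lower, upper = np.nanpercentile(arr, [2.5, 97.5])
        point = points.get(key) if points else None
        intervals[key] = IntervalEstimate(point=point, lower=float(lower), upper=float(upper))
    return intervals
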