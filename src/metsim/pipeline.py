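"""End-to-end orchestration: cohort -> rates -> curves -> simulation -> report.

The stages are deliberately small pure functions over the module surfaces so
that counterfactual scenarios and the uncertainty ensemble can re-enter the
chain at the rate-set stage.  A single master seed drives every stage;
scenario simulations reuse the same per-individual random streams (common
random numbers), so an identity counterfactual reproduces the observed
scenario exactly and scenario contrasts are low-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AgeGroupRate, PrevalenceAt18, all_strata
from .counterfactual import CounterfactualSpec, scenario_rates
from .curves import RateCurve, fit_curve
from .engine import SimulationSpec, simulate_cohort
from .rates import estimate_prevalence_at_18, estimate_rates
from .summaries import SummaryStats, merge_cohort, summarize


@dataclass
class RateEstimates:
    prevalence_at_18: list[PrevalenceAt18]
    rates: dict  # {"incidence": [AgeGroupRate], "recovery": [AgeGroupRate]}

    @property
    def init_probs(self) -> dict[str, float]:
        return {p.stratum.label: p.probability for p in self.prevalence_at_18}


def estimate_all(cohort: pd.DataFrame) -> RateEstimates:
    return RateEstimates(
        prevalence_at_18=estimate_prevalence_at_18(cohort),
        rates={
            "incidence": estimate_rates(cohort, "incidence"),
            "recovery": estimate_rates(cohort, "recovery"),
        },
    )


def fit_all_curves(rates_by_kind: dict) -> dict:
    """Fit one curve per stratum and kind: logistic incidence, quartic recovery."""
    curves: dict[tuple[str, str], RateCurve] = {}
    for kind, rates in rates_by_kind.items():
        for stratum in all_strata():
            points = sorted(
                (r for r in rates if r.stratum == stratum), key=lambda r: r.age_lo
            )
            if not points:
                raise ValueError(f"no rate points for {stratum.label} {kind}")
            curves[(stratum.label, kind)] = fit_curve(points)
    return curves


def simulate_and_summarize(
    curves: dict,
    init_probs: dict[str, float],
    n_per_group: int,
    seed: int,
    grid: Optional[Sequence[float]] = None,
    merge_threshold: Optional[float] = None,
) -> dict[str, SummaryStats]:
    spec = SimulationSpec(curves, init_probs, n_per_group, seed)
    lcs = simulate_cohort(spec)
    if merge_threshold:
        lcs = merge_cohort(lcs, merge_threshold)
    return {s.label: summarize(lcs, stratum=s, grid=grid) for s in all_strata()}


def run_observed_pipeline(
    cohort: pd.DataFrame,
    n_per_group: int,
    seed: int,
    grid: Optional[Sequence[float]] = None,
    merge_threshold: Optional[float] = None,
) -> tuple[RateEstimates, dict, dict[str, SummaryStats]]:
    """Estimate, fit, simulate; returns (estimates, curves, summaries)."""
    estimates = estimate_all(cohort)
    curves = fit_all_curves(estimates.rates)
    stats = simulate_and_summarize(
        curves, estimates.init_probs, n_per_group, seed, grid, merge_threshold
    )
    return estimates, curves, stats


def run_counterfactual_pipeline(
    cohort: pd.DataFrame,
    spec: CounterfactualSpec,
    n_per_group: int,
    seed: int,
    estimates: Optional[RateEstimates] = None,
    grid: Optional[Sequence[float]] = None,
    merge_threshold: Optional[float] = None,
) -> dict[str, SummaryStats]:
    """Summaries under one counterfactual scenario.

    High-education rates are not re-estimated: their observed rates (from
    ``estimates``, computed here if not supplied) are reused, and the same
    master seed keeps the high-education simulations identical to the
    observed scenario."""
    if estimates is None:
        estimates = estimate_all(cohort)
    cf_rates = scenario_rates(cohort, spec, estimates.rates)
    curves = fit_all_curves(cf_rates)
    return simulate_and_summarize(
        curves, estimates.init_probs, n_per_group, seed, grid, merge_threshold
    )


def run_all_scenarios(
    cohort: pd.DataFrame,
    n_per_group: int,
    seed: int,
    factors: Sequence[str] = ("smoking", "alcohol", "health_literacy", "diet"),
    include_joint: bool = True,
    grid: Optional[Sequence[float]] = None,
    merge_threshold: Optional[float] = None,
) -> dict[str, dict[str, SummaryStats]]:
    """Observed plus single-factor and joint counterfactual scenarios, all
    sharing one estimation pass and one set of random streams."""
    estimates, curves, observed = run_observed_pipeline(
        cohort, n_per_group, seed, grid, merge_threshold
    )
    scenarios: dict[str, dict[str, SummaryStats]] = {"observed": observed}
    specs = [CounterfactualSpec((f,)) for f in factors]
    if include_joint:
        specs.append(CounterfactualSpec(tuple(factors)))
    for cf in specs:
        scenarios[cf.label] = run_counterfactual_pipeline(
            cohort, cf, n_per_group, seed, estimates, grid, merge_threshold
        )
    return scenarios
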