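"""Mediation ranking and counterfactual transition rates.

The counterfactual question: what would the low-education group's transition
rates be if its distribution of one or more modifiable factors (smoking,
alcohol, diet quality, health literacy) equalled the high-education group's,
all else held fixed?

Two pieces:

* ``mediation_percentages`` ranks factors by the difference method — the
  percentage attenuation of the education coefficient in a logistic
  transition model when the factor is added;
* ``counterfactual_rates`` computes the counterfactual age-group rates by
  marginal standardization implemented as distribution-ratio reweighting:
  each low-education at-risk record receives weight
  ``prod_f P_high(f = category) / P_low(f = category)``, and the cell's
  counterfactual probability is the weighted mean of the fitted transition
  model's predicted probabilities at observed covariates.  High-education
  rates are unchanged by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    AgeGroupRate,
    MEDIATOR_CATEGORIES,
    MEDIATORS,
    Stratum,
    age_bins,
)
from .rates import (
    _assign_age_bins,
    _at_risk,
    _event,
    annualize_intervals,
    estimate_interval_probabilities,
    stratum_mask,
)

ALL_FACTORS = tuple(MEDIATORS)


@dataclass
class MediationResult:
    factor: str
    mediated_percent_incidence: Optional[float]
    mediated_percent_recovery: Optional[float]

    @property
    def mean_mediated_percent(self) -> Optional[float]:
        vals = [
            v
            for v in (self.mediated_percent_incidence, self.mediated_percent_recovery)
            if v is not None
        ]
        return float(np.mean(vals)) if vals else None


@dataclass
class CounterfactualSpec:
    """Which factor distributions to shift.  ``joint`` marks the scenario in
    which all four factors are changed at once."""

    factors: tuple

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("CounterfactualSpec needs at least one factor")
        unknown = set(self.factors) - set(ALL_FACTORS)
        if unknown:
            raise ValueError(f"unknown factors: {sorted(unknown)}")
        self.factors = tuple(self.factors)

    @property
    def joint(self) -> bool:
        return set(self.factors) == set(ALL_FACTORS)

    @property
    def label(self) -> str:
        if self.joint:
            return "counterfactual_joint"
        return "counterfactual_" + "_".join(self.factors)


# ---------------------------------------------------------------------------
# Mediation (difference method)
# ---------------------------------------------------------------------------


def _mediation_design(df: pd.DataFrame, factor: Optional[str]) -> np.ndarray:
    """Intercept + low-education indicator + age-group dummies
    (+ factor-category dummies)."""
    df = _assign_age_bins(df)
    bins_present = sorted(df["_age_bin"].unique())
    cols = [np.ones(len(df)), (df["edu_years"] == 10).to_numpy(dtype=float)]
    for label in bins_present[1:]:
        cols.append((df["_age_bin"] == label).to_numpy(dtype=float))
    if factor is not None:
        categories = sorted(df[factor].unique())
        for category in categories[1:]:
            cols.append((df[factor] == category).to_numpy(dtype=float))
    return np.column_stack(cols)


def _education_coefficient(df: pd.DataFrame, kind: str, factor: Optional[str]) -> float:
    y = _event(df, kind)
    X = _mediation_design(df, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    return float(fit.params[1])  # the low-education log-odds coefficient


def mediation_percentages(cohort: pd.DataFrame, kind: str) -> list[MediationResult]:
    """Difference-method mediated percentage of the education effect, per factor.

    ``100 * (beta_without - beta_with) / beta_without`` where the betas are
    the low-education coefficients of transition models without and with the
    factor.  Undefined (None, with a warning) when the unadjusted education
    effect is essentially zero.  Values can be negative (inconsistent
    mediation) and are reported as-is."""
    if kind not in ("incidence", "recovery"):
        raise ValueError(f"kind must be incidence or recovery, got {kind!r}")
    df = _at_risk(cohort, kind)
    if df["edu_years"].nunique() < 2:
        raise ValueError("cohort must contain both education groups")
    beta_without = _education_coefficient(df, kind, None)
    results = []
    for factor in ALL_FACTORS:
        if abs(beta_without) < 1e-6:
            warnings.warn(
                f"education coefficient ~0 for {kind}; mediated % undefined"
            )
            pct = None
        else:
            beta_with = _education_coefficient(df, kind, factor)
            pct = 100.0 * (beta_without - beta_with) / beta_without
        results.append((factor, pct))
    return [
        MediationResult(
            factor,
            pct if kind == "incidence" else None,
            pct if kind == "recovery" else None,
        )
        for factor, pct in results
    ]


def rank_factors(cohort: pd.DataFrame) -> list[MediationResult]:
    """Combine incidence and recovery mediation into one ranking, ordered by
    the mean mediated percentage (descending)."""
    inc = {m.factor: m.mediated_percent_incidence for m in mediation_percentages(cohort, "incidence")}
    rec = {m.factor: m.mediated_percent_recovery for m in mediation_percentages(cohort, "recovery")}
    merged = [MediationResult(f, inc[f], rec[f]) for f in ALL_FACTORS]
    return sorted(
        merged,
        key=lambda m: -(m.mean_mediated_percent if m.mean_mediated_percent is not None else -np.inf),
    )


# ---------------------------------------------------------------------------
# Counterfactual rates by distribution-ratio reweighting
# ---------------------------------------------------------------------------


def factor_marginals(df: pd.DataFrame, factor: str) -> dict[str, float]:
    """Observed category proportions of one factor in ``df``."""
    counts = df[factor].value_counts(normalize=True)
    return {cat: float(counts.get(cat, 0.0)) for cat in MEDIATOR_CATEGORIES[factor]}


def reweighting_weights(
    low_df: pd.DataFrame,
    spec: CounterfactualSpec,
    target_marginals: dict[str, dict[str, float]],
) -> np.ndarray:
    """Per-record weights shifting the low group's factor marginals to the
    target (normally high-education) marginals: the product over the spec's
    factors of target/source category-probability ratios."""
    w = np.ones(len(low_df))
    for factor in spec.factors:
        source = factor_marginals(low_df, factor)
        target = target_marginals[factor]
        cats = low_df[factor].to_numpy()
        ratios = np.empty(len(low_df))
        for cat in MEDIATOR_CATEGORIES[factor]:
            mask = cats == cat
            if not mask.any():
                continue
            if target.get(cat, 0.0) <= 0.0:
                raise ValueError(
                    f"category {cat!r} of factor {factor!r} present in the "
                    "low-education group but absent in the target distribution"
                )
            ratios[mask] = target[cat] / source[cat]
        w *= ratios
    return w


def counterfactual_rates(
    cohort: pd.DataFrame,
    spec: CounterfactualSpec,
    kind: str,
    target_marginals: Optional[dict[str, dict[str, dict[str, float]]]] = None,
    per_cell_marginals: bool = False,
) -> list[AgeGroupRate]:
    """Counterfactual age-group rates for the two low-education strata.

    ``target_marginals`` optionally overrides the target distribution per
    sex (``{sex: {factor: {category: prob}}}``); the default target is the
    same-sex high-education at-risk set.  With ``per_cell_marginals`` the
    source (and default target) marginals are computed within each age-group
    cell instead of stratum-wide; stratum-wide is the default because sparse
    cells make per-cell weights noisy."""
    weights: dict[str, np.ndarray] = {}
    for sex in ("female", "male"):
        low = Stratum(sex, "low")
        high = Stratum(sex, "high")
        low_df = _at_risk(cohort[stratum_mask(cohort, low)], kind)
        high_df = _at_risk(cohort[stratum_mask(cohort, high)], kind)
        if target_marginals is not None:
            targets = target_marginals[sex]
        else:
            targets = {f: factor_marginals(high_df, f) for f in spec.factors}
        if per_cell_marginals:
            low_binned = _assign_age_bins(low_df)
            high_binned = _assign_age_bins(high_df)
            w = np.ones(len(low_df))
            for label in low_binned["_age_bin"].unique():
                cell_mask = (low_binned["_age_bin"] == label).to_numpy()
                cell_low = low_binned[low_binned["_age_bin"] == label]
                if target_marginals is not None:
                    cell_targets = targets
                else:
                    cell_high = high_binned[high_binned["_age_bin"] == label]
                    if len(cell_high) == 0:
                        raise ValueError(
                            f"no high-education at-risk records in age group {label}"
                        )
                    cell_targets = {
                        f: factor_marginals(cell_high, f) for f in spec.factors
                    }
                w[cell_mask] = reweighting_weights(cell_low, spec, cell_targets)
        else:
            w = reweighting_weights(low_df, spec, targets)
        weights[low.label] = w

    intervals = estimate_interval_probabilities(cohort, kind, weights=weights)
    low_intervals = [iv for iv in intervals if iv.stratum.education == "low"]
    return annualize_intervals(low_intervals)


def scenario_rates(
    cohort: pd.DataFrame,
    spec: CounterfactualSpec,
    observed_rates: dict[str, list[AgeGroupRate]],
) -> dict[str, list[AgeGroupRate]]:
    """Full rate set for one counterfactual scenario: reweighted rates for the
    low-education strata, the observed rates for the high-education strata."""
    out: dict[str, list[AgeGroupRate]] = {}
    for kind in ("incidence", "recovery"):
        cf = counterfactual_rates(cohort, spec, kind)
        kept = [r for r in observed_rates[kind] if r.stratum.education == "high"]
        out[kind] = kept + cf
    return out
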