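"""Estimation of age-specific MetS transition rates from two-wave data.

Three sets of quantities are estimated separately within each of the four
sex-by-education strata:

1. MetS prevalence at age 18 — a logistic regression of baseline status on
   baseline age, evaluated at age 18 (delta-method standard error);
2. incidence probabilities per 5-year age group among participants free of
   MetS at baseline;
3. recovery probabilities per 5-year age group among participants with MetS
   at baseline.

The interval models are logistic regressions of the transition indicator on
age-group indicators plus the four modifiable factors.  The age-group
probability is the average of the model's predicted probabilities over the
at-risk records of that group at their observed covariates (marginal
standardization); its standard error follows from the delta method.

Interval probabilities are converted to annual hazards assuming a constant
hazard over the (cell-mean) follow-up interval:
``rate = -ln(1 - p) / dt``.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    AgeGroupRate,
    IntervalProbability,
    MEDIATOR_CATEGORIES,
    MEDIATORS,
    PrevalenceAt18,
    Stratum,
    age_bins,
    all_strata,
)

EDU_YEARS_TO_LEVEL = {10: "low", 16: "high"}


def stratum_mask(df: pd.DataFrame, stratum: Stratum) -> pd.Series:
    edu_years = 10 if stratum.education == "low" else 16
    return (df["sex"] == stratum.sex) & (df["edu_years"] == edu_years)


def _agresti(successes: int, n: int) -> tuple[float, float]:
    """Continuity-corrected proportion and its binomial standard error."""
    p = (successes + 0.5) / (n + 1.0)
    se = np.sqrt(p * (1.0 - p) / (n + 1.0))
    return p, se


# ---------------------------------------------------------------------------
# Prevalence at age 18
# ---------------------------------------------------------------------------


def estimate_prevalence_at_18(cohort: pd.DataFrame) -> list[PrevalenceAt18]:
    """Per-stratum model-based prevalence of MetS at the simulation entry age."""
    results = []
    for stratum in all_strata():
        sub = cohort[stratum_mask(cohort, stratum)]
        if len(sub) == 0:
            raise ValueError(f"no participants in stratum {stratum.label}")
        y = sub["mets_t1"].to_numpy(dtype=float)
        if y.min() == y.max():
            warnings.warn(
                f"{stratum.label}: all baseline statuses identical; "
                "using continuity-corrected proportion for prevalence at 18"
            )
            p, se = _agresti(int(y.sum()), len(y))
            results.append(PrevalenceAt18(stratum, p, se, flag="corrected"))
            continue
        X = sm.add_constant(sub[["age_t1"]].to_numpy())
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            x18 = np.array([1.0, 18.0])
            eta = float(x18 @ fit.params)
            p = 1.0 / (1.0 + np.exp(-eta))
            var_eta = float(x18 @ fit.cov_params() @ x18)
            se = p * (1.0 - p) * np.sqrt(var_eta)
        except Exception:
            warnings.warn(
                f"{stratum.label}: prevalence model failed; "
                "using continuity-corrected proportion"
            )
            p, se = _agresti(int(y.sum()), len(y))
            results.append(PrevalenceAt18(stratum, p, se, flag="corrected"))
            continue
        results.append(PrevalenceAt18(stratum, p, se))
    return results


# ---------------------------------------------------------------------------
# Interval transition probabilities
# ---------------------------------------------------------------------------


def _at_risk(cohort: pd.DataFrame, kind: str) -> pd.DataFrame:
    if kind == "incidence":
        return cohort[cohort["mets_t1"] == 0]
    if kind == "recovery":
        return cohort[cohort["mets_t1"] == 1]
    raise ValueError(f"kind must be incidence or recovery, got {kind!r}")


def _event(df: pd.DataFrame, kind: str) -> np.ndarray:
    if kind == "incidence":
        return (df["mets_t4"] == 1).to_numpy(dtype=float)
    return (df["mets_t4"] == 0).to_numpy(dtype=float)


def _design_matrix(
    df: pd.DataFrame, bin_labels: list[str], include_mediators: bool = True
) -> np.ndarray:
    """Intercept + age-group dummies (first bin present in data = reference)
    + mediator-category dummies (first category = reference)."""
    cols = [np.ones(len(df))]
    for label in bin_labels[1:]:
        cols.append((df["_age_bin"] == label).to_numpy(dtype=float))
    if include_mediators:
        for factor in MEDIATORS:
            for category in MEDIATOR_CATEGORIES[factor][1:]:
                cols.append((df[factor] == category).to_numpy(dtype=float))
    return np.column_stack(cols)


def _assign_age_bins(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    labels = []
    bins = age_bins()
    edges = [lo for lo, _ in bins] + [bins[-1][1]]
    idx = np.clip(
        np.searchsorted(edges, df["age_t1"].to_numpy(), side="right") - 1,
        0,
        len(bins) - 1,
    )
    df["_age_bin"] = [f"{bins[i][0]:g}-{bins[i][1]:g}" for i in idx]
    return df


def estimate_interval_probabilities(
    cohort: pd.DataFrame,
    kind: str,
    weights: Optional[dict] = None,
    include_mediators: bool = True,
) -> list[IntervalProbability]:
    """Marginally standardized transition probability per stratum x age group.

    ``weights`` optionally maps a stratum label to a per-record weight array
    aligned with that stratum's at-risk subset (used by the counterfactual
    reweighting); default is unit weights."""
    out: list[IntervalProbability] = []
    for stratum in all_strata():
        at_risk = _at_risk(cohort[stratum_mask(cohort, stratum)], kind)
        if len(at_risk) == 0:
            raise ValueError(f"no at-risk records for {stratum.label} {kind}")
        at_risk = _assign_age_bins(at_risk)
        y = _event(at_risk, kind)
        w = None
        if weights is not None and stratum.label in weights:
            w = np.asarray(weights[stratum.label], dtype=float)
            if len(w) != len(at_risk):
                raise ValueError(
                    f"weights for {stratum.label} have length {len(w)}, "
                    f"expected {len(at_risk)}"
                )

        bins_present = [
            f"{lo:g}-{hi:g}"
            for lo, hi in age_bins()
            if (at_risk["_age_bin"] == f"{lo:g}-{hi:g}").any()
        ]
        X = _design_matrix(at_risk, bins_present, include_mediators)
        fit = None
        cov = None
        if 0.0 < y.mean() < 1.0:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
                if not np.all(np.isfinite(fit.params)) or np.abs(fit.params).max() > 30:
                    fit = None
                else:
                    cov = np.asarray(fit.cov_params())
            except Exception:
                fit = None
        if fit is None:
            warnings.warn(
                f"{stratum.label} {kind}: transition model degenerate or "
                "non-converged; falling back to cell proportions"
            )

        for lo, hi in age_bins():
            label = f"{lo:g}-{hi:g}"
            cell = (at_risk["_age_bin"] == label).to_numpy()
            n_cell = int(cell.sum())
            if n_cell == 0:
                continue  # absent cell: curve fitting skips it
            events = int(y[cell].sum())
            mean_dt = float(
                (at_risk["age_t4"] - at_risk["age_t1"]).to_numpy()[cell].mean()
            )
            flag = None
            if fit is None or events == 0 or events == n_cell:
                p, se = _agresti(events, n_cell)
                flag = "corrected"
            else:
                Xc = X[cell]
                p_hat = fit.predict(Xc)
                if w is None:
                    p = float(p_hat.mean())
                    grad = (p_hat * (1.0 - p_hat))[:, None] * Xc
                    g = grad.mean(axis=0)
                else:
                    wc = w[cell]
                    p = float(np.average(p_hat, weights=wc))
                    grad = (wc * p_hat * (1.0 - p_hat))[:, None] * Xc
                    g = grad.sum(axis=0) / wc.sum()
                se = float(np.sqrt(g @ cov @ g))
            out.append(
                IntervalProbability(
                    stratum=stratum,
                    kind=kind,
                    age_lo=lo,
                    age_hi=hi,
                    probability=p,
                    se=se,
                    mean_followup=mean_dt,
                    n_at_risk=n_cell,
                    flag=flag,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Annualization
# ---------------------------------------------------------------------------


def annualize(probability: float, mean_followup: float, se: float = 0.0) -> tuple[float, float]:
    """Convert an interval transition probability to a constant annual hazard.

    Under a constant hazard ``r`` over ``dt`` years the transition
    probability is ``1 - exp(-r dt)``, so ``r = -ln(1-p)/dt``.  The standard
    error propagates by the delta method: ``se_r = se_p / ((1-p) dt)``."""
    if not (0.0 <= probability < 1.0):
        raise ValueError(f"probability must be in [0, 1), got {probability}")
    if mean_followup <= 0:
        raise ValueError(f"mean_followup must be positive, got {mean_followup}")
    rate = -np.log1p(-probability) / mean_followup
    se_rate = se / ((1.0 - probability) * mean_followup)
    return float(rate), float(se_rate)


def annualize_intervals(intervals: list[IntervalProbability]) -> list[AgeGroupRate]:
    rates = []
    for iv in intervals:
        rate, se = annualize(iv.probability, iv.mean_followup, iv.se)
        rates.append(
            AgeGroupRate(
                stratum=iv.stratum,
                kind=iv.kind,
                age_lo=iv.age_lo,
                age_hi=iv.age_hi,
                rate_per_year=rate,
                se=se,
                n_at_risk=iv.n_at_risk,
                flag=iv.flag,
            )
        )
    return rates


def estimate_rates(cohort: pd.DataFrame, kind: str) -> list[AgeGroupRate]:
    """Convenience: interval probabilities -> annual hazards for all strata."""
    return annualize_intervals(estimate_interval_probabilities(cohort, kind))


# ---------------------------------------------------------------------------
# Rates CSV (also the reader target for externally published rate tables)
# ---------------------------------------------------------------------------

RATES_COLUMNS = ["sex", "edu", "kind", "age_lo", "age_hi", "rate_per_year", "se", "n_at_risk"]


def write_rates_csv(rates: list[AgeGroupRate], path) -> None:
    rows = [
        {
            "sex": r.stratum.sex,
            "edu": r.stratum.education,
            "kind": r.kind,
            "age_lo": r.age_lo,
            "age_hi": r.age_hi,
            "rate_per_year": r.rate_per_year,
            "se": r.se,
            "n_at_risk": r.n_at_risk if r.n_at_risk is not None else "",
        }
        for r in rates
    ]
    pd.DataFrame(rows, columns=RATES_COLUMNS).to_csv(path, index=False)


def read_rates_csv(path) -> list[AgeGroupRate]:
    df = pd.read_csv(path)
    missing = [c for c in RATES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rates CSV {path} missing columns: {missing}")
    rates = []
    for i, row in df.iterrows():
        try:
            n_at_risk = (
                int(row["n_at_risk"]) if pd.notna(row["n_at_risk"]) and row["n_at_risk"] != "" else None
            )
            rates.append(
                AgeGroupRate(
                    stratum=Stratum(str(row["sex"]), str(row["edu"])),
                    kind=str(row["kind"]),
                    age_lo=float(row["age_lo"]),
                    age_hi=float(row["age_hi"]),
                    rate_per_year=float(row["rate_per_year"]),
                    se=float(row["se"]),
                    n_at_risk=n_at_risk,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"rates CSV {path}, row {i + 2}: {exc}") from exc
    return rates
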