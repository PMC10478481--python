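"""Bundled reference tables.

``published_lifecourse_summaries`` holds the published point estimates and
95% intervals of the three life-course summary measures for the
Lifelines-based simulation (observed and counterfactual scenarios, by sex
and education).  These are simulation *outputs* reported by the source
study; the package uses them as inputs for the inequality arithmetic, not
as something its own simulations are tuned to.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .summaries import SummaryStats
from .core import Stratum


def published_lifecourse_summaries() -> pd.DataFrame:
    with resources.files("metsim.data").joinpath(
        "published_lifecourse_summaries.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def published_scenario_stats() -> dict[str, dict[str, SummaryStats]]:
    """The published table reshaped into the report builder's input form:
    ``{scenario: {stratum_label: SummaryStats}}``.

    High-education rows are unchanged under every counterfactual (only the
    low-education rates are re-estimated), so the observed high-education
    summaries are carried into each counterfactual scenario."""
    df = published_lifecourse_summaries()
    out: dict[str, dict[str, SummaryStats]] = {}
    for _, row in df.iterrows():
        stratum = Stratum(row["sex"], row["education"])
        stats = SummaryStats(
            stratum=stratum,
            n=0,
            life_course_prevalence=row["life_course_prevalence_pct"] / 100.0,
            mean_age_onset=row["mean_age_onset"],
            mean_duration=row["mean_duration"],
        )
        out.setdefault(row["scenario"], {})[stratum.label] = stats
    observed_high = {
        label: stats
        for label, stats in out["observed"].items()
        if label.endswith("_high")
    }
    for scenario, stats in out.items():
        if scenario != "observed":
            for label, s in observed_high.items():
                stats.setdefault(label, s)
    return out
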