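"""Headline inequality measures and counterfactual reductions.

Gaps between the low- and high-education groups are oriented so that a
positive value always means a heavier burden for the low-educated:

* prevalence gap — percentage points of life-course prevalence, low minus
  high;
* onset gap — years, high minus low (positive = low-educated develop MetS
  earlier);
* duration gap — years with MetS, low minus high.

A counterfactual scenario's effect is summarized as the percentage
reduction of each observed gap.  Reported numbers are rounded
half-away-from-zero to one decimal in decimal arithmetic, matching how
one-decimal published tables combine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .summaries import SummaryStats


@dataclass
class Gaps:
    prevalence_gap: Optional[float]  # percentage points, low - high
    onset_gap: Optional[float]  # years, high - low
    duration_gap: Optional[float]  # years, low - high


def gaps(stats_low: SummaryStats, stats_high: SummaryStats) -> Gaps:
    """Education gaps for one sex."""
    if (
        stats_low.stratum is not None
        and stats_high.stratum is not None
        and stats_low.stratum.sex != stats_high.stratum.sex
    ):
        raise ValueError("gaps compare education groups within one sex")
    prevalence_gap = 100.0 * (
        stats_low.life_course_prevalence - stats_high.life_course_prevalence
    )
    onset_gap = (
        stats_high.mean_age_onset - stats_low.mean_age_onset
        if stats_low.mean_age_onset is not None and stats_high.mean_age_onset is not None
        else None
    )
    duration_gap = (
        stats_low.mean_duration - stats_high.mean_duration
        if stats_low.mean_duration is not None and stats_high.mean_duration is not None
        else None
    )
    return Gaps(prevalence_gap, onset_gap, duration_gap)


def round_reported(value: float, decimals: int = 1) -> float:
    """Round half away from zero in decimal (not binary) arithmetic."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def sex_average(gaps_f: Gaps, gaps_m: Gaps) -> Gaps:
    """Arithmetic mean of the female and male gaps, computed in decimal
    arithmetic and rounded to one decimal for reporting."""

    def avg(a: Optional[float], b: Optional[float]) -> Optional[float]:
        if a is None or b is None:
            return None
        one = Decimal("0.1")
        a_d = Decimal(repr(a)).quantize(one, rounding=ROUND_HALF_UP)
        b_d = Decimal(repr(b)).quantize(one, rounding=ROUND_HALF_UP)
        return float(((a_d + b_d) / 2).quantize(one, rounding=ROUND_HALF_UP))

    return Gaps(
        avg(gaps_f.prevalence_gap, gaps_m.prevalence_gap),
        avg(gaps_f.onset_gap, gaps_m.onset_gap),
        avg(gaps_f.duration_gap, gaps_m.duration_gap),
    )


def percent_reduction(gap_observed: float, gap_counterfactual: float) -> Optional[float]:
    """Percentage of the observed gap removed under the counterfactual."""
    if gap_observed == 0:
        warnings.warn("observed gap is zero; percent reduction undefined")
        return None
    return 100.0 * (gap_observed - gap_counterfactual) / gap_observed


def reduction_gaps(observed: Gaps, counterfactual: Gaps) -> Gaps:
    """Per-measure percent reductions (None where either gap is absent)."""

    def red(o: Optional[float], c: Optional[float]) -> Optional[float]:
        if o is None or c is None or o == 0:
            return None
        return 100.0 * (o - c) / o

    return Gaps(
        red(observed.prevalence_gap, counterfactual.prevalence_gap),
        red(observed.onset_gap, counterfactual.onset_gap),
        red(observed.duration_gap, counterfactual.duration_gap),
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

_MEASURES = ("prevalence_gap", "onset_gap", "duration_gap")


def build_report(
    scenario_stats: dict[str, dict[str, SummaryStats]],
    intervals: Optional[dict] = None,
) -> dict:
    """Assemble the inequality report.

    ``scenario_stats`` maps scenario name (``"observed"`` first, then
    counterfactual labels) to ``{stratum_label: SummaryStats}``.
    ``intervals`` optionally maps ``(stratum_label, measure)`` to interval
    estimates for the observed scenario.  Returns a JSON-serializable dict:
    per scenario the stratum summaries, per-sex gaps, sex-averaged gaps, and
    (for counterfactuals) percent reductions relative to ``"observed"``."""
    if "observed" not in scenario_stats:
        raise ValueError("scenario_stats must include an 'observed' scenario")

    report: dict = {"scenarios": {}}
    observed_gaps: dict[str, Gaps] = {}

    for scenario, stats in scenario_stats.items():
        block: dict = {"summaries": {}, "gaps": {}}
        for label, s in stats.items():
            entry = s.to_dict()
            entry.pop("age_grid", None)
            entry.pop("age_prevalence", None)
            if scenario == "observed" and intervals is not None:
                for measure_key, json_key in (
                    ("life_course_prevalence", "life_course_prevalence_ci"),
                    ("mean_age_onset", "mean_age_onset_ci"),
                    ("mean_duration", "mean_duration_ci"),
                ):
                    iv = intervals.get((label, measure_key))
                    if iv is not None:
                        entry[json_key] = [iv.lower, iv.upper]
            block["summaries"][label] = entry
        by_sex = {}
        for sex in ("female", "male"):
            low = stats.get(f"{sex}_low")
            high = stats.get(f"{sex}_high")
            if low is None or high is None:
                continue
            g = gaps(low, high)
            by_sex[sex] = g
            block["gaps"][sex] = vars(g)
        if len(by_sex) == 2:
            block["gaps"]["average"] = vars(sex_average(by_sex["female"], by_sex["male"]))
        if scenario == "observed":
            observed_gaps = by_sex
        elif observed_gaps:
            block["reductions"] = {}
            for sex, g in by_sex.items():
                if sex in observed_gaps:
                    block["reductions"][sex] = vars(
                        reduction_gaps(observed_gaps[sex], g)
                    )
        report["scenarios"][scenario] = block
    return report


def write_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def read_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def plot_gap_bars(report: dict, measure: str, path) -> None:
    """Bar chart of one gap measure across scenarios, annotated with the
    percent reduction relative to the observed scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = list(report["scenarios"])
    sexes = ("female", "male")
    fig, ax = plt.subplots(figsize=(8, 4.5))
    width = 0.38
    for j, sex in enumerate(sexes):
        values, labels = [], []
        for scenario in scenarios:
            block = report["scenarios"][scenario]
            g = block["gaps"].get(sex, {})
            v = g.get(measure)
            if v is None:
                continue
            values.append(v)
            red = block.get("reductions", {}).get(sex, {}).get(measure)
            labels.append("" if red is None else f"{red:.1f}%")
        x = [i + (j - 0.5) * width for i in range(len(values))]
        bars = ax.bar(x, values, width=width, label=sex)
        for bar, text in zip(bars, labels):
            if text:
                ax.annotate(
                    text,
                    (bar.get_x() + bar.get_width() / 2, bar.get_height()),
                    ha="center",
                    va="bottom",
                    fontsize=8,
                )
    ax.set_xticks(range(len(scenarios)))
    ax.set_xticklabels(scenarios, rotation=20, ha="right", fontsize=8)
    ax.set_ylabel(measure.replace("_", " "))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
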