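"""Estimate entry prevalence and age-group transition rates.

Reads ``results/cohort.csv``, fits the per-stratum logistic models, and
writes the annualized incidence and recovery rates per 5-year age group to
``results/rates.csv`` plus the MetS prevalence at age 18 to
``results/prevalence_at_18.json``.
"""

import argparse
import json
from pathlib import Path

from metsim.cohort import read_cohort_csv
from metsim.pipeline import estimate_all
from metsim.rates import write_rates_csv


def main(out_dir: str = "results") -> None:
    out = Path(out_dir)
    cohort = read_cohort_csv(out / "cohort.csv")
    estimates = estimate_all(cohort)

    write_rates_csv(
        estimates.rates["incidence"] + estimates.rates["recovery"], out / "rates.csv"
    )
    prev = {
        p.stratum.label: {"probability": p.probability, "se": p.se}
        for p in estimates.prevalence_at_18
    }
    (out / "prevalence_at_18.json").write_text(json.dumps(prev, indent=2))

    print(f"rates -> {out / 'rates.csv'}")
    print("prevalence of MetS at age 18 by stratum:")
    for p in estimates.prevalence_at_18:
        print(f"  {p.stratum.label:13s} {100 * p.probability:5.2f}%  (se {100 * p.se:.2f})")
    for kind in ("incidence", "recovery"):
        rates = estimates.rates[kind]
        lo = min(r.rate_per_year for r in rates)
        hi = max(r.rate_per_year for r in rates)
        print(f"{kind}: {len(rates)} age-group cells, rates {lo:.4f}-{hi:.4f} /yr")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--out-dir", default="results")
    main(parser.parse_args().out_dir)
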