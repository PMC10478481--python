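"""Parameterize the age-group rates as continuous-age curves.

Reads ``results/rates.csv``, fits a three-parameter logistic to each
stratum's incidence rates and a fourth-degree polynomial to its recovery
rates, reports the mean absolute error of each fit at the bin midpoints
(the internal-validity check), and writes ``results/curves.json``.
"""

import argparse
from pathlib import Path

from metsim.core import all_strata
from metsim.curves import curves_to_json, mean_absolute_error
from metsim.pipeline import fit_all_curves
from metsim.rates import read_rates_csv


def main(out_dir: str = "results") -> None:
    out = Path(out_dir)
    rates = read_rates_csv(out / "rates.csv")
    by_kind = {
        kind: [r for r in rates if r.kind == kind]
        for kind in ("incidence", "recovery")
    }
    curves = fit_all_curves(by_kind)
    (out / "curves.json").write_text(curves_to_json(list(curves.values())))

    print(f"curves -> {out / 'curves.json'}")
    print("mean absolute error at bin midpoints (/yr):")
    for kind in ("incidence", "recovery"):
        for s in all_strata():
            points = [r for r in by_kind[kind] if r.stratum == s]
            mae = mean_absolute_error(curves[(s.label, kind)], points)
            print(f"  {kind:9s} {s.label:13s} {mae:.5f}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--out-dir", default="results")
    main(parser.parse_args().out_dir)
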