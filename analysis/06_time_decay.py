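#!/usr/bin/env python
"""Time-decay of community similarity and recurrence classification.

Within each zone and nucleic-acid type, builds within-station
similarity-vs-days points (log10-log10), fits linear and quadratic models,
and classifies the turnover shape: linear_decay (open-water-like monotone
turnover), recurrent (lagoon-like annual return), or indeterminate.
"""

import argparse
from pathlib import Path

import pandas as pd

from paired16s import io
from paired16s.decay import compare_decay, decay_points


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panels/mass_effect"))
    ap.add_argument("--outdir", type=Path, default=Path("results/decay"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    records = io.read_metadata(args.panel / "metadata.tsv")
    all_points, fit_rows = [], []
    for kind in ("dna", "rna"):
        table = io.read_count_table(args.panel / f"{kind}_counts.tsv")
        for zone in ("Lagoon", "Seaward"):
            res = decay_points(table, records, zone, kind.upper())
            if res.n_dropped:
                print(f"{zone}/{kind}: dropped {res.n_dropped} zero-similarity pairs")
            all_points.append(res.points)
            label, lin, quad = compare_decay(res.points)
            for fit in (lin, quad):
                fit_rows.append(
                    {
                        "zone": zone,
                        "nucleic_acid": kind.upper(),
                        "model": fit.model,
                        "coefficients": ";".join(f"{c:.5f}" for c in fit.coefficients),
                        "adj_r2": fit.adj_r2,
                        "p": fit.p,
                        "n_points": fit.n_points,
                    }
                )
            print(
                f"{zone}/{kind.upper()}: {label} "
                f"(linear adjR2={lin.adj_r2:.3f}, quadratic adjR2={quad.adj_r2:.3f})"
            )
    pd.concat(all_points, ignore_index=True).to_csv(
        args.outdir / "decay_points.tsv", sep="\t", index=False
    )
    pd.DataFrame(fit_rows).to_csv(args.outdir / "decay_fits.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
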