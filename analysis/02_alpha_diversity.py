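#!/usr/bin/env python
"""Rarefy the panel and compute per-sample alpha diversity.

Samples are rarefied to a common depth (default 11,542 reads — the survey's
rarefaction depth; samples below it are excluded and reported), then ZOTU
richness, Shannon entropy and root-inclusive Faith's PD are written per
sample, with zone/month labels for downstream comparison.
"""

import argparse
from pathlib import Path

from paired16s import io
from paired16s.diversity import alpha_table, rarefy


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panels/mass_effect"))
    ap.add_argument("--outdir", type=Path, default=Path("results/alpha"))
    ap.add_argument("--depth", type=int, default=11_542)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    records = io.read_metadata(args.panel / "metadata.tsv")
    meta = io.records_frame(records)
    tree = io.read_newick(args.panel / "tree.nwk")
    for kind in ("dna", "rna"):
        table = io.read_count_table(args.panel / f"{kind}_counts.tsv")
        result = rarefy(table, depth=args.depth, seed=args.seed)
        if result.dropped:
            print(f"{kind}: dropped below depth {args.depth}: {result.dropped}")
        alpha = alpha_table(result.table, tree)
        alpha = alpha.join(meta[["station", "zone", "month"]])
        alpha.to_csv(args.outdir / f"alpha_{kind}.tsv", sep="\t")
        by_zone = alpha.groupby("zone")[["richness", "shannon", "pd"]].mean()
        print(f"{kind}: zone means\n{by_zone.round(3)}")


if __name__ == "__main__":
    main()
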