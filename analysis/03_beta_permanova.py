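#!/usr/bin/env python
"""Beta diversity: distance matrices, PCoA coordinates, and PERMANOVA.

For Bray-Curtis and Sørensen dissimilarity over all DNA+RNA samples:
writes the square distance matrix, PCoA coordinates with eigenvalues and
explained proportions, and a sequential PERMANOVA table quantifying month,
zone, nucleic-acid type and their interactions (999 permutations).
"""

import argparse
from pathlib import Path

import pandas as pd

from paired16s import io
from paired16s.beta import bray_curtis, pcoa, permanova_table, sorensen

TERMS = ["month", "zone", "nucleic_acid", "month:zone",
         "month:nucleic_acid", "zone:nucleic_acid"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panels/mass_effect"))
    ap.add_argument("--outdir", type=Path, default=Path("results/beta"))
    ap.add_argument("--permutations", type=int, default=999)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    dna = io.read_count_table(args.panel / "dna_counts.tsv")
    rna = io.read_count_table(args.panel / "rna_counts.tsv")
    combined = dna.concat(rna)
    meta = io.records_frame(io.read_metadata(args.panel / "metadata.tsv"))

    for name, metric in (("bray_curtis", bray_curtis), ("sorensen", sorensen)):
        dm = metric(combined)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            args.outdir / f"distance_{name}.tsv", sep="\t"
        )
        ord_ = pcoa(dm)
        coords = ord_.coords_frame()
        coords.to_csv(args.outdir / f"pcoa_coords_{name}.tsv", sep="\t")
        pd.DataFrame(
            {
                "eigenvalue": ord_.eigenvalues,
                "proportion_explained": ord_.proportion_explained,
            }
        ).to_csv(args.outdir / f"pcoa_eigenvalues_{name}.tsv", sep="\t", index=False)
        tab = permanova_table(
            dm, meta, TERMS, n_perm=args.permutations, seed=args.seed
        )
        tab.to_csv(args.outdir / f"permanova_{name}.tsv", sep="\t")
        print(f"{name}: PERMANOVA (sequential SS, {args.permutations} permutations)")
        print(tab.round(3))


if __name__ == "__main__":
    main()
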