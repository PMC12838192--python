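#!/usr/bin/env python
"""RNA:DNA 16S potential-activity ratios and zone dominance.

Applies the phantom-taxon correction (DNA=1 wherever RNA>0 and DNA=0, before
normalisation), then computes per-pair 16S ratios at the genus level
(collapse first, then adjust → normalise → divide) and for the top-50 ZOTUs,
L/(L+S) lagoon-vs-seaward matrices for both relative abundance and activity,
and Spearman screens against the environmental factors.
"""

import argparse
from pathlib import Path

import pandas as pd

from paired16s import io
from paired16s.activity import (
    collapse_taxonomy,
    dominance_matrix,
    phantom_adjust,
    ratio_16s,
    spearman_screen,
    to_proportions,
    top_n_zotus,
)
from paired16s.simulate import env_for_samples


def pair_meta(pairs):
    zone = pd.Series({p.pair_id: p.zone for p in pairs})
    month = pd.Series({p.pair_id: p.month for p in pairs})
    return zone, month


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panels/mass_effect"))
    ap.add_argument("--outdir", type=Path, default=Path("results/activity"))
    ap.add_argument("--top-n", type=int, default=50)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    dna = io.read_count_table(args.panel / "dna_counts.tsv")
    rna = io.read_count_table(args.panel / "rna_counts.tsv")
    taxonomy = io.read_taxonomy(args.panel / "taxonomy.tsv")
    records = io.read_metadata(args.panel / "metadata.tsv")
    env = io.read_env_table(args.panel / "environment.tsv")
    pairs = io.pair_samples(records).pairs
    zone, month = pair_meta(pairs)

    # genus level: collapse counts first, then adjust -> normalise -> ratio
    dna_gen = collapse_taxonomy(dna, taxonomy, "genus")
    rna_gen = collapse_taxonomy(rna, taxonomy, "genus")
    adj_gen = phantom_adjust(dna_gen, rna_gen, pairs)
    genus_ratios = ratio_16s(to_proportions(rna_gen), to_proportions(adj_gen), pairs)
    genus_ratios.to_csv(args.outdir / "genus_16s_ratios.tsv", sep="\t")

    # ZOTU level: top-N selection after whole-table normalisation
    adj = phantom_adjust(dna, rna, pairs)
    dna_prop, rna_prop = to_proportions(adj), to_proportions(rna)
    top, coverage = top_n_zotus(dna.concat(rna), n=args.top_n)
    print(f"top {args.top_n} ZOTUs cover {100 * coverage:.2f}% of all reads")
    zotu_ratios = ratio_16s(rna_prop, dna_prop, pairs).loc[top]
    zotu_ratios.to_csv(args.outdir / "top_zotu_16s_ratios.tsv", sep="\t")

    # L/(L+S): dominance from DNA relative abundance, activity from ratios
    dna_by_pair = dna_prop.loc[[p.dna_sample_id for p in pairs], top]
    dna_by_pair.index = [p.pair_id for p in pairs]
    dominance = dominance_matrix(dna_by_pair, zone, month)
    dominance.to_csv(args.outdir / "dominance_L_over_LS.tsv", sep="\t")
    activity = dominance_matrix(zotu_ratios.T, zone, month)
    activity.to_csv(args.outdir / "activity_L_over_LS.tsv", sep="\t")
    lagoon_led = (dominance > 0.5).sum().sum()
    total = dominance.notna().sum().sum()
    print(f"dominance matrix: {lagoon_led}/{total} taxon-months lagoon-dominant")

    # Spearman screens vs environment (per-sample values)
    env_s = env_for_samples(env, records)
    genus_rel = to_proportions(dna_gen)
    rho, p = spearman_screen(genus_rel, env_s.loc[genus_rel.index])
    rho.to_csv(args.outdir / "spearman_genus_env_rho.tsv", sep="\t")
    p.to_csv(args.outdir / "spearman_genus_env_p.tsv", sep="\t")
    n_sig = int((p < 0.05).sum().sum())
    print(f"genus-vs-environment screen: {n_sig} significant cells (raw P<0.05)")


if __name__ == "__main__":
    main()
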