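#!/usr/bin/env python
"""Simulate the paired DNA/RNA survey panels that the later steps analyse.

Writes, per assembly regime (mass_effect — the lagoon-like, water-mass-
dominated condition — and selection), a full fixture set: DNA and RNA ZOTU
tables, sample metadata, environmental factors, a phylogenetic tree over the
taxa, a synthetic taxonomy, and the generator's ground truth.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from paired16s import io
from paired16s.simulate import (
    SimulationParams,
    simulate_panel,
    simulate_taxonomy,
    simulate_tree,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/panels"))
    ap.add_argument("--seed", type=int, default=20220215)
    args = ap.parse_args()

    for regime in ("mass_effect", "selection"):
        params = SimulationParams(assembly_regime=regime, seed=args.seed)
        panel = simulate_panel(params)
        out = args.outdir / regime
        out.mkdir(parents=True, exist_ok=True)
        io.write_count_table(panel.dna, out / "dna_counts.tsv")
        io.write_count_table(panel.rna, out / "rna_counts.tsv")
        io.write_metadata(panel.records, out / "metadata.tsv")
        io.write_env_table(panel.env, out / "environment.tsv")
        taxa = panel.dna.taxon_ids
        io.write_newick(simulate_tree(taxa, seed=args.seed + 1), out / "tree.nwk")
        simulate_taxonomy(taxa, seed=args.seed + 2).write(out / "taxonomy.tsv")
        truth = {
            "assembly_regime": panel.truth.assembly_regime,
            "temporal_regime": panel.truth.temporal_regime,
            "n_injected_phantoms": len(panel.truth.injected_phantoms),
            "injected_phantoms": panel.truth.injected_phantoms,
            "params": dataclasses.asdict(params),
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        print(
            f"{regime}: {panel.dna.shape[0]} DNA + {panel.rna.shape[0]} RNA samples, "
            f"{panel.dna.shape[1]} taxa, "
            f"{len(panel.truth.injected_phantoms)} injected phantom cells -> {out}"
        )


if __name__ == "__main__":
    main()
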