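"""Rarefaction and alpha-diversity: richness, Shannon entropy, Faith's PD.

Conventions: Shannon uses the natural logarithm; Faith's phylogenetic
diversity is root-inclusive (the branch path from each observed tip up to the
root is counted, matching the picante ``include.root=TRUE`` convention — this
changes single-tip values, so it is stated explicitly). Rarefaction is a
single subsampling draw without replacement per sample, reproducible by seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import CountTable


@dataclass
class RarefactionResult:
    """Rarefied table plus the samples dropped for insufficient depth."""

    table: CountTable
    depth: int
    seed: int
    dropped: list[str] = field(default_factory=list)


def rarefy(table: CountTable, depth: int, seed: int) -> RarefactionResult:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are excluded and listed in
    the result (never silently dropped). Samples at exactly ``depth`` are
    returned unchanged. A multivariate hypergeometric draw per sample is the
    exact model of subsampling reads without replacement.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    out = np.empty((len(kept_ids), counts.shape[1]), dtype=np.int64)
    for i, row_idx in enumerate(np.flatnonzero(keep)):
        row = counts[row_idx]
        if totals[row_idx] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    rarefied = CountTable(
        pd.DataFrame(out, index=kept_ids, columns=table.taxon_ids)
    )
    return RarefactionResult(table=rarefied, depth=depth, seed=seed, dropped=dropped)


def richness(counts: np.ndarray) -> int:
    """Number of taxa observed (count > 0)."""
    counts = np.asarray(counts)
    if counts.size and counts.min() < 0:
        raise ValueError("negative counts")
    return int(np.count_nonzero(counts))


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy −Σ p_i ln p_i over positive proportions (natural log)."""
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0:
        raise ValueError("negative counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no Shannon entropy")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def faith_pd(counts: np.ndarray, taxon_ids: list[str], tree: TreeNode) -> float:
    """Faith's phylogenetic diversity, root-inclusive.

    Sum of branch lengths of the minimal subtree spanning the observed taxa
    and the root: every edge whose subtree contains at least one observed
    tip contributes its length.
    """
    counts = np.asarray(counts)
    observed = {t for t, c in zip(taxon_ids, counts) if c > 0}
    if not observed:
        return 0.0
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(observed - tip_names)
    if missing:
        raise ValueError(f"observed taxa absent from tree: {missing}")
    total = 0.0
    # postorder flag propagation: an edge counts iff its clade holds an
    # observed tip
    has_obs: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            flag = node.name in observed
        else:
            flag = any(has_obs[id(child)] for child in node.children)
        has_obs[id(node)] = flag
        if flag and node.parent is not None and node.length is not None:
            total += node.length
    return float(total)


def alpha_table(
    table: CountTable, tree: TreeNode | None = None
) -> pd.DataFrame:
    """Per-sample alpha diversity (richness, shannon, and pd if a tree is given)."""
    rows = {}
    for sid in table.sample_ids:
        vec = table.sample(sid)
        row = {"richness": richness(vec), "shannon": shannon(vec)}
        if tree is not None:
            row["pd"] = faith_pd(vec, table.taxon_ids, tree)
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
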