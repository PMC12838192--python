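"""RNA:DNA 16S ratios, phantom-taxon correction, and zone dominance ratios.

The RNA:DNA ratio of a taxon — its proportion in the 16S rRNA (transcript)
assemblage divided by its proportion in the 16S rRNA gene assemblage — is a
proxy for protein-synthesis potential ("potential activity"). Phantom taxa
(detected in RNA but absent in DNA of the same sample) would give a zero
denominator; the correction sets DNA = 1 read for every (RNA > 0, DNA = 0)
observation *before* normalising to proportions, which keeps every
RNA-positive taxon's ratio finite while perturbing the DNA profile by at
most one read per phantom cell.

Genus-level ratios are computed by collapsing counts to genus first and then
running adjust → normalise → ratio; summing counts before the ratio is the
only order under which the phantom rule stays well-defined at coarser ranks.

L/(L+S) compares a taxon's zone-mean value between the lagoon (L) and the
seaward (S) zone: 0.5 means parity, values toward 1 lagoon dominance, toward
0 seaward dominance; undefined (blank, never 0) when both zones are 0.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, SamplePair, TaxonomyMap


def _aligned(dna: CountTable, rna: CountTable) -> None:
    if dna.taxon_ids != rna.taxon_ids:
        raise ValueError("DNA and RNA tables must share an identical taxon ordering")


def phantom_adjust(
    dna: CountTable, rna: CountTable, pairs: Sequence[SamplePair]
) -> CountTable:
    """Return the DNA table with phantom cells (RNA > 0, DNA = 0) set to 1.

    Only cells of paired samples are touched; everything else is unchanged.
    """
    _aligned(dna, rna)
    out = dna.data.copy()
    for pair in pairs:
        d = out.loc[pair.dna_sample_id].to_numpy()
        r = rna.data.loc[pair.rna_sample_id].to_numpy()
        phantom = (r > 0) & (d == 0)
        if phantom.any():
            d = d.copy()
            d[phantom] = 1
            out.loc[pair.dna_sample_id] = d
    return CountTable(out)


def to_proportions(table: CountTable) -> pd.DataFrame:
    """Row-normalise counts to proportions (each sample sums to 1)."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cannot normalise all-zero sample(s): "
            f"{[table.sample_ids[i] for i in zero]}"
        )
    return pd.DataFrame(
        counts / totals[:, None], index=table.sample_ids, columns=table.taxon_ids
    )


def collapse_taxonomy(
    table: CountTable, taxonomy: TaxonomyMap, rank: str
) -> CountTable:
    """Sum counts within each ``rank``-level label.

    Taxa unclassified at ``rank`` are grouped under
    ``"unclassified <deepest classified name>"`` (e.g. a ZOTU known only to
    family Poseidoniaceae collapses to "unclassified Poseidoniaceae").
    """
    missing = [t for t in table.taxon_ids if t not in taxonomy]
    if missing:
        raise ValueError(f"taxa missing from taxonomy: {missing[:5]}")
    labels = [taxonomy.label_at(t, rank) for t in table.taxon_ids]
    collapsed = table.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    return CountTable(collapsed)


def ratio_16s(
    rna_prop: pd.DataFrame,
    dna_prop_adjusted: pd.DataFrame,
    pairs: Sequence[SamplePair],
) -> pd.DataFrame:
    """Per-taxon RNA:DNA proportion ratios, one column per pair.

    ``dna_prop_adjusted`` must come from a phantom-adjusted table, which
    guarantees a positive denominator wherever RNA > 0. Cells where both
    assemblages are 0 are undefined (NaN).
    """
    if list(rna_prop.columns) != list(dna_prop_adjusted.columns):
        raise ValueError("proportion tables must share taxon ordering")
    taxa = list(rna_prop.columns)
    out = {}
    for pair in pairs:
        r = rna_prop.loc[pair.rna_sample_id].to_numpy()
        d = dna_prop_adjusted.loc[pair.dna_sample_id].to_numpy()
        bad = (r > 0) & (d == 0)
        if bad.any():
            raise AssertionError(
                f"pair {pair.pair_id}: RNA-positive taxa with zero DNA proportion "
                "— ratio_16s requires a phantom-adjusted DNA table"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(d > 0, r / np.where(d > 0, d, 1.0), np.nan)
        out[pair.pair_id] = ratio
    return pd.DataFrame(out, index=pd.Index(taxa, name="taxon_id"))


def top_n_zotus(table: CountTable, n: int = 50) -> tuple[list[str], float]:
    """Top-``n`` taxa by total count over the whole dataset, plus coverage.

    Coverage is their summed count over the grand total. Rank ties at the
    cut are broken by lexicographic taxon id, so the selection is
    deterministic.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    totals = pd.Series(table.counts.sum(axis=0), index=table.taxon_ids)
    grand = totals.sum()
    ranked = totals.sort_index().sort_values(ascending=False, kind="stable")
    chosen = list(ranked.index[: min(n, len(ranked))])
    coverage = float(totals[chosen].sum() / grand) if grand > 0 else float("nan")
    return chosen, coverage


def dominance_ratio(lagoon_mean: float, seaward_mean: float) -> float:
    """L/(L+S); NaN (undefined) when both zone means are 0."""
    if lagoon_mean < 0 or seaward_mean < 0:
        raise ValueError("zone means must be non-negative")
    total = lagoon_mean + seaward_mean
    if total == 0:
        return float("nan")
    return lagoon_mean / total


def dominance_matrix(
    values: pd.DataFrame, sample_zone: pd.Series, sample_month: pd.Series
) -> pd.DataFrame:
    """Taxon × month L/(L+S) matrix from per-sample values.

    ``values`` is samples × taxa (relative abundances or per-pair ratios);
    each month's zone mean averages that zone's stations. Months missing a
    zone, or cells where both zone means are 0 (or unobserved), are NaN —
    serialised blank, never 0.
    """
    zones = sample_zone.loc[values.index]
    months = sample_month.loc[values.index]
    out = {}
    for month in sorted(months.unique()):
        in_month = months == month
        lag = values[in_month & (zones == "Lagoon")]
        sea = values[in_month & (zones == "Seaward")]
        if lag.empty or sea.empty:
            out[month] = pd.Series(np.nan, index=values.columns)
            continue
        l_mean = lag.mean(axis=0, skipna=True)
        s_mean = sea.mean(axis=0, skipna=True)
        total = l_mean + s_mean
        with np.errstate(invalid="ignore"):
            ratio = l_mean / total
        ratio[total == 0] = np.nan
        ratio[total.isna()] = np.nan
        out[month] = ratio
    mat = pd.DataFrame(out)
    mat.index.name = "taxon_id"
    mat.columns.name = "month"
    return mat


def spearman_screen(
    x_table: pd.DataFrame, env: pd.DataFrame, min_n: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p for every (x variable, env factor) cell.

    Average ranks for ties; p from the t approximation; pairs with fewer
    than ``min_n`` complete observations or a constant vector are NaN
    (flagged, not silently zeroed). P-values are raw (uncorrected), and a
    significance mask is conventionally applied at 0.05 downstream.
    """
    shared = x_table.index.intersection(env.index)
    x = x_table.loc[shared]
    e = env.loc[shared]
    rho = pd.DataFrame(np.nan, index=x.columns, columns=e.columns)
    pval = pd.DataFrame(np.nan, index=x.columns, columns=e.columns)
    for xc in x.columns:
        xv = x[xc].to_numpy(dtype=float)
        for ec in e.columns:
            ev = e[ec].to_numpy(dtype=float)
            ok = np.isfinite(xv) & np.isfinite(ev)
            if ok.sum() < min_n:
                continue
            a, b = xv[ok], ev[ok]
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue  # rho undefined for constant vectors
            r, p = stats.spearmanr(a, b)
            rho.loc[xc, ec] = r
            pval.loc[xc, ec] = p
    return rho, pval
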