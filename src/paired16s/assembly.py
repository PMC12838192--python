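"""Δ-distance inference of community assembly from DNA–RNA divergence.

For each DNA–RNA sample pair, the distance between the two assemblages is
measured inside the leading ordination subspace that cumulatively explains
75% of the variation — once in a Bray-Curtis (abundance-based) PCoA, giving
m_BC, and once in a Sørensen (incidence-based) PCoA, giving m_S. The
difference Δ = m_BC − m_S separates two assembly signatures:

* Δ < 0 — incidence-based divergence dominates: the DNA and RNA assemblages
  contain different taxa, the signature of water-mass effects / dispersal.
* Δ > 0 — abundance-based divergence dominates: the assemblages share taxa
  but at very different abundances, the signature of selection.

Only the sign and relative change of Δ are interpretable; absolute Δ values
are not comparable across datasets, and the API deliberately exposes no such
comparison.

Each metric's pair distance uses its own ordination's 75% axis count (the
two ordinations will generally retain different numbers of axes). The
ordination is computed jointly over all samples — both zones, all months,
DNA and RNA together.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .beta import Ordination, bray_curtis, n75_axes, pcoa, sorensen
from .io import CountTable, SamplePair

METRICS = ("bray_curtis", "sorensen")


def joint_ordination(dna_rna_table: CountTable, metric: str) -> Ordination:
    """Single PCoA over all (DNA and RNA) samples for one metric."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if dna_rna_table.shape[0] < 3:
        raise ValueError("joint ordination needs at least 3 samples")
    dm = bray_curtis(dna_rna_table) if metric == "bray_curtis" else sorensen(
        dna_rna_table
    )
    return pcoa(dm)


def paired_subspace_distance(
    ordination: Ordination,
    pairs: Sequence[SamplePair],
    fraction: float = 0.75,
) -> pd.Series:
    """Euclidean DNA–RNA distance per pair in the leading-``fraction`` subspace."""
    k = n75_axes(ordination, fraction)
    index = {sid: i for i, sid in enumerate(ordination.sample_ids)}
    coords = ordination.coordinates[:, :k]
    out = {}
    for pair in pairs:
        try:
            i, j = index[pair.dna_sample_id], index[pair.rna_sample_id]
        except KeyError as exc:
            raise ValueError(
                f"pair {pair.pair_id} member {exc.args[0]!r} missing from ordination"
            ) from exc
        out[pair.pair_id] = float(np.linalg.norm(coords[i] - coords[j]))
    s = pd.Series(out, name=f"m_{fraction:g}")
    s.attrs["n_axes"] = k
    return s


def delta_distance(m_bc: float, m_s: float) -> float:
    """Δ = m_BC − m_S (exact; no tolerance)."""
    if not (np.isfinite(m_bc) and np.isfinite(m_s)):
        raise ValueError("pair distances must be finite")
    if m_bc < 0 or m_s < 0:
        raise ValueError("pair distances must be non-negative")
    return m_bc - m_s


def paired_deltas(
    dna_rna_table: CountTable,
    pairs: Sequence[SamplePair],
    fraction: float = 0.75,
) -> pd.DataFrame:
    """Per-pair m_BC, m_S and Δ from joint ordinations of both metrics.

    Returns a frame indexed by pair id with columns station, zone, month,
    m_bc, m_s, delta, n_axes_bc, n_axes_s.
    """
    ord_bc = joint_ordination(dna_rna_table, "bray_curtis")
    ord_s = joint_ordination(dna_rna_table, "sorensen")
    m_bc = paired_subspace_distance(ord_bc, pairs, fraction)
    m_s = paired_subspace_distance(ord_s, pairs, fraction)
    rows = []
    for pair in pairs:
        mb, ms = m_bc[pair.pair_id], m_s[pair.pair_id]
        rows.append(
            {
                "pair_id": pair.pair_id,
                "station": pair.station,
                "zone": pair.zone,
                "month": pair.month,
                "m_bc": mb,
                "m_s": ms,
                "delta": delta_distance(mb, ms),
                "n_axes_bc": m_bc.attrs["n_axes"],
                "n_axes_s": m_s.attrs["n_axes"],
            }
        )
    return pd.DataFrame(rows).set_index("pair_id")


def regime_hint(mean_delta: float, eps: float = 0.0) -> str:
    """Classify a mean Δ: mass_effect (< −ε), selection (> +ε), else indeterminate."""
    if eps < 0:
        raise ValueError("dead-band eps must be non-negative")
    if mean_delta < -eps:
        return "mass_effect"
    if mean_delta > eps:
        return "selection"
    return "indeterminate"


def summarize_delta(deltas: pd.DataFrame, eps: float = 0.0) -> pd.DataFrame:
    """Zone × month Δ summary with per-station means and a regime hint.

    ``deltas`` is the output of :func:`paired_deltas`. Empty zone-month groups
    simply do not appear. The regime hint reads only the sign of the group
    mean (dead-band ε, default 0, configurable).
    """
    rows = []
    for (zone, month), grp in deltas.groupby(["zone", "month"], sort=True):
        per_station = grp.groupby("station")["delta"].mean().to_dict()
        mean_delta = float(grp["delta"].mean())
        rows.append(
            {
                "zone": zone,
                "month": month,
                "n_pairs": len(grp),
                "mean_delta": mean_delta,
                "station_means": per_station,
                "regime_hint": regime_hint(mean_delta, eps),
            }
        )
    return pd.DataFrame(rows)
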