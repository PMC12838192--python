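"""Beta diversity: Bray-Curtis / Sørensen dissimilarity, PCoA, the
cumulative-75% axis rule, and permutation PERMANOVA.

Bray-Curtis is the abundance-based dissimilarity
``BC(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i)``; Sørensen is its incidence-based
counterpart ``1 − 2a/(2a + b + c)``, identically Bray-Curtis computed on
presence/absence. The pair underpins the downstream DNA–RNA divergence
analysis, which contrasts abundance- and incidence-driven distances.

PCoA policy: classical scaling (double-centred −½D², eigendecomposition).
Negative eigenvalues are discarded without Cailliez/Lingoes correction and
explained-variation proportions are taken over positive eigenvalues only —
the leading-75% subspace rule only needs those proportions, and a correction
would perturb them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

#: relative eigenvalue magnitude below which an axis is treated as zero
EIG_TOL = 1e-10


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    from .io import CountTable

    if isinstance(table, CountTable):
        return table.counts.astype(float), table.sample_ids
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.index)
    raise TypeError(f"expected CountTable or DataFrame, got {type(table)!r}")


def _check_rows(mat: np.ndarray, ids: list[str]) -> None:
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    zero = np.flatnonzero(mat.sum(axis=1) == 0)
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[ids[i] for i in zero]}")


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample rows."""
    mat, ids = _as_matrix(table)
    _check_rows(mat, ids)
    condensed = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids)


def sorensen(table) -> DistanceMatrix:
    """Sørensen dissimilarity: Bray-Curtis on presence/absence."""
    mat, ids = _as_matrix(table)
    _check_rows(mat, ids)
    condensed = pdist((mat > 0).astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids)


@dataclass
class Ordination:
    """PCoA result: retained (positive-eigenvalue) axes only.

    ``proportion_explained`` is relative to the sum of positive eigenvalues,
    so it sums to 1 over the retained axes.
    """

    sample_ids: list[str]
    coordinates: np.ndarray  # samples × retained axes
    eigenvalues: np.ndarray  # descending, all > 0
    proportion_explained: np.ndarray

    def coords_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Classical multidimensional scaling of a distance matrix."""
    n = dm.shape[0]
    if n < 3:
        raise ValueError(f"PCoA needs at least 3 samples, got {n}")
    d2 = dm.data ** 2
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    gower = -0.5 * centerer @ d2 @ centerer
    gower = (gower + gower.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = EIG_TOL * max(eigvals.max(), 0.0) if eigvals.size else 0.0
    keep = eigvals > tol
    eigvals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(eigvals)
    total = eigvals.sum()
    prop = eigvals / total if total > 0 else eigvals
    return Ordination(
        sample_ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def n75_axes(ordination: Ordination, fraction: float = 0.75) -> int:
    """Smallest k whose leading axes cumulatively explain ≥ ``fraction``.

    The boundary is closed (a cumulative proportion exactly at the fraction
    qualifies).
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    cum = np.cumsum(ordination.proportion_explained)
    # small float slack so fraction=1.0 and exact-boundary ties behave closed
    hits = np.flatnonzero(cum >= fraction - 1e-12)
    if hits.size == 0:
        return len(cum)
    return int(hits[0]) + 1


@dataclass
class PermanovaResult:
    factor: str
    r2: float
    pseudo_f: float
    p: float
    n_permutations: int


def _within_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    factor: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F, raw-label permutation).

    ``p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)``, so the smallest
    attainable p is ``1/(n_perm + 1)``.
    """
    labels = np.asarray(pd.Categorical(np.asarray(groups)).codes)
    if labels.shape[0] != dm.shape[0]:
        raise ValueError("group labels must match distance matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    n = labels.size
    a = uniq.size
    d2 = dm.data ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _within_ss(d2, labels, uniq)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    # batch all permutations: indicator-matrix quadratic forms per group
    perms = np.empty((n_perm, n), dtype=np.int64)
    for i in range(n_perm):
        perms[i] = rng.permutation(n)
    perm_labels = labels[perms]  # n_perm × n
    ss_within_perm = np.zeros(n_perm)
    for g in uniq:
        z = (perm_labels == g).astype(float)  # n_perm × n
        n_g = counts[uniq == g][0]
        ss_within_perm += np.einsum("pi,ij,pj->p", z, d2, z) / (2.0 * n_g)
    ss_between_perm = ss_total - ss_within_perm
    f_perm = (ss_between_perm / (a - 1)) / (ss_within_perm / (n - a))
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermanovaResult(
        factor=factor, r2=float(r2), pseudo_f=float(f_obs), p=float(p),
        n_permutations=n_perm,
    )


def permanova_table(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Multi-factor PERMANOVA with sequential sums of squares.

    ``terms`` are metadata column names or ``"a:b"`` interactions, fitted in
    the stated order (main effects before interactions, mirroring the usual
    PERMANOVA table layout). Partitioning follows the distance-based linear
    model: the Gower-centred matrix is projected onto the cumulative design,
    and each term's SS is the increment in explained trace. P-values come
    from permuting sample identities (rows/columns of the centred matrix).
    """
    ids = list(dm.ids)
    meta = metadata.loc[ids]
    n = len(ids)
    d2 = dm.data ** 2
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    gower = -0.5 * centerer @ d2 @ centerer

    def design(term: str) -> np.ndarray:
        cols = term.split(":")
        combined = meta[cols[0]].astype(str)
        for c in cols[1:]:
            combined = combined + "␟" + meta[c].astype(str)
        return pd.get_dummies(combined).to_numpy(dtype=float)

    designs = [design(t) for t in terms]

    def hat(x: np.ndarray) -> np.ndarray:
        return x @ np.linalg.pinv(x)

    # cumulative-model hat matrices are permutation-invariant: precompute once
    hats, dfs = [], []
    cum = np.ones((n, 1))
    prev_hat = hat(cum)
    cum_rank = 1
    for x in designs:
        cum = np.hstack([cum, x])
        h = hat(cum)
        rank = np.linalg.matrix_rank(cum)
        hats.append((prev_hat, h))
        dfs.append(rank - cum_rank)
        prev_hat, cum_rank = h, rank
    df_resid = n - cum_rank

    def term_ss(g: np.ndarray) -> tuple[np.ndarray, float]:
        out = np.empty(len(terms))
        for k, (h_prev, h_cur) in enumerate(hats):
            out[k] = float(np.sum((h_cur - h_prev) * g.T))
        explained = float(np.sum(hats[-1][1] * g.T))
        return out, explained

    ss_terms, explained = term_ss(gower)
    ss_total = float(np.trace(gower))
    ss_resid = ss_total - explained
    ms_resid = ss_resid / df_resid
    f_obs = np.array(
        [ (ss / df) / ms_resid if df > 0 else np.nan
          for ss, df in zip(ss_terms, dfs) ]
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = gower[np.ix_(perm, perm)]
        ss_p, expl_p = term_ss(gp)
        ms_resid_p = (ss_total - expl_p) / df_resid
        f_p = np.array(
            [ (ss / df) / ms_resid_p if df > 0 else np.nan
              for ss, df in zip(ss_p, dfs) ]
        )
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {
            "factor": terms,
            "df": dfs,
            "R2": ss_terms / ss_total,
            "pseudo_F": f_obs,
            "p": pvals,
        }
    ).set_index("factor")
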