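"""Time-decay of community similarity and seasonal-recurrence detection.

Within each zone, every within-station ordered pair of sampling dates (for a
given nucleic-acid type) contributes one point: Bray-Curtis similarity
(1 − dissimilarity) against the number of days between observations. Both
axes are log10-transformed before ordinary least squares. A significant
negative linear slope with no curvature is the classic distance-decay of
similarity; a U shape — an initial decline followed by recovery toward the
annual revisit — indicates seasonal recurrence and is captured by a
quadratic term that is significantly positive.

Pairs are within-station only and pooled across the zone's stations:
cross-station pairs would conflate spatial and temporal turnover.
Zero-similarity points are not log-transformable and are dropped with a
reported count (no pseudo-count).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import braycurtis

from .io import CountTable, SampleRecord


@dataclass
class DecayPointsResult:
    points: pd.DataFrame  # station, zone, nucleic_acid, days_between, similarity
    n_dropped: int  # zero-similarity pairs (not log-transformable)


@dataclass
class DecayFit:
    model: str  # "linear" | "quadratic"
    coefficients: np.ndarray  # intercept, slope[, quadratic] on log10 axes
    adj_r2: float
    p: float  # model F-test
    n_points: int
    coef_pvalues: np.ndarray  # per-coefficient two-sided t-test


def decay_points(
    table: CountTable,
    records: Sequence[SampleRecord],
    zone: str,
    nucleic_acid: str,
) -> DecayPointsResult:
    """Similarity-vs-days points for one zone and nucleic-acid type."""
    recs = [
        r
        for r in records
        if r.zone == zone
        and r.nucleic_acid == nucleic_acid
        and r.sample_id in table.data.index
    ]
    stations = sorted({r.station for r in recs})
    if not stations:
        raise ValueError(f"no stations with samples for zone {zone!r}")
    rows, dropped = [], 0
    for station in stations:
        st = sorted(
            (r for r in recs if r.station == station), key=lambda r: r.date
        )
        for r1, r2 in itertools.combinations(st, 2):
            days = (r2.date - r1.date).days
            if days <= 0:
                continue
            sim = 1.0 - braycurtis(
                table.sample(r1.sample_id).astype(float),
                table.sample(r2.sample_id).astype(float),
            )
            if sim <= 0:
                dropped += 1
                continue
            rows.append(
                {
                    "station": station,
                    "zone": zone,
                    "nucleic_acid": nucleic_acid,
                    "days_between": days,
                    "similarity": sim,
                }
            )
    return DecayPointsResult(points=pd.DataFrame(rows), n_dropped=dropped)


def _design(log_days: np.ndarray, model: str) -> np.ndarray:
    if model == "linear":
        return sm.add_constant(log_days)
    if model == "quadratic":
        return sm.add_constant(np.column_stack([log_days, log_days ** 2]))
    raise ValueError(f"model must be 'linear' or 'quadratic', got {model!r}")


def fit_decay(points: pd.DataFrame, model: str = "linear") -> DecayFit:
    """OLS of log10(similarity) on log10(days) (plus its square if quadratic)."""
    x = np.log10(points["days_between"].to_numpy(dtype=float))
    y = np.log10(points["similarity"].to_numpy(dtype=float))
    design = _design(x, model)
    k = design.shape[1] - 1
    if len(y) < k + 3:
        raise ValueError(f"too few points ({len(y)}) for a {model} fit")
    if np.allclose(x, x[0]):
        raise ValueError("all time lags identical: singular design")
    res = sm.OLS(y, design).fit()
    return DecayFit(
        model=model,
        coefficients=np.asarray(res.params),
        adj_r2=float(res.rsquared_adj),
        p=float(res.f_pvalue),
        n_points=len(y),
        coef_pvalues=np.asarray(res.pvalues),
    )


def _station_level_terms(points: pd.DataFrame) -> tuple | None:
    """Per-station slope and quadratic coefficients with across-station t-tests.

    Within a station the 66 pairs reuse the same 12 samples, so pooled OLS
    t-tests drastically overstate the evidence for curvature. Stations are
    the independent replicates within a zone: each station's points get
    their own fits, and the coefficients are t-tested across stations.
    Returns None when fewer than 3 stations have enough points.
    """
    slopes, quads = [], []
    for _, grp in points.groupby("station"):
        if len(grp) < 6:
            continue
        x = np.log10(grp["days_between"].to_numpy(dtype=float))
        y = np.log10(grp["similarity"].to_numpy(dtype=float))
        slopes.append(sm.OLS(y, _design(x, "linear")).fit().params[1])
        quads.append(sm.OLS(y, _design(x, "quadratic")).fit().params[2])
    if len(slopes) < 3:
        return None
    _, p_slope = stats.ttest_1samp(slopes, 0.0)
    _, p_quad = stats.ttest_1samp(quads, 0.0)
    return float(np.mean(slopes)), float(p_slope), float(np.mean(quads)), float(p_quad)


def compare_decay(
    points: pd.DataFrame, alpha: float = 0.05
) -> tuple[str, DecayFit, DecayFit]:
    """Classify the turnover shape: linear_decay, recurrent, or indeterminate.

    recurrent — quadratic term significantly positive and the quadratic fit's
    adjusted R² exceeds the linear fit's; linear_decay — linear slope
    significantly negative while the quadratic term is not significant;
    otherwise indeterminate.

    Coefficient significance is judged at the station level when at least
    three stations contribute points (see :func:`_station_level_terms`);
    with fewer stations it falls back to the pooled OLS t-tests.
    """
    lin = fit_decay(points, "linear")
    quad = fit_decay(points, "quadratic")
    by_station = _station_level_terms(points)
    if by_station is not None:
        slope, p_slope, quad_coef, quad_p = by_station
    else:
        slope, p_slope = lin.coefficients[1], lin.coef_pvalues[1]
        quad_coef, quad_p = quad.coefficients[2], quad.coef_pvalues[2]
    if quad_coef > 0 and quad_p < alpha and quad.adj_r2 > lin.adj_r2:
        label = "recurrent"
    elif slope < 0 and p_slope < alpha and quad_p >= alpha:
        label = "linear_decay"
    else:
        label = "indeterminate"
    return label, lin, quad
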