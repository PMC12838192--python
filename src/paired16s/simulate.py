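"""Synthetic paired DNA/RNA community panels with known ground truth.

The generator emulates the downstream structure of a 6-station (2 lagoon +
4 seaward) × 12-month × {DNA, RNA} amplicon survey:

* a lognormal species-abundance distribution (few dominant taxa, long rare
  tail), with zone-preferring taxon blocks;
* seasonal taxon dynamics — either a 12-month sinusoidal modulation of log
  abundances (``recurrent``: the community returns toward its starting
  composition at the annual revisit) or a cumulative random-walk drift
  (``drift``: monotone divergence from the initial composition);
* an RNA (active) assemblage derived from the DNA (total) assemblage by the
  assembly regime — ``selection``: same taxon support, per-taxon
  multiplicative activity factors (abundance-driven DNA–RNA divergence);
  ``mass_effect``: a fraction of non-dominant resident taxa replaced by a
  disjoint immigrant block (incidence-driven divergence);
* multinomial read sampling at fixed depth (every emitted row sums to the
  depth exactly);
* injected phantom cells (RNA > 0, DNA = 0), listed in the ground truth;
* environmental covariates with known linear couplings to the latent season
  and zone signals.

All randomness flows from one seed through named
``numpy.random.SeedSequence`` child streams, so every output is reproducible
and sub-streams are independent by construction.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .assembly import paired_deltas
from .decay import compare_decay, decay_points
from .io import CountTable, SampleRecord, TaxonomyMap, pair_samples, records_frame

#: sampling campaign: monthly, February through the following January
_START_YEAR, _START_MONTH, _SAMPLING_DAY = 2022, 2, 15

ENV_FACTORS = (
    "temperature", "salinity", "pH", "DO", "ORP", "SP", "chl_a",
    "NH4", "NO3", "NO2", "PO4", "FDOM_C1", "FDOM_C2", "FDOM_C3",
)


@dataclass
class SimulationParams:
    """Study-design and noise parameters of one synthetic panel.

    Defaults reflect the emulated survey: 2 lagoon + 4 seaward stations,
    12 monthly visits, sequencing depth 12,000 reads per sample, and a
    lognormal abundance spread (σ = 1.5 in log space) dominated by a few
    taxa.
    """

    n_stations_lagoon: int = 2
    n_stations_seaward: int = 4
    n_months: int = 12
    n_taxa: int = 150  # resident taxa
    n_immigrant_taxa: int = 50  # disjoint pool used by the mass_effect regime
    depth: int = 12_000
    assembly_regime: str = "selection"  # or "mass_effect"
    temporal_regime: str = "recurrent"  # or "drift"
    phantom_rate: float = 0.05  # expected fraction of taxa injected per pair
    abundance_lognormal_sigma: float = 1.5
    zone_effect: float = 1.0  # log-units added/subtracted for zone-preferring taxa
    seasonal_amplitude: float = 2.0  # max per-taxon sinusoid amplitude (log units)
    drift_similarity_1mo: float = 0.8  # drift target: mean similarity at 1-month lag
    drift_similarity_11mo: float = 0.55  # drift target: mean similarity at 11-month lag
    station_sigma: float = 0.15  # per station-month log noise (shared by DNA/RNA)
    rna_noise_sigma: float = 0.3  # extra per-sample log noise on the RNA profile
    activity_sigma: float = 1.0  # log-spread of per-taxon activity factors (selection)
    swap_fraction: float = 0.3  # fraction of residents swapped out (mass_effect)
    n_protected: int = 30  # top residents never swapped/damped (dominants persist)
    seed: int = 0

    def validate(self) -> None:
        if self.n_stations_lagoon < 1 or self.n_stations_seaward < 1:
            raise ValueError("need at least one station per zone")
        if self.n_months < 2:
            raise ValueError("need at least 2 months")
        if self.n_taxa < 2 or self.depth < 1:
            raise ValueError("n_taxa and depth must be positive")
        if not (0 <= self.phantom_rate < 1):
            raise ValueError("phantom_rate must be in [0, 1)")
        if self.abundance_lognormal_sigma <= 0:
            raise ValueError("abundance_lognormal_sigma must be > 0")
        if self.assembly_regime not in ("selection", "mass_effect"):
            raise ValueError(f"unknown assembly_regime {self.assembly_regime!r}")
        if self.temporal_regime not in ("recurrent", "drift"):
            raise ValueError(f"unknown temporal_regime {self.temporal_regime!r}")
        if not (0 <= self.swap_fraction < 1):
            raise ValueError("swap_fraction must be in [0, 1)")
        if self.assembly_regime == "mass_effect" and self.n_immigrant_taxa < 1:
            raise ValueError("mass_effect regime needs an immigrant pool")
        if not (0 < self.drift_similarity_11mo < self.drift_similarity_1mo < 1):
            raise ValueError(
                "drift similarity targets must satisfy 0 < 11mo < 1mo < 1"
            )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    assembly_regime: str
    temporal_regime: str
    zone_preference: pd.Series  # per resident taxon: Lagoon / Seaward / none
    activity_log: pd.Series | None  # per-taxon log activity factors (selection)
    injected_phantoms: list[dict] = field(default_factory=list)


@dataclass
class Panel:
    dna: CountTable
    rna: CountTable
    records: list[SampleRecord]
    env: pd.DataFrame  # station-date rows × environmental factors
    truth: GroundTruth


def _month_dates(n_months: int) -> list[_dt.date]:
    dates = []
    year, month = _START_YEAR, _START_MONTH
    for _ in range(n_months):
        dates.append(_dt.date(year, month, _SAMPLING_DAY))
        month += 1
        if month > 12:
            month, year = 1, year + 1
    return dates


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_panel(params: SimulationParams) -> Panel:
    """Generate one paired DNA/RNA panel with metadata, environment, truth."""
    params.validate()
    p = params
    rng = _streams(
        p.seed,
        ["taxa", "temporal", "station", "rna", "counts", "phantom", "env"],
    )

    n_res, n_imm = p.n_taxa, p.n_immigrant_taxa
    res_taxa = [f"ZOTU{i + 1}" for i in range(n_res)]
    imm_taxa = [f"IMM{i + 1}" for i in range(n_imm)]
    taxa = res_taxa + imm_taxa

    # resident community skeleton: lognormal SAD + zone preference blocks
    base = rng["taxa"].normal(0.0, p.abundance_lognormal_sigma, n_res)
    pref_code = rng["taxa"].choice([-1, 0, 1], size=n_res, p=[0.3, 0.4, 0.3])
    zone_pref = pd.Series(
        np.where(pref_code == 1, "Lagoon", np.where(pref_code == -1, "Seaward", "none")),
        index=res_taxa,
        name="zone_preference",
    )
    # immigrants arrive at moderate abundance (narrower spread, no dominants)
    imm_base = rng["taxa"].normal(0.0, 1.0, n_imm)

    # temporal structure: a shared seasonal sinusoid (recurrent), or
    # per-station power-law drift trajectories (drift; see _drift_factor)
    drift_damping = np.ones(n_res)
    drift_factor_matrix = None
    month_effect = None
    if p.temporal_regime == "recurrent":
        amp = rng["temporal"].uniform(0.0, p.seasonal_amplitude, n_res)
        phase = rng["temporal"].uniform(0.0, p.n_months, n_res)
        month_effect = np.stack(
            [
                amp * np.cos(2 * np.pi * (m - phase) / p.n_months)
                for m in range(p.n_months)
            ]
        )  # months × taxa
    else:
        n_damped = min(p.n_protected, n_res)
        if n_damped:
            drift_damping[np.argsort(base)[-n_damped:]] = 0.4
        drift_factor_matrix = _drift_factor(base, drift_damping, p, rng["temporal"])

    activity_log = None
    if p.assembly_regime == "selection":
        activity_log = pd.Series(
            rng["taxa"].normal(0.0, p.activity_sigma, n_res),
            index=res_taxa,
            name="activity_log",
        )

    stations = [f"L{i + 1}" for i in range(p.n_stations_lagoon)] + [
        f"S{i + 1}" for i in range(p.n_stations_seaward)
    ]
    zones = {s: ("Lagoon" if s.startswith("L") else "Seaward") for s in stations}
    dates = _month_dates(p.n_months)

    # mass_effect swaps target the rare-to-mid abundance ranks: immigrant
    # water masses add/remove many low-abundance taxa while the dominant
    # residents persist — an incidence signature with little abundance mass
    swappable = np.argsort(base)[: n_res - min(p.n_protected, n_res)]
    n_swap = int(round(p.swap_fraction * n_res))

    records: list[SampleRecord] = []
    dna_rows, rna_rows, sample_ids = {}, {}, []
    truth_phantoms: list[dict] = []

    for station in stations:
        zone_sign = 1.0 if zones[station] == "Lagoon" else -1.0
        if p.temporal_regime == "drift":
            # each station drifts independently (within-station pairs are
            # the time-decay unit; stations are independent replicates)
            month_effect = (
                drift_factor_matrix
                @ rng["temporal"].normal(0.0, 1.0, (p.n_months, n_res))
            ) * drift_damping
        for m_idx, date in enumerate(dates):
            log_dna = (
                base
                + p.zone_effect * zone_sign * pref_code
                + month_effect[m_idx]
                + rng["station"].normal(0.0, p.station_sigma, n_res)
            )
            # RNA latent profile per assembly regime
            if p.assembly_regime == "selection":
                log_rna = (
                    log_dna
                    + activity_log.to_numpy()
                    + rng["rna"].normal(0.0, p.rna_noise_sigma, n_res)
                )
                imm_log_rna = np.full(n_imm, -np.inf)
            else:
                log_rna = log_dna + rng["rna"].normal(0.0, p.rna_noise_sigma, n_res)
                out_idx = rng["rna"].choice(
                    swappable, size=min(n_swap, swappable.size), replace=False
                )
                log_rna[out_idx] = -np.inf
                imm_log_rna = np.full(n_imm, -np.inf)
                in_idx = rng["rna"].choice(
                    n_imm, size=min(n_swap, n_imm), replace=False
                )
                imm_log_rna[in_idx] = imm_base[in_idx] + rng["rna"].normal(
                    0.0, p.rna_noise_sigma, in_idx.size
                )

            full_dna = np.concatenate([log_dna, np.full(n_imm, -np.inf)])
            full_rna = np.concatenate([log_rna, imm_log_rna])

            dna_counts = rng["counts"].multinomial(p.depth, _softmax(full_dna))
            rna_counts = rng["counts"].multinomial(p.depth, _softmax(full_rna))

            dna_id = f"{station}_{date.isoformat()}_DNA"
            rna_id = f"{station}_{date.isoformat()}_RNA"
            for sid, na in ((dna_id, "DNA"), (rna_id, "RNA")):
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        station=station,
                        zone=zones[station],
                        date=date,
                        nucleic_acid=na,
                    )
                )

            # phantom injection: create (RNA>0, DNA=0) cells by moving reads
            # from the most abundant RNA taxon, preserving the row total
            n_total = n_res + n_imm
            n_inject = rng["phantom"].binomial(n_total, p.phantom_rate)
            candidates = np.flatnonzero((dna_counts == 0) & (rna_counts == 0))
            if n_inject > 0 and candidates.size > 0:
                chosen = rng["phantom"].choice(
                    candidates, size=min(n_inject, candidates.size), replace=False
                )
                donor = int(np.argmax(rna_counts))
                for tix in chosen:
                    k = int(rng["phantom"].integers(1, 4))
                    if rna_counts[donor] <= k + 1:
                        break
                    rna_counts[donor] -= k
                    rna_counts[tix] += k
                    truth_phantoms.append(
                        {
                            "dna_sample_id": dna_id,
                            "rna_sample_id": rna_id,
                            "taxon_id": taxa[tix],
                            "rna_reads": k,
                        }
                    )

            dna_rows[dna_id] = dna_counts
            rna_rows[rna_id] = rna_counts
            sample_ids.append((dna_id, rna_id))

    dna = CountTable(
        pd.DataFrame.from_dict(dna_rows, orient="index", columns=taxa)
    )
    rna = CountTable(
        pd.DataFrame.from_dict(rna_rows, orient="index", columns=taxa)
    )
    env = _simulate_env(stations, zones, dates, rng["env"])
    truth = GroundTruth(
        assembly_regime=p.assembly_regime,
        temporal_regime=p.temporal_regime,
        zone_preference=zone_pref,
        activity_log=activity_log,
        injected_phantoms=truth_phantoms,
    )
    return Panel(dna=dna, rna=rna, records=records, env=env, truth=truth)


def _gp_factor(gamma: np.ndarray, n_months: int) -> np.ndarray:
    """Factor matrix A of a stationary Gaussian process with structure
    function ``gamma`` over month lags (trajectory = A @ iid-normal)."""
    lag = np.abs(np.arange(n_months)[:, None] - np.arange(n_months)[None, :])
    g = gamma[lag]
    cov = g.max() / 2.0 - g / 2.0
    vals, vecs = np.linalg.eigh(cov)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _mean_logsim_by_lag(
    factor: np.ndarray,
    damping: np.ndarray,
    base: np.ndarray,
    p: "SimulationParams",
    rng: np.random.Generator,
    n_draws: int,
) -> np.ndarray:
    """Monte-Carlo mean log10 Bray-Curtis similarity per month lag for the
    full generative chain (trajectory + station noise + multinomial reads)."""
    from scipy.spatial.distance import braycurtis

    n_res = base.size
    sums = np.zeros(p.n_months - 1)
    counts = np.zeros(p.n_months - 1)
    for _ in range(n_draws):
        traj = (factor @ rng.normal(0.0, 1.0, (p.n_months, n_res))) * damping
        profiles = []
        for m in range(p.n_months):
            lam = base + traj[m] + rng.normal(0.0, p.station_sigma, n_res)
            profiles.append(
                rng.multinomial(p.depth, _softmax(lam)).astype(float)
            )
        for i in range(p.n_months):
            for j in range(i + 1, p.n_months):
                sim = max(1.0 - braycurtis(profiles[i], profiles[j]), 1e-3)
                sums[j - i - 1] += np.log10(sim)
                counts[j - i - 1] += 1
    return sums / counts


def _drift_factor(
    base: np.ndarray,
    damping: np.ndarray,
    p: "SimulationParams",
    rng: np.random.Generator,
    n_iter: int = 6,
) -> np.ndarray:
    """Gaussian-process factor whose trajectories yield power-law time decay.

    The drift regime is defined by its decay law: expected log similarity
    falls linearly in log lag between the 1-month and 11-month targets (the
    canonical distance-decay form). Because read sampling, station noise and
    the abundance distribution all bend the map from log-abundance
    displacement to observed similarity, the month-lag structure function is
    calibrated in closed loop: simulate the full chain, compare realized
    mean log-similarity per lag with the target line, and adjust.
    """
    lags = np.arange(1, p.n_months)
    max_lag = p.n_months - 1
    slope = (
        np.log10(p.drift_similarity_1mo) - np.log10(p.drift_similarity_11mo)
    ) / np.log10(max_lag)
    target = np.log10(p.drift_similarity_1mo) - slope * np.log10(lags)
    floor = -_mean_logsim_by_lag(
        np.zeros((p.n_months, p.n_months)), damping, base, p, rng, n_draws=6
    ).mean()
    gamma = np.zeros(p.n_months)
    gamma[1:] = (0.8 * np.log1p(lags)) ** 2
    for it in range(n_iter):
        factor = _gp_factor(gamma, p.n_months)
        real = _mean_logsim_by_lag(factor, damping, base, p, rng, n_draws=20)
        excess_target = np.maximum(-target - floor, 1e-3)
        excess_real = np.maximum(-real - floor, 1e-3)
        step = 1.3 if it < 3 else 0.8  # damp late iterations
        gamma[1:] *= np.clip((excess_target / excess_real) ** step, 0.5, 2.0)
    return _gp_factor(gamma, p.n_months)


def _softmax(log_abund: np.ndarray) -> np.ndarray:
    finite = np.isfinite(log_abund)
    out = np.zeros_like(log_abund)
    shifted = log_abund[finite] - log_abund[finite].max()
    ex = np.exp(shifted)
    out[finite] = ex / ex.sum()
    return out


def _simulate_env(
    stations: list[str],
    zones: dict[str, str],
    dates: list[_dt.date],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Station-date environmental factors with known season/zone couplings.

    ``season`` peaks in August (warmest); the lagoon runs fresher, less
    turbid, lower-nitrate, and richer in humus-like FDOM (C2) than the
    seaward zone. Concentrations are clipped at 0 (below detection limit is
    recorded as 0, a valid observation).
    """
    rows = {}
    for station in stations:
        lag = 1.0 if zones[station] == "Lagoon" else 0.0
        for m_idx, date in enumerate(dates):
            s = np.cos(2 * np.pi * (m_idx - 6) / 12)  # index 6 = August
            e = rng.normal
            row = {
                "temperature": 17.0 + 9.0 * s + e(0, 0.8),
                "salinity": 26.0 - 3.0 * lag + e(0, 0.7),
                "pH": 8.05 + 0.08 * s + e(0, 0.05),
                "DO": 9.0 - 2.5 * s + e(0, 0.5),
                "ORP": 160.0 - 35.0 * s + e(0, 12.0),
                "SP": 35.0 - 15.0 * lag + e(0, 6.0),
                "chl_a": 2.5 + 1.2 * s + 0.8 * lag + e(0, 0.6),
                "NH4": 0.06 + 0.02 * lag + e(0, 0.02),
                "NO3": 0.45 - 0.18 * lag + e(0, 0.08),
                "NO2": 0.05 + 0.01 * s + e(0, 0.015),
                "PO4": 0.05 - 0.015 * lag + e(0, 0.01),
                "FDOM_C1": 0.30 + 0.10 * s + e(0, 0.05),
                "FDOM_C2": 0.50 + 0.25 * lag + e(0, 0.07),
                "FDOM_C3": 0.35 + 0.08 * s + e(0, 0.05),
            }
            rows[f"{station}:{date.isoformat()}"] = {
                k: max(v, 0.0) for k, v in row.items()
            }
    env = pd.DataFrame.from_dict(rows, orient="index", columns=list(ENV_FACTORS))
    env.index.name = "station_date"
    return env


def env_for_samples(env: pd.DataFrame, records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Broadcast station-date environment rows to per-sample rows."""
    keys = {r.sample_id: f"{r.station}:{r.date.isoformat()}" for r in records}
    out = env.loc[[keys[r.sample_id] for r in records]].copy()
    out.index = pd.Index([r.sample_id for r in records], name="sample_id")
    return out


def simulate_tree(taxon_ids: Sequence[str], seed: int) -> TreeNode:
    """Random rooted bifurcating tree over ``taxon_ids``, exponential branch
    lengths (mean 1)."""
    ids = list(taxon_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=t, length=float(rng.exponential(1.0))) for t in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def simulate_taxonomy(
    taxon_ids: Sequence[str], seed: int, unclassified_fraction: float = 0.2
) -> TaxonomyMap:
    """Synthetic archaeal-style lineages (labels are synthetic, not real taxa).

    Taxa are nested into 2 phyla / 3 classes / 4 orders / 6 families /
    12 genera; a fraction is left unclassified at genus level so the
    "unclassified <family>" collapse path is exercised.
    """
    rng = np.random.default_rng(seed)
    lineages = {}
    n_phyla, n_classes, n_orders, n_families, n_genera = 2, 3, 4, 6, 12
    for t in taxon_ids:
        g = int(rng.integers(n_genera))
        f = g % n_families
        o = f % n_orders
        c = o % n_classes
        ph = c % n_phyla
        lin = [
            "Archaea",
            f"Phylum{ph + 1}",
            f"Class{c + 1}",
            f"Order{o + 1}",
            f"Family{f + 1}",
            f"Genus{g + 1}",
        ]
        if rng.random() < unclassified_fraction:
            lin[5] = None  # unclassified at genus → collapses to family label
        lineages[t] = lin
    return TaxonomyMap(lineages)


def regime_recovery_experiment(
    params: SimulationParams,
    n_replicates: int,
    seed: int,
) -> dict:
    """Run the full Δ-distance and time-decay pipeline over replicate panels.

    Per replicate: simulate a panel under ``params`` (with a child seed),
    pair the samples, compute the grand mean Δ over all DNA–RNA pairs, and
    classify the temporal regime from the DNA time-decay points of all six
    stations (the temporal regime is panel-wide, so both zones' within-
    station points inform the classification). Reports the fraction of
    replicates whose inferred regimes match the generator's truth.
    """
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    mean_deltas, decay_labels, quad_better = [], [], []
    for rep in range(n_replicates):
        rep_params = SimulationParams(**{**params.__dict__, "seed": int(child_seeds[rep])})
        panel = simulate_panel(rep_params)
        pairing = pair_samples(panel.records)
        combined = panel.dna.concat(panel.rna)
        deltas = paired_deltas(combined, pairing.pairs)
        mean_deltas.append(float(deltas["delta"].mean()))
        pts = pd.concat(
            [
                decay_points(panel.dna, panel.records, zone, "DNA").points
                for zone in ("Lagoon", "Seaward")
            ],
            ignore_index=True,
        )
        label, lin, quad = compare_decay(pts)
        decay_labels.append(label)
        quad_better.append(quad.adj_r2 > lin.adj_r2)
    want_sign = 1.0 if params.assembly_regime == "selection" else -1.0
    want_label = (
        "recurrent" if params.temporal_regime == "recurrent" else "linear_decay"
    )
    mean_deltas = np.asarray(mean_deltas)
    return {
        "assembly_regime": params.assembly_regime,
        "temporal_regime": params.temporal_regime,
        "n_replicates": n_replicates,
        "mean_deltas": mean_deltas.tolist(),
        "delta_sign_accuracy": float(np.mean(np.sign(mean_deltas) == want_sign)),
        "decay_labels": decay_labels,
        "decay_accuracy": float(np.mean([lb == want_label for lb in decay_labels])),
        "quad_better_fraction": float(np.mean(quad_better)),
    }
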