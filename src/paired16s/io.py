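"""Domain types and file I/O for paired DNA/RNA amplicon studies.

The central object is the :class:`CountTable` — a samples × taxa matrix of
non-negative integer read counts (ZOTU/ASV counts). Samples carry metadata
(:class:`SampleRecord`) describing station, zone (lagoon vs seaward), calendar
date and nucleic-acid type (DNA = total community, RNA = potentially active
community). DNA and RNA samples taken from the same station on the same day
form a :class:`SamplePair`, the unit of the downstream DNA–RNA divergence and
RNA:DNA ratio analyses.

On-disk formats are plain TSV (count tables in the common taxa × samples
amplicon dialect by default) and newick for trees.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

ZONES = ("Lagoon", "Seaward")
NUCLEIC_ACIDS = ("DNA", "RNA")

#: rank ladder used for taxonomy collapse (genus is the finest rank analysed)
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class CountTable:
    """Samples × taxa matrix of non-negative integer read counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa, values non-negative integers.

    Raises
    ------
    ValueError
        On negative entries, non-integer values, or duplicate row/column ids.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        arr = data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            # accept float frames that are exactly integral (e.g. parsed TSV)
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))
                i, j = bad[0]
                raise ValueError(
                    f"non-integer count at sample {data.index[i]!r}, "
                    f"taxon {data.columns[j]!r}: {arr[i, j]!r}"
                )
            arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {data.index[i]!r}, "
                f"taxon {data.columns[j]!r}: {arr[i, j]}"
            )
        self._data = pd.DataFrame(
            arr.astype(np.int64, copy=False),
            index=data.index.astype(str),
            columns=data.columns.astype(str),
        )

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def sample(self, sample_id: str) -> np.ndarray:
        """Count vector of one sample."""
        return self._data.loc[sample_id].to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self._data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return CountTable(self._data.loc[list(sample_ids)])

    def concat(self, other: "CountTable") -> "CountTable":
        """Stack two tables sample-wise; taxon sets are unioned (missing → 0)."""
        merged = pd.concat([self._data, other._data], axis=0).fillna(0)
        return CountTable(merged)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self._data.equals(other._data)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"<CountTable {n} samples x {m} taxa>"


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata; (station, date, nucleic_acid) is the sample key."""

    sample_id: str
    station: str
    zone: str
    date: _dt.date
    nucleic_acid: str

    def __post_init__(self):
        if self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r} (expected one of {ZONES})")
        if self.nucleic_acid not in NUCLEIC_ACIDS:
            raise ValueError(
                f"unknown nucleic acid {self.nucleic_acid!r} "
                f"(expected one of {NUCLEIC_ACIDS})"
            )

    @property
    def month(self) -> int:
        """Calendar month (1–12) derived from the sampling date."""
        return self.date.month


@dataclass(frozen=True)
class SamplePair:
    """DNA and RNA samples from the same station and date."""

    dna_sample_id: str
    rna_sample_id: str
    station: str
    zone: str
    date: _dt.date

    @property
    def month(self) -> int:
        return self.date.month

    @property
    def pair_id(self) -> str:
        return f"{self.station}:{self.date.isoformat()}"


@dataclass
class PairingResult:
    """Pairs found plus samples that could not be paired (never dropped silently)."""

    pairs: list[SamplePair]
    unpaired: list[str] = field(default_factory=list)


class TaxonomyMap:
    """taxon_id → lineage (domain … species); unclassified ranks are None."""

    def __init__(self, lineages: Mapping[str, Sequence[str | None]]):
        self._lineages: dict[str, tuple[str | None, ...]] = {}
        for taxon, lineage in lineages.items():
            lin = tuple(lineage)
            if len(lin) > len(RANKS):
                raise ValueError(f"lineage for {taxon!r} longer than {len(RANKS)} ranks")
            lin = lin + (None,) * (len(RANKS) - len(lin))
            self._lineages[str(taxon)] = lin

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def lineage(self, taxon: str) -> tuple[str | None, ...]:
        return self._lineages[taxon]

    def label_at(self, taxon: str, rank: str) -> str:
        """Collapse label at ``rank``: the name there, or an explicit
        ``unclassified <deepest classified name>`` marker."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        lin = self._lineages[taxon]
        idx = RANKS.index(rank)
        name = lin[idx]
        if name is not None:
            return name
        known = [x for x in lin[:idx] if x is not None]
        if known:
            return f"unclassified {known[-1]}"
        return "unclassified"

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_id\tlineage\n")
            for taxon, lin in self._lineages.items():
                joined = ";".join("" if x is None else x for x in lin)
                fh.write(f"{taxon}\t{joined}\n")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"taxon_id", "lineage"} <= set(df.columns):
        raise ValueError("taxonomy file needs columns: taxon_id, lineage")
    lineages = {}
    for _, row in df.iterrows():
        parts = [p if p else None for p in str(row["lineage"]).split(";")]
        lineages[row["taxon_id"]] = parts
    return TaxonomyMap(lineages)


# ---------------------------------------------------------------------------
# count tables


def read_count_table(
    path: str | Path, orientation: str = "taxa_by_samples"
) -> CountTable:
    """Read a TSV count table.

    ``orientation`` declares the file layout: ``"taxa_by_samples"`` (the common
    amplicon dialect, first column = taxon ids; default) or
    ``"samples_by_taxa"``. The returned table is always samples × taxa.
    """
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa_by_samples":
        df = df.T
    return CountTable(df)


def write_count_table(
    table: CountTable, path: str | Path, orientation: str = "taxa_by_samples"
) -> None:
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = table.data
    if orientation == "taxa_by_samples":
        df = df.T
        df.index.name = "taxon_id"
    else:
        df = df.copy()
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# metadata


def read_metadata(
    path: str | Path, station_zone: Mapping[str, str] | None = None
) -> list[SampleRecord]:
    """Read a sample metadata TSV.

    Required columns: sample_id, station, zone, date (ISO-8601), nucleic_acid.
    If ``station_zone`` (a station → zone map, typically from the study config)
    is given, each row's zone is validated against it rather than trusted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "station", "zone", "date", "nucleic_acid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        date = _dt.date.fromisoformat(row["date"])
        zone = row["zone"]
        if station_zone is not None:
            expected = station_zone.get(row["station"])
            if expected is None:
                raise ValueError(f"station {row['station']!r} not in station→zone map")
            if zone != expected:
                raise ValueError(
                    f"sample {row['sample_id']!r}: zone {zone!r} contradicts "
                    f"configured zone {expected!r} for station {row['station']!r}"
                )
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                station=row["station"],
                zone=zone,
                date=date,
                nucleic_acid=row["nucleic_acid"],
            )
        )
    keys = [(r.station, r.date, r.nucleic_acid) for r in records]
    if len(set(keys)) != len(keys):
        seen, dups = set(), []
        for k in keys:
            if k in seen:
                dups.append(k)
            seen.add(k)
        raise ValueError(f"duplicate (station, date, nucleic_acid) keys: {dups}")
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "station": r.station,
            "zone": r.zone,
            "date": r.date.isoformat(),
            "nucleic_acid": r.nucleic_acid,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def records_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id (month column included)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "station": r.station,
            "zone": r.zone,
            "date": r.date,
            "month": r.month,
            "nucleic_acid": r.nucleic_acid,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def pair_samples(records: Sequence[SampleRecord]) -> PairingResult:
    """Match DNA and RNA samples by (station, date).

    Every (station, date) cell holding both a DNA and an RNA sample yields one
    :class:`SamplePair`; samples in incomplete cells are returned in
    ``unpaired``. Output order is sorted by (station, date) and therefore
    independent of input order.
    """
    by_key: dict[tuple[str, _dt.date], dict[str, SampleRecord]] = {}
    for r in records:
        by_key.setdefault((r.station, r.date), {})[r.nucleic_acid] = r
    pairs, unpaired = [], []
    for (station, date), cell in sorted(by_key.items()):
        if "DNA" in cell and "RNA" in cell:
            pairs.append(
                SamplePair(
                    dna_sample_id=cell["DNA"].sample_id,
                    rna_sample_id=cell["RNA"].sample_id,
                    station=station,
                    zone=cell["DNA"].zone,
                    date=date,
                )
            )
        else:
            unpaired.extend(sorted(r.sample_id for r in cell.values()))
    if unpaired:
        warnings.warn(f"{len(unpaired)} sample(s) could not be DNA-RNA paired")
    return PairingResult(pairs=pairs, unpaired=unpaired)


# ---------------------------------------------------------------------------
# trees


def read_newick(path: str | Path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises format-specific errors
        raise ValueError(f"could not parse newick file {path}: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dups = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tip labels in tree: {dups}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    if n_missing:
        warnings.warn(f"{n_missing} branch length(s) missing; set to 0")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# environment table and config


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Environmental factors, rows keyed by sample or station-date id.

    Zeros are valid observations (below-detection-limit values are recorded
    as 0, not missing).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    out = env.copy()
    out.index.name = out.index.name or "id"
    out.to_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """YAML study config: station→zone map, rarefaction depth, seeds."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
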