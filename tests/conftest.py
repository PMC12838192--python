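import datetime as dt

import numpy as np
import pandas as pd
import pytest

from paired16s.io import CountTable, SampleRecord
from paired16s.simulate import SimulationParams, simulate_panel


@pytest.fixture
def small_table() -> CountTable:
    """2 samples x 3 taxa with known counts."""
    return CountTable(
        pd.DataFrame(
            [[1, 2, 3], [4, 5, 6]],
            index=["s1", "s2"],
            columns=["t1", "t2", "t3"],
        )
    )


def make_records(stations=("A", "B"), zones=None, n_months=1, types=("DNA", "RNA")):
    """Build a metadata grid: stations x months x nucleic-acid types."""
    zones = zones or {s: "Lagoon" for s in stations}
    records = []
    for station in stations:
        for m in range(n_months):
            year, month = (2022, 2 + m) if m < 11 else (2023, m - 10)
            date = dt.date(year, month, 15)
            for na in types:
                records.append(
                    SampleRecord(
                        sample_id=f"{station}_{date.isoformat()}_{na}",
                        station=station,
                        zone=zones[station],
                        date=date,
                        nucleic_acid=na,
                    )
                )
    return records


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel, shared across tests (read-only)."""
    return simulate_panel(SimulationParams(seed=1234))


@pytest.fixture(scope="session")
def small_panel_params():
    """Reduced panel size for tests that simulate repeatedly."""
    return SimulationParams(n_taxa=80, n_immigrant_taxa=30, depth=4000, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
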