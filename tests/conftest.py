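import numpy as np
import pandas as pd
import pytest

from cryptmap import synthetic as syn


@pytest.fixture
def small_config():
    return syn.SimulationConfig(lattice_nx=6, lattice_ny=6, rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_record(counts: dict, depths: dict, crypt_id=0, x=0.0, y=0.0,
                condition="NA") -> pd.Series:
    """Hand-built crypt record row following the TSV schema."""
    row = {"crypt_id": crypt_id, "sample_id": "S1", "condition": condition,
           "x_um": x, "y_um": y}
    total = 0
    wdepth = 0.0
    for taxon, c in counts.items():
        row[f"count_{taxon}"] = c
        row[f"depth_{taxon}"] = depths.get(taxon, np.nan)
        total += c
        if c > 0 and np.isfinite(depths.get(taxon, np.nan)):
            wdepth += c * depths[taxon]
    row["count_total"] = total
    row["depth_total"] = wdepth / total if total else np.nan
    return pd.Series(row)
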