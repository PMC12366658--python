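import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import chimeradecomp as cd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def random_quartets():
    """10,000 strictly positive random quartets as a DataFrame."""
    r = np.random.default_rng(42)
    vals = 2.0 ** r.normal(0.0, 2.0, size=(10_000, 4))
    return pd.DataFrame(
        vals,
        columns=["HM", "HR", "DM", "DR"],
        index=pd.Index([f"g{i:05d}" for i in range(10_000)], name="gene_id"),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic chimera dataset used across ingest/pipeline tests."""
    return cd.generate_chimera_counts(
        300,
        cells_per_combo={"HM": 120, "HR": 120, "DM": 60, "DR": 40},
        seed=7,
    )


@pytest.fixture(scope="session")
def recovered(small_dataset):
    """Full ingest -> normalize -> decompose chain on the small dataset."""
    res = cd.ingest_dataset(small_dataset.adata)
    table = res.tables["synthetic"]
    norm = cd.normalize_resampled(table, n_reps=30, seed=7)
    dec = cd.decompose_table(norm)
    return {"ingest": res, "table": table, "norm": norm, "dec": dec}
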