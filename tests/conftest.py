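import numpy as np
import pandas as pd
import pytest

import plasmarna as pr
from plasmarna.io import CountMatrix, SampleTable

#: published-scale fold changes planted on the first ten foreground transcripts
PLANTED_FCS = np.array([4.25, 0.50, 2.34, 0.61, 2.27, 0.54, 2.97, 1.71, 1.95, 2.02])
PLANTED_IDS = [f"FG{i + 1:04d}" for i in range(10)]


@pytest.fixture(scope="session")
def planted_dataset():
    """First-trimester cohort with ten planted signature-scale fold changes."""
    cfg = pr.SimulationConfig(rng_seed=5, fold_changes=PLANTED_FCS,
                              second_trimester=(0, 0))
    ds = pr.simulate_dataset(cfg)
    cm, meta = ds.first_trimester()
    return ds, cm, meta


@pytest.fixture(scope="session")
def null_dataset():
    """Cohort with no condition effects anywhere."""
    cfg = pr.SimulationConfig(rng_seed=17, fold_changes=None, coupling=None,
                              second_trimester=(0, 0))
    ds = pr.simulate_dataset(cfg)
    cm, meta = ds.first_trimester()
    return ds, cm, meta


@pytest.fixture(scope="session")
def signature():
    return pr.load_pe_signature()


def make_counts(counts: np.ndarray, prefix_t="T", prefix_s="S",
                biotype="miRNA") -> CountMatrix:
    T, S = counts.shape
    return CountMatrix([f"{prefix_t}{i}" for i in range(T)], [biotype] * T,
                       [f"{prefix_s}{j}" for j in range(S)], counts)


def make_metadata(conditions, batches=None, **extra) -> SampleTable:
    n = len(conditions)
    return SampleTable(pd.DataFrame({
        "sample_id": [f"S{j}" for j in range(n)],
        "condition": list(conditions),
        "batch": list(batches) if batches is not None else ["B1"] * n,
        **extra,
    }))
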