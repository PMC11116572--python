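import numpy as np
import pandas as pd
import pytest

from soilconet.datatypes import METALS, PHYSCHEM, AbundanceTable, SampleFrame
from soilconet.synthetic import SyntheticConfig, simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_table():
    counts = pd.DataFrame(
        {
            "T1": [5, 0, 3, 10],
            "T2": [1, 2, 0, 0],
            "T3": [1, 8, 2, 5],
            "T4": [2, 0, 0, 1],
        },
        index=["S1", "S2", "S3", "S4"],
    )
    lineage = pd.DataFrame(
        {
            "phylum": ["P1", "P1", "P2", "P2"],
            "class": ["c"] * 4,
            "order": ["o"] * 4,
            "family": ["f"] * 4,
            "genus": ["gA", "gB", "gC", "gD"],
        },
        index=["T1", "T2", "T3", "T4"],
    )
    return AbundanceTable(counts, "bacteria", lineage)


@pytest.fixture()
def small_meta():
    rows = []
    rng = np.random.default_rng(7)
    for i, group in enumerate(["contaminated"] * 2 + ["uncontaminated"] * 2):
        row = {"group": group}
        for m in METALS:
            row[m] = float(rng.uniform(0.1, 5.0))
        for v in PHYSCHEM:
            row[v] = float(rng.uniform(1, 100))
        rows.append(row)
    return SampleFrame(pd.DataFrame(rows, index=["S1", "S2", "S3", "S4"]))


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic dataset shared across read-only tests."""
    cfg = SyntheticConfig(seed=42)
    meta, bact, fungi, truth = simulate(cfg)
    return cfg, meta, bact, fungi, truth
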