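import numpy as np
import pandas as pd
import pytest

import e2atlas as ea


@pytest.fixture
def small_design():
    return ea.ExperimentDesign(
        conditions=["E2a", "E2b", "E2c", "E2d"],
        batch_of={"E2a": 1, "E2b": 1, "E2c": 2, "E2d": 2},
        n_proteins=60)


@pytest.fixture
def tiny_abundance():
    """Hand-built two-batch matrix with one clean up-regulation."""
    meta = pd.DataFrame(
        {"condition": ["E2a"] * 3 + ["NT"] * 4,
         "batch": [1] * 7,
         "replicate": [1, 2, 3, 1, 2, 3, 4],
         "is_control": [False] * 3 + [True] * 4},
        index=pd.Index([f"s{i}" for i in range(7)], name="sample"))
    values = pd.DataFrame(
        [[1.0, 1.2, 1.1, 0.0, 0.1, -0.1, 0.0],   # regulated
         [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0]],   # flat
        index=pd.Index(["p1", "p2"], name="protein"), columns=meta.index)
    return ea.AbundanceMatrix(values=values, sample_meta=meta)


@pytest.fixture
def ipms_table():
    lengths = {f"PRY{i:02d}": 300 + 10 * i for i in range(20)}
    baits = ["B1", "B2"]
    lengths.update({b: 250 for b in baits})
    edges = [(b, f"PRY{(5 * i + j):02d}", 20.0)
             for i, b in enumerate(baits) for j in range(5)]
    return ea.simulate_ipms_counts(
        edges, contaminants={"PRY19": 3.0}, lengths=lengths, seed=11)
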