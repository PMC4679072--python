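import numpy as np
import pandas as pd
import pytest

import batchaudit as ba


@pytest.fixture
def seesaw_design():
    """Two groups split 1:5 and 5:1 between two batches (n = 12)."""
    return ba.design_from_counts([[1, 5], [5, 1]], groups=("A", "B"))


@pytest.fixture
def seesaw_annotation():
    rows = []
    for i, counts in enumerate([[1, 5], [5, 1]], start=1):
        for j, c in enumerate(counts):
            for r in range(c):
                rows.append(
                    {
                        "sample": f"b{i}g{j}r{r}",
                        "batch": f"batch{i}",
                        "group": "AB"[j],
                    }
                )
    return pd.DataFrame(rows)


def random_design(rng, m_max=5, M_max=4, cell_max=20, connected=False):
    """Random non-degenerate design: every batch and group non-empty."""
    while True:
        m = rng.integers(1, m_max + 1)
        M = rng.integers(1, M_max + 1)
        counts = rng.integers(0, cell_max + 1, size=(m, M))
        if (counts.sum(axis=1) < 1).any() or (counts.sum(axis=0) < 1).any():
            continue
        d = ba.design_from_counts(counts)
        if connected and not d.is_connected():
            continue
        if connected and d.n - d.M - d.m + 1 < 1:
            continue
        return d


def null_matrix(design, n_features, rng, sigma=1.0):
    vals = rng.normal(0.0, sigma, size=(n_features, design.n))
    return ba.ExpressionMatrix(
        vals,
        tuple(f"g{k}" for k in range(n_features)),
        design.sample_ids,
    )
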