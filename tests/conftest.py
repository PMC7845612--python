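import numpy as np
import pandas as pd
import pytest

from woodweb import InteractionMatrix, OtuTable


@pytest.fixture
def small_table() -> OtuTable:
    """2 trees x 2 replicates x 1 compartment, 4 OTUs."""
    counts = pd.DataFrame(
        [[10, 5, 0, 1], [8, 6, 1, 0], [0, 2, 9, 7], [1, 1, 8, 9]],
        index=["oakA", "oakB", "pineA", "pineB"],
        columns=["otu1", "otu2", "otu3", "otu4"],
    )
    meta = pd.DataFrame(
        {
            "resource": ["Quercus", "Quercus", "Pinus", "Pinus"],
            "compartment": ["sapwood"] * 4,
            "replicate": ["p1", "p2", "p1", "p2"],
        },
        index=counts.index,
    )
    return OtuTable(counts, meta)


@pytest.fixture
def two_compartment_table() -> OtuTable:
    rng = np.random.default_rng(7)
    ids, meta, rows = [], [], []
    for tree in ("Fagus", "Picea", "Tilia"):
        for comp in ("sapwood", "heartwood"):
            for rep in ("p1", "p2", "p3"):
                ids.append(f"{tree}_{comp}_{rep}")
                meta.append({"resource": tree, "compartment": comp, "replicate": rep})
                rows.append(rng.integers(0, 30, size=6))
    counts = pd.DataFrame(rows, index=ids, columns=[f"o{i}" for i in range(6)])
    return OtuTable(counts, pd.DataFrame(meta, index=ids))


def random_matrix(rng, max_rows=4, max_cols=5, max_nodes=9, integer=True):
    """A random valid InteractionMatrix, small enough for exhaustive search."""
    nr = int(rng.integers(2, max_rows + 1))
    nc = int(rng.integers(2, min(max_nodes - nr, max_cols) + 1))
    while True:
        if integer:
            W = rng.integers(0, 5, size=(nr, nc)).astype(float)
        else:
            W = np.round(rng.random((nr, nc)) * (rng.random((nr, nc)) > 0.3), 3)
        if W.sum() > 0:
            return InteractionMatrix(W)
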