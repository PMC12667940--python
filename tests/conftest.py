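import numpy as np
import pandas as pd
import pytest

from pseudocascade import (
    CellOrdering,
    ExpressionMatrix,
    CascadeAnalysis,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def ref_sim():
    """Reference synthetic study: 300 cells, 150/150/100/100 patterned genes
    plus 100 nulls, amplitude 1, noise sd 0.3.  Shared across tests; results
    objects must not be mutated."""
    cfg = SimulationConfig(seed=11)
    ds = simulate_dataset(cfg)
    res = CascadeAnalysis(ds.matrices["s1"], ds.orderings["s1"]).fit()
    return cfg, ds, res


@pytest.fixture(scope="session")
def ref_truth(ref_sim):
    _, ds, _ = ref_sim
    return ds.truth.set_index("gene")["pattern"].to_dict()


@pytest.fixture
def tiny_matrix():
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 5, size=(3, 4))
    return ExpressionMatrix(("g1", "g2", "g3"), ("c1", "c2", "c3", "c4"), values)


@pytest.fixture
def tiny_ordering():
    return CellOrdering.from_ranks(["c1", "c2", "c3", "c4"])


def brute_force_switches(x):
    """Independent oracle: naive scan for strict sign products < 0."""
    return [i + 1 for i in range(len(x) - 1) if x[i] * x[i + 1] < 0]


def brute_force_bh(p):
    """Independent BH oracle: sort, multiply by m/rank, cumulative minimum
    from the largest rank, cap at 1, undo the sort."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
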