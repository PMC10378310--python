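import networkx as nx
import numpy as np
import pandas as pd
import pytest

from spreadfs import LabeledDataset, Network


def net_from_edges(edges, name="test"):
    g = nx.Graph()
    g.add_edges_from(edges)
    return Network(g, name=name)


@pytest.fixture
def triangle():
    return net_from_edges([(0, 1), (1, 2), (0, 2)], "triangle")


@pytest.fixture
def path3():
    # a--b--c as 0--1--2
    return net_from_edges([(0, 1), (1, 2)], "path3")


@pytest.fixture
def star5():
    # centre 0 with four leaves
    return net_from_edges([(0, i) for i in range(1, 5)], "star5")


@pytest.fixture
def k4():
    return net_from_edges([(i, j) for i in range(4) for j in range(i + 1, 4)], "K4")


def planted_dataset(seed, n=300, f=0.15, with_duplicate=True, gap=2.0):
    """Tabular dataset with one informative feature and noise columns.

    The positive class (a top-f fraction) is separated from the negative
    class by a clear margin along the informative column, mimicking a
    noiseless threshold-on-centrality labelling rule.  Optionally the
    informative column is duplicated verbatim.
    """
    rng = np.random.default_rng(seed)
    n_pos = round(f * n)
    info = np.concatenate([rng.normal(gap + 1.0, 0.5, n_pos),
                           rng.normal(0.0, 0.5, n - n_pos)])
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n - n_pos, dtype=int)])
    perm = rng.permutation(n)
    info, y = info[perm], y[perm]
    cols = {"K": info}
    if with_duplicate:
        cols["Ksum"] = info.copy()
    cols.update({"C": rng.normal(size=n), "B": rng.normal(size=n),
                 "CC": rng.normal(size=n)})
    return LabeledDataset(pd.DataFrame(cols), y, {"planted": "K"})
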