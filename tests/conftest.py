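import os

import numpy as np
import pytest

from ghcdti.hetgraph import NODE_TYPES, RELATIONS, HeteroGraph, add_self_loops
from ghcdti.synthetic import tiny_fixture

FIXTURE_DIR = os.path.join(os.path.dirname(__file__), "fixtures", "tiny")


@pytest.fixture(scope="session")
def tiny():
    return tiny_fixture()


@pytest.fixture
def tiny_graph(tiny):
    return tiny[0]


def random_graph(rng: np.random.Generator, n_drug=5, n_protein=6, n_disease=3,
                 n_se=3, density=0.4) -> HeteroGraph:
    """Small random heterogeneous graph for oracle tests."""
    counts = {"drug": n_drug, "protein": n_protein, "disease": n_disease,
              "side_effect": n_se}
    adj = {}
    for rel, (s, d) in RELATIONS.items():
        A = (rng.random((counts[s], counts[d])) < density).astype(np.float64)
        if s == d:
            A = np.maximum(A, A.T)
            A = add_self_loops(A)
        adj[rel] = A
    sim = {}
    for t in ("drug", "protein"):
        S = rng.random((counts[t], counts[t]))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        sim[t] = S
    names = {t: [f"{t}_{i}" for i in range(n)] for t, n in counts.items()}
    return HeteroGraph(node_counts=counts, adj=adj, sim=sim, names=names).validate()


def random_features(rng: np.random.Generator, g: HeteroGraph, dim=8) -> dict:
    return {t: rng.standard_normal((g.node_counts[t], dim)) for t in NODE_TYPES}
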