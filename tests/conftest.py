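"""Shared fixtures and independent oracles for the test suite.

networkx serves as the independent graph oracle (acyclicity, topological
order); scikit-learn as the independent AUC oracle.  Both are test-only
dependencies — the package implements its own machinery.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from bninfer import (
    Dataset, Network, draw_weights, paper_design, raf_gold_standard,
    simulate_gaussian,
)

NAMES3 = ("A", "B", "C")


def nx_digraph(net: Network) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.node_names)
    g.add_edges_from(net.edges())
    return g


def nx_is_acyclic(net: Network) -> bool:
    return nx.is_directed_acyclic_graph(nx_digraph(net))


def skeleton_and_vstructures(net: Network):
    """Independent extraction of the Markov-class invariants of a DAG."""
    adj = net.adjacency
    n = net.n_nodes
    skel = frozenset(
        frozenset((i, j)) for i in range(n) for j in range(n) if adj[i, j]
    )
    vstructs = set()
    for c in range(n):
        parents = [i for i in range(n) if adj[i, c]]
        for a, b in itertools.combinations(parents, 2):
            if not adj[a, b] and not adj[b, a]:
                vstructs.add((frozenset((a, b)), c))
    return skel, frozenset(vstructs)


def brute_force_moves(net: Network, fan_in: int):
    """Every conceivable single-edge change, filtered for validity."""
    adj = net.adjacency
    n = net.n_nodes
    valid = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if not adj[i, j]:
                cand = adj.copy()
                cand[i, j] = True
                c = Network(net.node_names, cand)
                if nx_is_acyclic(c) and cand[:, j].sum() <= fan_in:
                    valid.append(("add", (i, j)))
            else:
                valid.append(("delete", (i, j)))
                cand = adj.copy()
                cand[i, j] = False
                cand[j, i] = True
                c = Network(net.node_names, cand)
                if nx_is_acyclic(c) and cand[:, i].sum() <= fan_in:
                    valid.append(("reverse", (i, j)))
    return valid


def random_dag(n: int, rng, p_edge: float = 0.4, fan_in: int | None = None) -> Network:
    """A random labelled DAG via a random topological order."""
    order = rng.permutation(n)
    adj = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p_edge:
                i, j = order[a], order[b]
                if fan_in is None or adj[:, j].sum() < fan_in:
                    adj[i, j] = True
    return Network(tuple(f"X{k}" for k in range(n)), adj)


def chain3_dataset(n_records: int = 50, seed: int = 1) -> Dataset:
    """Gaussian data from the chain A -> B -> C.

    The noise level (0.8 against unit-scale signals) keeps the conditional
    independence A _|_ C | B detectable at moderate sample sizes; with
    near-deterministic links the exact posterior genuinely favours a third
    edge, which would make structure-recovery expectations meaningless.
    """
    rng = np.random.default_rng(seed)
    x = np.empty((n_records, 3))
    x[:, 0] = rng.normal(0.0, 1.0, n_records)
    x[:, 1] = 1.5 * x[:, 0] + rng.normal(0.0, 0.8, n_records)
    x[:, 2] = -1.2 * x[:, 1] + rng.normal(0.0, 0.8, n_records)
    return Dataset(x, NAMES3)


@pytest.fixture(scope="session")
def raf():
    return raf_gold_standard()


@pytest.fixture(scope="session")
def raf_dataset(raf):
    weights = draw_weights(raf, seed=11)
    return simulate_gaussian(raf, weights, paper_design(), seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def data3():
    return chain3_dataset()
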