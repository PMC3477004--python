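"""Directed-graph machinery for Bayesian-network structure inference.

A network structure is a labelled DAG stored as a boolean adjacency matrix
(row = parent, column = child).  This module provides acyclicity checking,
the single-edge proposal neighbourhood used by the structure-MCMC samplers,
exhaustive DAG enumeration for small systems (the test/posterior oracle),
and conversion of DAGs to the completed partially directed graph (CPDAG)
of their Markov-equivalence class — plain, or refined by interventions
(transition-sequence equivalence).

Internally most algorithms work on parent *bitmasks* (one integer per node
whose set bits are the node's parents); this keeps the MCMC inner loop cheap
for the 11-node systems this package targets.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Network",
    "Cpdag",
    "InterventionSet",
    "is_acyclic",
    "topological_order",
    "neighbor_moves",
    "enumerate_dags",
    "dag_to_cpdag",
    "ts_cpdag",
    "read_network_tsv",
    "write_network_tsv",
    "read_network_csv",
    "write_network_csv",
]

# reserved prefix for the internal dummy parents used by ts_cpdag
_DUMMY_PREFIX = "__ts_dummy_"


class GraphStructureError(ValueError):
    """Raised for structurally invalid graphs (cycles, bad shapes, name clashes)."""


@dataclass(frozen=True)
class Network:
    """A directed graph over named nodes.

    Parameters
    ----------
    node_names
        Ordered node identifiers; fixes the row/column order of ``adjacency``.
    adjacency
        Boolean matrix, entry ``(i, j)`` true iff there is a directed edge
        ``node i -> node j``.
    """

    node_names: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise GraphStructureError(f"adjacency must be square, got {adj.shape}")
        if adj.shape[0] != len(self.node_names):
            raise GraphStructureError("adjacency size does not match node_names")
        if len(set(self.node_names)) != len(self.node_names):
            raise GraphStructureError("duplicate node names")
        if adj.diagonal().any():
            raise GraphStructureError("self-edges are not allowed")
        object.__setattr__(self, "node_names", tuple(self.node_names))
        object.__setattr__(self, "adjacency", adj)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edges(cls, node_names, edges) -> "Network":
        """Build a network from ``(parent, child)`` name pairs."""
        names = tuple(node_names)
        idx = {v: i for i, v in enumerate(names)}
        adj = np.zeros((len(names), len(names)), dtype=bool)
        for p, c in edges:
            if p not in idx or c not in idx:
                raise GraphStructureError(f"edge ({p}, {c}) uses unknown node")
            adj[idx[p], idx[c]] = True
        return cls(names, adj)

    @classmethod
    def empty(cls, node_names) -> "Network":
        names = tuple(node_names)
        return cls(names, np.zeros((len(names), len(names)), dtype=bool))

    @classmethod
    def from_parent_masks(cls, node_names, masks) -> "Network":
        names = tuple(node_names)
        n = len(names)
        adj = np.zeros((n, n), dtype=bool)
        for j, m in enumerate(masks):
            for i in _bits(m):
                adj[i, j] = True
        return cls(names, adj)

    # -- views --------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def edges(self) -> list[tuple[str, str]]:
        return [
            (self.node_names[i], self.node_names[j])
            for i, j in zip(*np.nonzero(self.adjacency))
        ]

    def parent_masks(self) -> list[int]:
        """Per-child integer bitmask of parents (bit ``i`` set iff ``i -> child``)."""
        n = self.n_nodes
        masks = []
        for j in range(n):
            m = 0
            for i in np.nonzero(self.adjacency[:, j])[0]:
                m |= 1 << int(i)
            masks.append(m)
        return masks

    def parents_of(self, j: int) -> tuple[int, ...]:
        return tuple(int(i) for i in np.nonzero(self.adjacency[:, j])[0])

    def __eq__(self, other):
        return (
            isinstance(other, Network)
            and self.node_names == other.node_names
            and np.array_equal(self.adjacency, other.adjacency)
        )

    def __hash__(self):
        return hash((self.node_names, self.adjacency.tobytes()))


@dataclass(frozen=True)
class InterventionSet:
    """Names of externally clamped nodes, for graph-level operations."""

    intervened: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "intervened", frozenset(self.intervened))

    def indices(self, node_names) -> frozenset[int]:
        idx = {v: i for i, v in enumerate(node_names)}
        missing = self.intervened - idx.keys()
        if missing:
            raise GraphStructureError(f"intervened nodes not in graph: {sorted(missing)}")
        return frozenset(idx[v] for v in self.intervened)


@dataclass(frozen=True)
class Cpdag:
    """A completed partially directed graph: one Markov- (or TS-) equivalence class.

    ``directed_edges`` holds ordered index pairs, ``undirected_edges``
    unordered (frozenset) pairs; the two sets are disjoint on node pairs.
    """

    node_names: tuple[str, ...]
    directed_edges: frozenset[tuple[int, int]]
    undirected_edges: frozenset[frozenset[int]]

    def __post_init__(self):
        object.__setattr__(self, "node_names", tuple(self.node_names))
        object.__setattr__(self, "directed_edges", frozenset(self.directed_edges))
        object.__setattr__(self, "undirected_edges", frozenset(self.undirected_edges))
        for i, j in self.directed_edges:
            if frozenset((i, j)) in self.undirected_edges:
                raise GraphStructureError(f"edge {i}-{j} both directed and undirected")

    def skeleton(self) -> frozenset[frozenset[int]]:
        return frozenset(
            {frozenset(e) for e in self.directed_edges} | set(self.undirected_edges)
        )

    def edge_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(directed-contribution, skeleton) matrices for posterior accumulation.

        A directed edge ``i -> j`` contributes 1 to entry ``(i, j)``; an
        undirected edge is counted as the superposition of both directions.
        The skeleton matrix is symmetric adjacency.
        """
        n = len(self.node_names)
        d = np.zeros((n, n))
        s = np.zeros((n, n))
        for i, j in self.directed_edges:
            d[i, j] = 1.0
            s[i, j] = s[j, i] = 1.0
        for e in self.undirected_edges:
            i, j = tuple(e)
            d[i, j] = d[j, i] = 1.0
            s[i, j] = s[j, i] = 1.0
        return d, s


# ---------------------------------------------------------------------------
# bitmask helpers

def _bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def _children_masks(parent_masks: list[int]) -> list[int]:
    n = len(parent_masks)
    ch = [0] * n
    for j, m in enumerate(parent_masks):
        for i in _bits(m):
            ch[i] |= 1 << j
    return ch


def _descendant_masks(children: list[int]) -> list[int]:
    """desc[i] = bitmask of all nodes reachable from i by a directed path."""
    n = len(children)
    desc = list(children)
    changed = True
    while changed:
        changed = False
        for i in range(n):
            acc = desc[i]
            for k in _bits(desc[i]):
                acc |= desc[k]
            if acc != desc[i]:
                desc[i] = acc
                changed = True
    return desc


def _path_avoiding_edge(children: list[int], i: int, j: int) -> bool:
    """True iff a directed path i ~> j exists that does not use the edge i->j."""
    frontier = children[i] & ~(1 << j)
    visited = frontier
    target = 1 << j
    while frontier:
        if visited & target:
            return True
        nxt = 0
        for k in _bits(frontier):
            nxt |= children[k]
        frontier = nxt & ~visited
        visited |= nxt
    return bool(visited & target)


def _masks_acyclic(parent_masks: list[int]) -> bool:
    n = len(parent_masks)
    indeg = [m.bit_count() for m in parent_masks]
    children = _children_masks(parent_masks)
    queue = deque(i for i in range(n) if indeg[i] == 0)
    seen = 0
    while queue:
        i = queue.popleft()
        seen += 1
        for j in _bits(children[i]):
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    return seen == n


# ---------------------------------------------------------------------------
# public graph operations

def is_acyclic(net: Network) -> bool:
    """True iff the network contains no directed cycle."""
    return _masks_acyclic(net.parent_masks())


def topological_order(net: Network) -> list[int]:
    """Node indices in a topological order; raises on cyclic input."""
    masks = net.parent_masks()
    n = net.n_nodes
    indeg = [m.bit_count() for m in masks]
    children = _children_masks(masks)
    queue = deque(i for i in range(n) if indeg[i] == 0)
    order = []
    while queue:
        i = queue.popleft()
        order.append(i)
        for j in _bits(children[i]):
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    if len(order) != n:
        raise GraphStructureError("graph is cyclic")
    return order


# move kinds, also used by the samplers
ADD, DELETE, REVERSE = "add", "delete", "reverse"


def _list_moves(parent_masks: list[int], fan_in: int) -> list[tuple[str, int, int]]:
    n = len(parent_masks)
    children = _children_masks(parent_masks)
    desc = _descendant_masks(children)
    moves: list[tuple[str, int, int]] = []
    full = (1 << n) - 1
    for j in range(n):
        pj = parent_masks[j]
        if pj.bit_count() < fan_in:
            # adding i->j is valid unless i == j, i already a parent, or j ~> i
            candidates = full & ~(pj | (1 << j) | desc[j])
            for i in _bits(candidates):
                moves.append((ADD, i, j))
        for i in _bits(pj):
            moves.append((DELETE, i, j))
    for j in range(n):
        for i in _bits(parent_masks[j]):
            # reversing i->j adds j->i: needs fan-in room at i and no
            # remaining path i ~> j once the direct edge is dropped
            if parent_masks[i].bit_count() >= fan_in:
                continue
            if _path_avoiding_edge(children, i, j):
                continue
            moves.append((REVERSE, i, j))
    return moves


def neighbor_moves(net: Network, fan_in: int = 3) -> tuple[list[tuple[str, tuple[int, int]]], int]:
    """All valid single-edge moves (add/delete/reverse) from ``net``.

    Returns the move list and its length — the proposal-neighbourhood size
    |N(net)| entering the Metropolis-Hastings correction.  A move is valid
    iff the resulting graph is acyclic and respects the fan-in bound.
    """
    if fan_in < 1:
        raise ValueError(f"fan_in must be >= 1, got {fan_in}")
    if not is_acyclic(net):
        raise GraphStructureError("neighbor_moves requires an acyclic network")
    raw = _list_moves(net.parent_masks(), fan_in)
    moves = [(kind, (i, j)) for kind, i, j in raw]
    return moves, len(moves)


def apply_move(net: Network, move: tuple[str, tuple[int, int]]) -> Network:
    """Return the network obtained by applying a single-edge move."""
    kind, (i, j) = move
    adj = net.adjacency.copy()
    if kind == ADD:
        adj[i, j] = True
    elif kind == DELETE:
        adj[i, j] = False
    elif kind == REVERSE:
        adj[i, j] = False
        adj[j, i] = True
    else:
        raise ValueError(f"unknown move kind {kind!r}")
    return Network(net.node_names, adj)


def enumerate_dags(n: int, fan_in: int | None = None) -> list[Network]:
    """All labelled DAGs on ``n`` nodes with in-degree <= ``fan_in``.

    Super-exponential in ``n``; refused for ``n > 5``.  Used as the
    exhaustive-enumeration oracle for posteriors and equivalence classes.
    """
    if n > 5:
        raise ValueError(f"enumerate_dags limited to n <= 5, got n={n}")
    if fan_in is None:
        fan_in = n - 1 if n > 0 else 0
    names = tuple(f"X{k}" for k in range(n))
    parent_choices = []
    for j in range(n):
        others = [i for i in range(n) if i != j]
        choices = []
        for k in range(0, min(fan_in, n - 1) + 1):
            for combo in itertools.combinations(others, k):
                m = 0
                for i in combo:
                    m |= 1 << i
                choices.append(m)
        parent_choices.append(choices)
    out = []
    for masks in itertools.product(*parent_choices):
        if _masks_acyclic(list(masks)):
            out.append(Network.from_parent_masks(names, masks))
    return out


# ---------------------------------------------------------------------------
# CPDAG construction

def _vstructure_orient(n: int, edges: set[tuple[int, int]]):
    """Initial orientation: keep exactly the v-structure edges directed."""
    parents = [set() for _ in range(n)]
    for i, j in edges:
        parents[j].add(i)
    adjacent = {frozenset(e) for e in edges}
    directed: set[tuple[int, int]] = set()
    for j in range(n):
        for a, b in itertools.combinations(sorted(parents[j]), 2):
            if frozenset((a, b)) not in adjacent:
                directed.add((a, j))
                directed.add((b, j))
    return adjacent, directed


def _meek_closure(n: int, skeleton: set[frozenset[int]], directed: set[tuple[int, int]]):
    """Apply Meek orientation rules R1-R3 to a fixpoint.

    R4 is only required when orientations come from background knowledge;
    starting from a DAG's v-structures, R1-R3 are complete.
    """
    neighbors = [set() for _ in range(n)]
    for e in skeleton:
        i, j = tuple(e)
        neighbors[i].add(j)
        neighbors[j].add(i)

    def undirected(i, j):
        return (
            frozenset((i, j)) in skeleton
            and (i, j) not in directed
            and (j, i) not in directed
        )

    changed = True
    while changed:
        changed = False
        for e in list(skeleton):
            x, y = tuple(e)
            for a, b in ((x, y), (y, x)):
                if not undirected(a, b):
                    continue
                # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
                if any(
                    (c, a) in directed and b not in neighbors[c] and c != b
                    for c in neighbors[a]
                ):
                    directed.add((a, b))
                    changed = True
                    continue
                # R2: a -> c -> b with a - b  =>  a -> b
                if any(
                    (a, c) in directed and (c, b) in directed
                    for c in neighbors[a] & neighbors[b]
                ):
                    directed.add((a, b))
                    changed = True
                    continue
                # R3: a - c, a - d, c -> b, d -> b, c and d non-adjacent => a -> b
                shared = [
                    c
                    for c in neighbors[a] & neighbors[b]
                    if undirected(a, c) and (c, b) in directed
                ]
                hit = False
                for c, d in itertools.combinations(shared, 2):
                    if d not in neighbors[c]:
                        hit = True
                        break
                if hit:
                    directed.add((a, b))
                    changed = True
    return directed


def _cpdag_from_edges(n: int, edges: set[tuple[int, int]]) -> tuple[set, set]:
    skeleton, directed = _vstructure_orient(n, edges)
    directed = _meek_closure(n, set(skeleton), directed)
    # soundness: compelled orientations must agree with the source DAG
    assert directed <= edges, "Meek closure oriented an edge against the DAG"
    undirected = {
        e
        for e in skeleton
        if (tuple(e)[0], tuple(e)[1]) not in directed
        and (tuple(e)[1], tuple(e)[0]) not in directed
    }
    return directed, undirected


def dag_to_cpdag(net: Network) -> Cpdag:
    """The completed partially directed graph of ``net``'s Markov class.

    Orientation is rule-based: v-structures are kept directed, then Meek
    rules propagate compelled orientations; every remaining skeleton edge is
    reversible within the class and left undirected.
    """
    if not is_acyclic(net):
        raise GraphStructureError("dag_to_cpdag requires an acyclic network")
    edges = {(int(i), int(j)) for i, j in zip(*np.nonzero(net.adjacency))}
    directed, undirected = _cpdag_from_edges(net.n_nodes, edges)
    return Cpdag(net.node_names, frozenset(directed), frozenset(undirected))


def ts_cpdag(net: Network, interventions: InterventionSet | set | frozenset) -> Cpdag:
    """Equivalence class refined by interventions (transition-sequence classes).

    Two dummy parents are attached to every intervened node, the augmented DAG
    is completed to a CPDAG, and the dummies are stripped.  The dummy pair
    forms a v-structure at each intervened node, so every edge incident to an
    intervened node comes out directed.
    """
    if not isinstance(interventions, InterventionSet):
        interventions = InterventionSet(frozenset(interventions))
    for name in net.node_names:
        if name.startswith(_DUMMY_PREFIX):
            raise GraphStructureError(
                f"node name {name!r} collides with reserved dummy-node prefix"
            )
    if not is_acyclic(net):
        raise GraphStructureError("ts_cpdag requires an acyclic network")
    targets = sorted(interventions.indices(net.node_names))
    n = net.n_nodes
    edges = {(int(i), int(j)) for i, j in zip(*np.nonzero(net.adjacency))}
    n_aug = n
    for t in targets:
        edges.add((n_aug, t))
        edges.add((n_aug + 1, t))
        n_aug += 2
    directed, undirected = _cpdag_from_edges(n_aug, edges)
    keep_d = frozenset((i, j) for i, j in directed if i < n and j < n)
    keep_u = frozenset(e for e in undirected if max(e) < n)
    out = Cpdag(net.node_names, keep_d, keep_u)
    target_set = set(targets)
    for e in out.undirected_edges:
        if e & target_set:
            raise AssertionError("undirected edge touching an intervened node")
    return out


# ---------------------------------------------------------------------------
# I/O

def write_network_tsv(net: Network, path):
    """Edge-list TSV (`parent<TAB>child`); node universe kept in a comment."""
    path = Path(path)
    lines = ["# nodes: " + ",".join(net.node_names), "parent\tchild"]
    lines += [f"{p}\t{c}" for p, c in net.edges()]
    path.write_text("\n".join(lines) + "\n")


def read_network_tsv(path, node_names=None) -> Network:
    path = Path(path)
    edges = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line[1:].strip().lower().startswith("nodes:") and node_names is None:
                node_names = [
                    v.strip() for v in line.split(":", 1)[1].split(",") if v.strip()
                ]
            continue
        p, c = line.split("\t")[:2]
        if (p, c) == ("parent", "child"):
            continue
        edges.append((p, c))
    if node_names is None:
        seen = []
        for p, c in edges:
            for v in (p, c):
                if v not in seen:
                    seen.append(v)
        node_names = seen
    return Network.from_edges(node_names, edges)


def write_network_csv(net: Network, path):
    """Square adjacency CSV with node names as header row and column."""
    import pandas as pd

    pd.DataFrame(
        net.adjacency.astype(int), index=net.node_names, columns=net.node_names
    ).to_csv(path)


def read_network_csv(path) -> Network:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise GraphStructureError("adjacency CSV rows and columns disagree")
    return Network(tuple(df.columns), df.values.astype(bool))


def write_cpdag_tsv(cpdag: Cpdag, path):
    """Edge-list TSV with a third column `directed|undirected`."""
    path = Path(path)
    lines = ["# nodes: " + ",".join(cpdag.node_names), "node_a\tnode_b\tkind"]
    names = cpdag.node_names
    for i, j in sorted(cpdag.directed_edges):
        lines.append(f"{names[i]}\t{names[j]}\tdirected")
    for e in sorted(cpdag.undirected_edges, key=sorted):
        i, j = sorted(e)
        lines.append(f"{names[i]}\t{names[j]}\tundirected")
    path.write_text("\n".join(lines) + "\n")
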