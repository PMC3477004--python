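"""Informative structure priors from belief matrices.

Prior knowledge about a network enters as a belief matrix B with entries in
[0, 1]: B_ij near 1 expresses confidence that the directed edge i -> j is
present, near 0 that it is absent, and 0.5 expresses no information.  The
disagreement between a structure M and B is its *energy*

    E(M) = sum_{i != j} |B_ij - M_ij|,

zero exactly when the structure matches the belief perfectly.  The prior
over structures is a Gibbs distribution P(M | beta) ∝ exp(-beta E(M)) whose
inverse temperature beta weights the prior knowledge against the data;
beta = 0 is flat, beta -> inf concentrates on the minimum-energy structure.

The partition function is approximated node-wise over fan-in-restricted
parent sets; because that sum ranges over all directed graphs rather than
DAGs only, it is an upper bound on the true DAG-space normalizer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import Network, is_acyclic

__all__ = [
    "BeliefMatrix",
    "GibbsPrior",
    "energy",
    "log_partition",
    "log_structure_prior",
    "make_b100",
    "make_b50",
]

logger = logging.getLogger(__name__)


class PriorError(ValueError):
    pass


@dataclass(frozen=True)
class BeliefMatrix:
    """Prior-knowledge matrix B, entries in [0, 1], diagonal fixed at 0."""

    entries: np.ndarray
    node_names: tuple[str, ...]

    def __post_init__(self):
        b = np.asarray(self.entries, dtype=float).copy()
        if b.ndim != 2 or b.shape[0] != b.shape[1]:
            raise PriorError("belief matrix must be square")
        if b.shape[0] != len(self.node_names):
            raise PriorError("belief matrix size does not match node_names")
        if np.any(b < 0) or np.any(b > 1):
            raise PriorError("belief entries must lie in [0, 1]")
        np.fill_diagonal(b, 0.0)  # structures never carry self-edges
        b.flags.writeable = False
        object.__setattr__(self, "entries", b)
        object.__setattr__(self, "node_names", tuple(self.node_names))

    @property
    def n_nodes(self) -> int:
        return self.entries.shape[0]

    @classmethod
    def uninformative(cls, node_names) -> "BeliefMatrix":
        n = len(node_names)
        b = np.full((n, n), 0.5)
        return cls(b, tuple(node_names))

    @classmethod
    def from_csv(cls, path) -> "BeliefMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise PriorError("belief CSV rows and columns disagree")
        return cls(df.values.astype(float), tuple(df.columns))

    def to_csv(self, path):
        pd.DataFrame(self.entries, index=self.node_names,
                     columns=self.node_names).to_csv(path)


def energy(net: Network, belief: BeliefMatrix) -> float:
    """Entry-wise absolute disagreement between structure and belief matrix."""
    if tuple(net.node_names) != tuple(belief.node_names):
        raise PriorError("network and belief matrix node names differ")
    diff = np.abs(belief.entries - net.adjacency.astype(float))
    np.fill_diagonal(diff, 0.0)
    return float(diff.sum())


def _node_energy_terms(belief: BeliefMatrix, child: int):
    """Per-child decomposition: eps(child, pi) = base + sum_{i in pi} delta[i].

    base is the energy of an empty parent set (sum of beliefs in column
    ``child``); including parent i replaces |B_ic - 0| by |B_ic - 1|,
    changing the energy by delta[i] = 1 - 2 B_ic.
    """
    col = belief.entries[:, child].copy()
    col[child] = 0.0
    base = float(col.sum())
    delta = 1.0 - 2.0 * col
    delta[child] = 0.0
    return base, delta


class GibbsPrior:
    """Gibbs structure prior for a fixed belief matrix and fan-in bound.

    Caches the per-node parent-set energies once and the log-partition value
    per requested beta (recomputed exactly, never interpolated).
    """

    def __init__(self, belief: BeliefMatrix, beta_max: float = 30.0,
                 fan_in: int = 3):
        if beta_max <= 0:
            raise PriorError("beta_max must be positive")
        self.belief = belief
        self.beta_max = float(beta_max)
        self.fan_in = int(fan_in)
        n = belief.n_nodes
        self._terms = [_node_energy_terms(belief, c) for c in range(n)]
        # energy of every fan-in-valid parent set, per child; the subset count
        # is the same for every child, so the energies stack to a rectangle
        eps_rows = []
        for c in range(n):
            base, delta = self._terms[c]
            others = [i for i in range(n) if i != c]
            vals = []
            for k in range(0, min(self.fan_in, n - 1) + 1):
                for combo in itertools.combinations(others, k):
                    vals.append(base + sum(delta[i] for i in combo))
            eps_rows.append(vals)
        self._eps = [np.asarray(r) for r in eps_rows]
        self._eps_mat = np.asarray(eps_rows)
        self._logz: dict[float, float] = {}

    def node_energy(self, child: int, parent_mask: int) -> float:
        base, delta = self._terms[child]
        e = base
        m = parent_mask
        while m:
            low = m & -m
            e += delta[low.bit_length() - 1]
            m ^= low
        return float(e)

    def total_energy(self, net: Network) -> float:
        return energy(net, self.belief)

    def log_partition(self, beta: float) -> float:
        if beta < 0:
            raise PriorError("beta must be non-negative")
        key = float(beta)
        if key not in self._logz:
            m = -key * self._eps_mat
            row_max = m.max(axis=1)
            self._logz[key] = float(
                (row_max + np.log(np.exp(m - row_max[:, None]).sum(axis=1))).sum()
            )
        return self._logz[key]

    def log_prior(self, net: Network, beta: float) -> float:
        return -beta * self.total_energy(net) - self.log_partition(beta)


def log_partition(beta: float, n_nodes: int, fan_in: int,
                  belief: BeliefMatrix) -> float:
    """Log of the node-wise product of fan-in-restricted parent-set sums.

    An upper bound on the DAG-space partition sum: the product ranges over
    all parent-set combinations, cyclic ones included.
    """
    if belief.n_nodes != n_nodes:
        raise PriorError("n_nodes does not match belief matrix")
    if fan_in < 0:
        raise PriorError("fan_in must be >= 0")
    return GibbsPrior(belief, beta_max=max(beta, 1.0), fan_in=fan_in).log_partition(beta)


def log_structure_prior(net: Network, spec: GibbsPrior, beta: float | None = None,
                        belief: BeliefMatrix | None = None) -> float:
    """Normalized Gibbs log-prior -beta E(M) - log Z(beta).

    ``spec`` carries the belief matrix and fan-in; ``beta`` defaults to
    ``spec.beta_max / 2``.  Only prior *differences* enter the samplers'
    structure sub-moves, where the partition term cancels.
    """
    if belief is not None and belief is not spec.belief:
        spec = GibbsPrior(belief, spec.beta_max, spec.fan_in)
    if beta is None:
        beta = spec.beta_max / 2.0
    return spec.log_prior(net, beta)


def make_b100(gold: Network) -> BeliefMatrix:
    """Completely correct belief matrix: B equals the gold adjacency matrix."""
    if not is_acyclic(gold):
        raise PriorError("gold standard must be acyclic")
    return BeliefMatrix(gold.adjacency.astype(float), gold.node_names)


def make_b50(gold: Network, seed: int) -> BeliefMatrix:
    """Half-correct belief matrix: flip a random half of the ordered pairs.

    Starting from the perfect matrix, exactly ``floor(N(N-1)/2)`` uniformly
    chosen off-diagonal ordered entries are replaced by one minus their
    value, so half of the entries are correct and the other half wrong.
    Deterministic in ``seed``; the realized flip set is logged.
    """
    b = np.array(make_b100(gold).entries)
    n = b.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    rng = np.random.default_rng(seed)
    k = len(pairs) // 2
    chosen = rng.choice(len(pairs), size=k, replace=False)
    flipped = [pairs[int(c)] for c in chosen]
    for i, j in flipped:
        b[i, j] = 1.0 - b[i, j]
    logger.info(
        "make_b50(seed=%d): flipped %d/%d ordered pairs: %s",
        seed, k, len(pairs),
        ",".join(f"{gold.node_names[i]}->{gold.node_names[j]}" for i, j in flipped),
    )
    return BeliefMatrix(b, gold.node_names)
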