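"""Synthetic expression-style data from a known gold-standard network.

The generator emulates the benchmark design used throughout this package:
linear-Gaussian data from the Raf signalling pathway.  Each non-intervened
node is drawn as

    x_i ~ Normal( sum_k w_ik x_k , sigma^2 ),   sigma = 0.1,

with the sum over the node's parents in the gold standard; edge weights have
|w| ~ Uniform[0.5, 2] and random sign.  Intervened (clamped) nodes are set
deterministically to a fixed value and flagged in the intervention mask.

The default interventional design mirrors the down-sampled flow-cytometry
protocol: 16 observational records plus 14 records for each of six
interventions (Akt, PKC, PIP2, Mek inhibited; PKC, PKA activated), 100
records in total.  The observational design is a single 100-record block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .graphs import Network, is_acyclic, read_network_tsv, topological_order
from .scoring import Dataset, InterventionMask

__all__ = [
    "GoldStandard",
    "WeightSet",
    "InterventionDesign",
    "raf_gold_standard",
    "draw_weights",
    "simulate_gaussian",
    "simulate_sigmoid",
    "paper_design",
    "simulate_replicates",
]

SIGMA_DEFAULT = 0.1
WEIGHT_LOW, WEIGHT_HIGH = 0.5, 2.0

RAF_INHIBITED = ("Akt", "PKC", "PIP2", "Mek")
RAF_ACTIVATED = ("PKC", "PKA")


@dataclass(frozen=True)
class GoldStandard:
    """A known true network against which reconstructions are scored."""

    network: Network
    description: str = ""

    def __post_init__(self):
        if not is_acyclic(self.network):
            raise ValueError("gold-standard network must be acyclic")


@dataclass(frozen=True)
class WeightSet:
    """Edge weights aligned with the gold adjacency; zero off-edges."""

    weights: np.ndarray
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


@dataclass(frozen=True)
class InterventionDesign:
    """Block design: (intervened node or None, direction, record count) triples."""

    blocks: tuple[tuple[str | None, str, int], ...]
    clamp_values: dict = field(default_factory=lambda: {"down": -1.0, "up": 1.0})

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        for node, direction, count in self.blocks:
            if count <= 0:
                raise ValueError("block record counts must be positive")
            if node is None and direction != "none":
                raise ValueError("observational blocks have direction 'none'")

    @property
    def n_records(self) -> int:
        return sum(c for _, _, c in self.blocks)

    def intervened_nodes(self) -> frozenset[str]:
        return frozenset(n for n, _, _ in self.blocks if n is not None)

    def to_json(self, path, extra=None):
        doc = {
            "blocks": [list(b) for b in self.blocks],
            "clamp_values": self.clamp_values,
        }
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def raf_gold_standard() -> GoldStandard:
    """The 11-node Raf pathway fixture shipped with the package."""
    with resources.as_file(
        resources.files("bninfer.data").joinpath("raf_gold.tsv")
    ) as p:
        net = read_network_tsv(p)
    return GoldStandard(net, "Raf signalling pathway consensus network (11 nodes)")


def paper_design(observational_only: bool = False) -> InterventionDesign:
    """The benchmark sampling design for the Raf system.

    Interventional: 16 observational records, then 14 records per inhibited
    protein (Akt, PKC, PIP2, Mek) and 14 per activated protein (PKC, PKA) —
    100 records.  PKC appears both inhibited and activated, as two separate
    blocks.  Observational-only: a single 100-record block, no clamping.
    """
    if observational_only:
        return InterventionDesign(((None, "none", 100),))
    blocks = [(None, "none", 16)]
    blocks += [(p, "down", 14) for p in RAF_INHIBITED]
    blocks += [(p, "up", 14) for p in RAF_ACTIVATED]
    return InterventionDesign(tuple(blocks))


def draw_weights(gold: GoldStandard, sigma: float = SIGMA_DEFAULT,
                 seed: int = 0) -> WeightSet:
    """Random edge weights: |w| ~ Uniform[0.5, 2], sign ~ +/-1 equiprobably."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    adj = gold.network.adjacency
    mag = rng.uniform(WEIGHT_LOW, WEIGHT_HIGH, size=adj.shape)
    sign = rng.choice([-1.0, 1.0], size=adj.shape)
    return WeightSet(np.where(adj, mag * sign, 0.0), sigma)


def _simulate(gold: GoldStandard, weights: WeightSet, design: InterventionDesign,
              seed: int, link=None) -> tuple[Dataset, InterventionMask]:
    net = gold.network
    names = net.node_names
    unknown = design.intervened_nodes() - set(names)
    if unknown:
        raise ValueError(f"design intervenes on unknown nodes: {sorted(unknown)}")
    idx = {v: i for i, v in enumerate(names)}
    order = topological_order(net)
    rng = np.random.default_rng(seed)
    n = len(names)
    values = np.zeros((design.n_records, n))
    clamped = np.zeros((design.n_records, n), dtype=bool)
    w = weights.weights
    row = 0
    for node, direction, count in design.blocks:
        target = None if node is None else idx[node]
        clamp = None if node is None else design.clamp_values[direction]
        for _ in range(count):
            for i in order:
                if i == target:
                    values[row, i] = clamp
                    clamped[row, i] = True
                else:
                    mean = float(values[row] @ w[:, i])
                    if link is not None:
                        mean = link(mean)
                    values[row, i] = rng.normal(mean, weights.sigma)
            row += 1
    return Dataset(values, names), InterventionMask(clamped)


def simulate_gaussian(gold: GoldStandard, weights: WeightSet,
                      design: InterventionDesign, seed: int = 0
                      ) -> tuple[Dataset, InterventionMask]:
    """Linear-Gaussian records in topological order, honouring clamps."""
    return _simulate(gold, weights, design, seed, link=None)


def simulate_sigmoid(gold: GoldStandard, weights: WeightSet,
                     design: InterventionDesign, seed: int = 0
                     ) -> tuple[Dataset, InterventionMask]:
    """Synthetic nonlinear stand-in: the linear predictor squashed by tanh.

    A convenience generator for exercising the samplers on data that violate
    the linear-Gaussian assumption; it does not emulate any particular
    enzyme-kinetics simulator and is excluded from the benchmark protocol.
    """
    return _simulate(gold, weights, design, seed, link=np.tanh)


def simulate_replicates(gold: GoldStandard, design: InterventionDesign,
                        n_replicates: int = 5, sigma: float = SIGMA_DEFAULT,
                        base_seed: int = 0
                        ) -> list[tuple[Dataset, InterventionMask]]:
    """Independent replicate datasets for protocol-style averaging.

    Each replicate draws fresh edge weights and fresh noise from seeds
    derived deterministically from ``base_seed``.
    """
    ss = np.random.SeedSequence(base_seed)
    out = []
    for child in ss.spawn(n_replicates):
        w_seed, d_seed = (int(s) % (2**31) for s in child.generate_state(2))
        weights = draw_weights(gold, sigma=sigma, seed=w_seed)
        out.append(simulate_gaussian(gold, weights, design, seed=d_seed))
    return out
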