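"""Closed-form marginal-likelihood scoring of network structures.

Continuous data are scored with the BGe metric: the marginal likelihood of a
linear-Gaussian network under a Normal-Wishart parameter prior, which
integrates the parameters out analytically.  The score decomposes over
nodes, so each (child, parent-set) pair has a *local* score and the network
score is their sum.

Intervention-aware scoring (the BN-I scheme) excludes a record from a node's
local score whenever that node was externally clamped in that record; the
record still contributes to every other node's score.  This asymmetric
removal is what breaks the score symmetry between Markov-equivalent
structures and lets interventional data resolve edge directions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import multigammaln

from .graphs import Network

__all__ = [
    "Dataset",
    "InterventionMask",
    "BgeHyperparams",
    "BgeScorer",
    "bge_local_score",
    "log_marginal_likelihood",
]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class Dataset:
    """Real-valued sample matrix (records x nodes) with named columns."""

    values: np.ndarray
    node_names: tuple[str, ...]

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ScoringError("values must be a 2-D matrix (records x nodes)")
        if vals.shape[1] != len(self.node_names):
            raise ScoringError("column count does not match node_names")
        if vals.shape[0] < 2:
            raise ScoringError("need at least 2 records")
        if not np.isfinite(vals).all():
            raise ScoringError("missing or non-finite values are not supported")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "node_names", tuple(self.node_names))

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tsv(cls, path) -> "Dataset":
        df = pd.read_csv(path, sep="\t")
        return cls(df.values.astype(float), tuple(df.columns))

    def to_tsv(self, path):
        pd.DataFrame(self.values, columns=self.node_names).to_csv(
            path, sep="\t", index=False
        )

    def standardized(self) -> "Dataset":
        """Per-column z-scores (mean 0, sd 1), computed over all records."""
        sd = self.values.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [self.node_names[i] for i in np.nonzero(sd == 0)[0]]
            raise ScoringError(f"constant columns cannot be standardized: {bad}")
        return Dataset((self.values - self.values.mean(axis=0)) / sd, self.node_names)


@dataclass(frozen=True)
class InterventionMask:
    """Per-cell clamp flags: entry (r, i) true iff node i was set externally in record r."""

    clamped: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.clamped, dtype=bool)
        if m.ndim != 2:
            raise ScoringError("mask must be a 2-D matrix")
        object.__setattr__(self, "clamped", m)

    @property
    def intervened_nodes(self) -> np.ndarray:
        """Indices of nodes clamped in at least one record."""
        return np.nonzero(self.clamped.any(axis=0))[0]

    def intervened_names(self, node_names) -> frozenset[str]:
        return frozenset(node_names[i] for i in self.intervened_nodes)

    @classmethod
    def none(cls, n_records: int, n_nodes: int) -> "InterventionMask":
        return cls(np.zeros((n_records, n_nodes), dtype=bool))

    @classmethod
    def from_tsv(cls, path, node_names=None, n_records=None) -> "InterventionMask":
        """Read either the full 0/1 matrix or the compact design form.

        The compact form has lines ``node<TAB>record_indices`` with
        comma-separated zero-based indices, and requires ``node_names`` and
        ``n_records``.
        """
        text = Path(path).read_text()
        first = next((l for l in text.splitlines() if l.strip()), "")
        cells = first.split("\t")
        is_compact = len(cells) == 2 and not set(cells[1].replace(",", "")) <= set("01")
        if not is_compact:
            df = pd.read_csv(path, sep="\t")
            return cls(df.values.astype(int).astype(bool))
        if node_names is None or n_records is None:
            raise ScoringError("compact mask form needs node_names and n_records")
        idx = {v: i for i, v in enumerate(node_names)}
        m = np.zeros((n_records, len(node_names)), dtype=bool)
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            node, recs = line.split("\t")
            rows = [int(r) for r in recs.split(",") if r != ""]
            m[rows, idx[node]] = True
        return cls(m)

    def to_tsv(self, path, node_names):
        pd.DataFrame(self.clamped.astype(int), columns=node_names).to_csv(
            path, sep="\t", index=False
        )

    def signature(self, child: int) -> str:
        """Stable hash of the child's clamped-record index set (cache key part)."""
        rows = np.nonzero(self.clamped[:, child])[0].astype(np.int64)
        return hashlib.sha1(rows.tobytes()).hexdigest()[:16]


@dataclass(frozen=True)
class BgeHyperparams:
    """Normal-Wishart prior parameters of the BGe score.

    The joint prior over (mean mu, precision W) of the full n-variate
    Gaussian is mu | W ~ N(prior_mean, (alpha_mu W)^-1) and
    W ~ Wishart(alpha_w, T0^-1) with T0 = t0_scale * I.  Defaults follow the
    standard proper parameterization for standardized data: prior_mean = 0,
    alpha_mu = 1, alpha_w = n + 2 and
    t0_scale = alpha_mu (alpha_w - n - 1) / (alpha_mu + 1).
    """

    n_nodes: int
    prior_mean: np.ndarray
    alpha_mu: float
    alpha_w: float
    t0_scale: float

    @classmethod
    def default(cls, n_nodes: int, alpha_mu: float = 1.0) -> "BgeHyperparams":
        alpha_w = n_nodes + 2.0
        t0 = alpha_mu * (alpha_w - n_nodes - 1.0) / (alpha_mu + 1.0)
        return cls(n_nodes, np.zeros(n_nodes), alpha_mu, alpha_w, t0)

    def __post_init__(self):
        object.__setattr__(
            self, "prior_mean", np.asarray(self.prior_mean, dtype=float)
        )
        if self.alpha_mu <= 0:
            raise ScoringError("alpha_mu must be positive")
        if self.alpha_w <= self.n_nodes + 1:
            raise ScoringError("alpha_w must exceed n_nodes + 1 for a proper prior")
        if self.t0_scale <= 0:
            raise ScoringError("t0_scale must be positive")


class BgeScorer:
    """Local and whole-network BGe log-scores with a transparent cache.

    Parameters
    ----------
    data
        The dataset to score on.
    hyper
        Prior parameters; defaults to :meth:`BgeHyperparams.default`.
    mask
        Optional clamp flags; clamped records are dropped from the clamped
        node's own local score only.
    standardize
        Z-score each column before scoring (statistics over *all* records,
        clamped ones included), making the score scale-free.
    cache
        Memoize local scores by (child, parent set).  Cached and cold values
        are bit-identical because the computation is deterministic.
    """

    def __init__(self, data: Dataset, hyper: BgeHyperparams | None = None,
                 mask: InterventionMask | None = None, standardize: bool = True,
                 cache: bool = True):
        if mask is not None and mask.clamped.shape != data.values.shape:
            raise ScoringError("mask shape does not match data shape")
        self.data = data.standardized() if standardize else data
        self.node_names = data.node_names
        n = data.n_nodes
        self.hyper = hyper if hyper is not None else BgeHyperparams.default(n)
        self.mask = mask
        self._use_cache = cache
        self._cache: dict[tuple, float] = {}
        # per-child effective record rows
        if mask is None:
            self._rows = [None] * n  # None = all rows
        else:
            self._rows = [np.nonzero(~mask.clamped[:, c])[0] for c in range(n)]

    # -- internals ----------------------------------------------------------

    def _subset_logml(self, cols: tuple[int, ...], rows) -> float:
        """log marginal likelihood of the data restricted to ``cols``/``rows``
        under the full (unconstrained) Gaussian model on those columns."""
        h = self.hyper
        x = self.data.values[:, list(cols)] if rows is None else self.data.values[
            np.ix_(rows, list(cols))
        ]
        # canonical layout so summation order (hence the score, bit for bit)
        # is independent of how the record subset was produced
        x = np.ascontiguousarray(x)
        m, l = x.shape
        if m == 0:
            return 0.0
        n = h.n_nodes
        nu = h.prior_mean[list(cols)]
        xbar = x.mean(axis=0)
        centered = x - xbar
        s_m = centered.T @ centered
        diff = (nu - xbar)[:, None]
        t_m = (
            h.t0_scale * np.eye(l)
            + s_m
            + (h.alpha_mu * m / (h.alpha_mu + m)) * (diff @ diff.T)
        )
        sign, logdet_tm = np.linalg.slogdet(t_m)
        if sign <= 0:
            raise ScoringError(
                "singular posterior precision matrix for columns "
                f"{[self.node_names[c] for c in cols]}: degenerate data or "
                "improper prior scale"
            )
        aw_l = h.alpha_w - n + l
        return (
            -0.5 * l * m * np.log(np.pi)
            + 0.5 * l * np.log(h.alpha_mu / (h.alpha_mu + m))
            + multigammaln(0.5 * (aw_l + m), l)
            - multigammaln(0.5 * aw_l, l)
            + 0.5 * aw_l * l * np.log(h.t0_scale)
            - 0.5 * (aw_l + m) * logdet_tm
        )

    # -- public -------------------------------------------------------------

    def local_score(self, child: int, parents) -> float:
        """Log marginal likelihood contribution of ``child`` given ``parents``.

        Computed only over records in which the child is not clamped; an
        empty effective record set scores 0 (unit evidence).
        """
        parents = tuple(sorted(int(p) for p in parents))
        if child in parents:
            raise ScoringError("child cannot be its own parent")
        key = (int(child), parents)
        if self._use_cache and key in self._cache:
            return self._cache[key]
        rows = self._rows[child]
        if rows is not None and len(rows) == 0:
            val = 0.0
        else:
            fam = self._subset_logml(parents + (int(child),), rows)
            par = self._subset_logml(parents, rows) if parents else 0.0
            val = fam - par
        if self._use_cache:
            self._cache[key] = val
        return val

    def score_network(self, net: Network) -> float:
        if tuple(net.node_names) != tuple(self.node_names):
            raise ScoringError("network and data node names differ")
        return sum(
            self.local_score(j, net.parents_of(j)) for j in range(net.n_nodes)
        )


def bge_local_score(data: Dataset, child: int, parents, hyper=None, mask=None,
                    standardize: bool = True) -> float:
    """Functional wrapper around :meth:`BgeScorer.local_score`."""
    return BgeScorer(data, hyper, mask, standardize=standardize).local_score(
        child, parents
    )


def log_marginal_likelihood(net: Network, data: Dataset, hyper=None, mask=None,
                            standardize: bool = True,
                            scorer: BgeScorer | None = None) -> float:
    """Whole-network log marginal likelihood: the sum of local scores."""
    if scorer is None:
        scorer = BgeScorer(data, hyper, mask, standardize=standardize)
    return scorer.score_network(net)
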