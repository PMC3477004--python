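"""Reconstruction-accuracy evaluation against a gold-standard network.

The MCMC sample of structures yields a matrix of marginal posterior edge
probabilities, which ranks candidate edges.  Two criteria turn the ranking
into a ROC curve against the gold standard:

* DGE (directed graph evaluation): ordered node pairs ranked by the directed
  posterior; a predicted undirected edge counts as the superposition of both
  directions.
* UGE (undirected graph evaluation): unordered pairs ranked by the skeleton
  posterior; the gold standard's edges are replaced by undirected ones.

The area under the ROC curve (AUC) summarizes a ranking: 1.0 for a perfect
predictor, about 0.5 for a random one.  Ties are handled by mid-ranks
(Mann-Whitney).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, rankdata

from .mcmc import McmcConfig, Trace, run_mcmc
from .priors import BeliefMatrix
from .scoring import Dataset, InterventionMask
from .simulate import GoldStandard

__all__ = [
    "EdgePosterior",
    "RocResult",
    "MethodSpec",
    "edge_posteriors",
    "roc_auc",
    "auc_from_scores",
    "beta_posterior_summary",
    "compare_methods",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class EdgePosterior:
    """Marginal posterior probabilities of directed edges and adjacencies.

    ``directed[i, j]`` is the fraction of retained samples whose
    equivalence-class representative carries ``i -> j`` (undirected edges
    counting for both directions); ``skeleton[i, j]`` is the fraction in
    which ``i`` and ``j`` are adjacent at all.  The two matrices are
    accumulated separately, so no fixed inequality links them.
    """

    directed: np.ndarray
    skeleton: np.ndarray
    n_samples: int
    node_names: tuple[str, ...]

    def __post_init__(self):
        for m in (self.directed, self.skeleton):
            if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
                raise EvaluationError("posterior entries must lie in [0, 1]")
        if not np.allclose(self.skeleton, self.skeleton.T):
            raise EvaluationError("skeleton posterior must be symmetric")


def edge_posteriors(trace: Trace) -> EdgePosterior:
    """Normalize a trace's accumulators into posterior probability matrices."""
    if trace.n_samples < 1:
        raise EvaluationError("trace has no post-burn-in samples")
    return EdgePosterior(
        directed=trace.directed_posterior,
        skeleton=trace.skeleton_posterior,
        n_samples=trace.n_samples,
        node_names=trace.node_names,
    )


@dataclass(frozen=True)
class RocResult:
    """Ranked edge list with cumulative TP/FP fractions and the AUC."""

    pairs: tuple
    scores: np.ndarray
    labels: np.ndarray
    tp_fraction: np.ndarray
    fp_fraction: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tp_fraction": self.tp_fraction, "fp_fraction": self.fp_fraction}
        )


def auc_from_scores(scores, labels) -> float:
    """Mann-Whitney AUC of a score vector against binary labels.

    Tied scores contribute their mid-rank, so the value equals the
    probability that a random positive outranks a random negative, counting
    ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC undefined without both positives and negatives")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _roc_points(scores, labels):
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    n_pos = l.sum()
    n_neg = l.size - n_pos
    # step the curve only at distinct score thresholds
    tp = np.cumsum(l)
    fp = np.cumsum(~l)
    distinct = np.nonzero(np.diff(s, append=-np.inf))[0]
    tpf = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpf = np.concatenate([[0.0], fp[distinct] / n_neg])
    return order, tpf, fpf


def roc_auc(posterior: EdgePosterior, gold: GoldStandard,
            criterion: str = "dge", uge_mode: str = "skeleton") -> RocResult:
    """ROC/AUC of an edge-posterior ranking against the gold standard.

    criterion ``"dge"``: candidate set = ordered node pairs, scores = directed
    posterior, positives = the gold standard's directed edges.  ``"uge"``:
    candidate set = unordered pairs, scores = skeleton posterior (or, with
    ``uge_mode="max"``, the larger of the two directed posteriors), positives
    = the gold skeleton.
    """
    if tuple(posterior.node_names) != tuple(gold.network.node_names):
        raise EvaluationError("posterior and gold standard node sets differ")
    n = len(posterior.node_names)
    adj = gold.network.adjacency
    criterion = criterion.lower()
    if criterion == "dge":
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        scores = np.array([posterior.directed[i, j] for i, j in pairs])
        labels = np.array([adj[i, j] for i, j in pairs])
    elif criterion == "uge":
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        if uge_mode == "skeleton":
            scores = np.array([posterior.skeleton[i, j] for i, j in pairs])
        elif uge_mode == "max":
            scores = np.array(
                [max(posterior.directed[i, j], posterior.directed[j, i])
                 for i, j in pairs]
            )
        else:
            raise EvaluationError(f"unknown uge_mode {uge_mode!r}")
        labels = np.array([adj[i, j] or adj[j, i] for i, j in pairs])
    else:
        raise EvaluationError(f"unknown criterion {criterion!r}; use 'dge' or 'uge'")
    auc = auc_from_scores(scores, labels)
    order, tpf, fpf = _roc_points(scores, labels)
    ranked = tuple(pairs[k] for k in order)
    return RocResult(ranked, scores, labels, tpf, fpf, auc)


@dataclass(frozen=True)
class BetaPosteriorSummary:
    """Kernel-density summary of the sampled inverse temperature."""

    grid: np.ndarray
    density: np.ndarray
    median: float
    q05: float
    q95: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.grid, "density": self.density})


def beta_posterior_summary(trace: Trace, bandwidth=None,
                           n_grid: int = 512) -> BetaPosteriorSummary:
    """Gaussian-kernel density of the beta samples on [0, beta_max],
    renormalized to unit mass on that interval, plus sample quantiles."""
    if trace.beta_samples.size == 0:
        raise EvaluationError(
            f"trace from method {trace.method!r} carries no beta samples"
        )
    samples = trace.beta_samples
    bmax = trace.config.beta_max
    grid = np.linspace(0.0, bmax, n_grid)
    if np.ptp(samples) < 1e-12:
        # degenerate chain: a spike at the constant value
        density = np.zeros_like(grid)
        k = int(np.argmin(np.abs(grid - samples[0])))
        dx = grid[1] - grid[0] if n_grid > 1 else 1.0
        density[k] = 1.0 / dx
    else:
        kde = gaussian_kde(samples, bw_method=bandwidth)
        density = kde(grid)
        mass = np.trapezoid(density, grid)
        density = density / mass
    q05, med, q95 = np.quantile(samples, [0.05, 0.5, 0.95])
    return BetaPosteriorSummary(grid, density, float(med), float(q05), float(q95))


# ---------------------------------------------------------------------------
# protocol-style method comparison

@dataclass(frozen=True)
class MethodSpec:
    """One inference scheme to benchmark: label, method name, optional prior."""

    label: str
    method: str
    belief: BeliefMatrix | None = None


@dataclass
class ComparisonResult:
    table: pd.DataFrame          # method, criterion, mean_auc, sd_auc, n_datasets
    per_run: pd.DataFrame        # method, dataset, criterion, auc
    traces: dict                 # (label, dataset index) -> Trace

    def __str__(self):
        return self.table.to_string(index=False)


def compare_methods(datasets, methods, gold: GoldStandard,
                    config: McmcConfig, seeds=None,
                    uge_mode: str = "skeleton") -> ComparisonResult:
    """Run every method on every dataset and tabulate DGE/UGE AUC.

    ``datasets`` is a list of ``(Dataset, InterventionMask | None)`` pairs;
    ``methods`` a list of :class:`MethodSpec`.  Each run gets a
    deterministic seed derived from ``config.seed`` (or the explicit
    ``seeds`` list, one per dataset).
    """
    if len(datasets) < 1:
        raise EvaluationError("need at least one dataset")
    for d, _ in datasets:
        if tuple(d.node_names) != tuple(gold.network.node_names):
            raise EvaluationError("dataset and gold standard node sets differ")
    if seeds is None:
        seeds = [config.seed + 1000 * k for k in range(len(datasets))]
    rows = []
    traces = {}
    from dataclasses import replace

    for spec in methods:
        for k, (data, mask) in enumerate(datasets):
            cfg = replace(config, seed=seeds[k])
            trace = run_mcmc(data, spec.method, cfg, mask=mask, belief=spec.belief)
            traces[(spec.label, k)] = trace
            post = edge_posteriors(trace)
            for crit in ("dge", "uge"):
                auc = roc_auc(post, gold, crit, uge_mode=uge_mode).auc
                rows.append(
                    {"method": spec.label, "dataset": k, "criterion": crit.upper(),
                     "auc": auc}
                )
    per_run = pd.DataFrame(rows)
    table = (
        per_run.groupby(["method", "criterion"], sort=False)["auc"]
        .agg(mean_auc="mean", sd_auc=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    table["n_datasets"] = len(datasets)
    return ComparisonResult(table=table, per_run=per_run, traces=traces)


# ---------------------------------------------------------------------------
# plots (thin wrappers; matplotlib imported lazily)

def plot_comparison(result: ComparisonResult, ax=None):
    """Bar chart of mean AUC per method and criterion with sd error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tab = result.table
    methods = list(dict.fromkeys(tab["method"]))
    criteria = list(dict.fromkeys(tab["criterion"]))
    width = 0.8 / len(methods)
    for m_i, m in enumerate(methods):
        sub = tab[tab["method"] == m].set_index("criterion")
        xs = np.arange(len(criteria)) + m_i * width
        ax.bar(xs, [sub.loc[c, "mean_auc"] for c in criteria], width,
               yerr=[sub.loc[c, "sd_auc"] for c in criteria],
               label=m, capsize=3)
    ax.set_xticks(np.arange(len(criteria)) + 0.4 - width / 2)
    ax.set_xticklabels(criteria)
    ax.set_ylabel("AUC")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax


def plot_beta_densities(summaries: dict, ax=None):
    """Overlaid kernel-density lines of sampled beta, one per label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, summary in summaries.items():
        ax.plot(summary.grid, summary.density, label=label)
    ax.set_xlabel("beta (inverse temperature)")
    ax.set_ylabel("posterior density")
    ax.legend()
    return ax
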