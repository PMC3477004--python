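"""Model/Results front end for structure inference.

``NetworkInference`` bundles data, method choice and sampler settings the way
a regression model bundles endog/exog: construct once, call :meth:`fit` to
run the chain, and work with the returned :class:`NetworkInferenceResults`,
which carries edge posteriors, sampled hyper-parameters, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .evaluate import (
    EdgePosterior, beta_posterior_summary, edge_posteriors, roc_auc,
)
from .mcmc import McmcConfig, Trace, canonical_method, check_convergence, run_mcmc
from .priors import BeliefMatrix
from .scoring import BgeHyperparams, Dataset, InterventionMask
from .simulate import GoldStandard

__all__ = ["NetworkInference", "NetworkInferenceResults"]


class NetworkInference:
    """Bayesian-network structure inference model.

    Parameters
    ----------
    data
        :class:`~bninfer.scoring.Dataset` (records x nodes).
    method
        ``"bn"`` (plain), ``"bn-i"`` (intervention-aware, needs ``mask``) or
        ``"bn-e"`` (Gibbs structure prior, needs ``belief``).
    mask, belief, hyper
        Method-specific inputs; see :func:`bninfer.mcmc.run_mcmc`.
    **config
        Any :class:`~bninfer.mcmc.McmcConfig` field (n_steps, fan_in, ...).
    """

    def __init__(self, data: Dataset, method: str = "bn",
                 mask: InterventionMask | None = None,
                 belief: BeliefMatrix | None = None,
                 hyper: BgeHyperparams | None = None, **config):
        self.data = data
        self.method = canonical_method(method)
        self.mask = mask
        self.belief = belief
        self.hyper = hyper
        self.config = McmcConfig(**config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, method: str = "bn",
                       mask_df: pd.DataFrame | None = None, **kwargs
                       ) -> "NetworkInference":
        data = Dataset(df.values.astype(float), tuple(df.columns))
        mask = None
        if mask_df is not None:
            mask = InterventionMask(mask_df.values.astype(bool))
        return cls(data, method=method, mask=mask, **kwargs)

    def fit(self, n_steps: int | None = None, seed: int | None = None,
            **overrides) -> "NetworkInferenceResults":
        """Run the sampler and return the results object."""
        cfg = self.config
        if n_steps is not None:
            overrides["n_steps"] = n_steps
        if seed is not None:
            overrides["seed"] = seed
        if overrides:
            cfg = replace(cfg, **overrides)
        trace = run_mcmc(self.data, self.method, cfg,
                         mask=self.mask, belief=self.belief, hyper=self.hyper)
        return NetworkInferenceResults(self, trace)


class NetworkInferenceResults:
    """Posterior edge probabilities and diagnostics from one fitted chain."""

    def __init__(self, model: NetworkInference, trace: Trace):
        self.model = model
        self.trace = trace
        self._posterior: EdgePosterior | None = None

    @property
    def edge_posterior(self) -> EdgePosterior:
        if self._posterior is None:
            self._posterior = edge_posteriors(self.trace)
        return self._posterior

    @property
    def directed_posterior(self) -> pd.DataFrame:
        names = self.trace.node_names
        return pd.DataFrame(self.edge_posterior.directed, index=names, columns=names)

    @property
    def skeleton_posterior(self) -> pd.DataFrame:
        names = self.trace.node_names
        return pd.DataFrame(self.edge_posterior.skeleton, index=names, columns=names)

    @property
    def beta_samples(self) -> np.ndarray:
        return self.trace.beta_samples

    def beta_summary(self, **kwargs):
        return beta_posterior_summary(self.trace, **kwargs)

    def auc(self, gold: GoldStandard, criterion: str = "dge", **kwargs) -> float:
        return roc_auc(self.edge_posterior, gold, criterion, **kwargs).auc

    def check_convergence_against(self, other: "NetworkInferenceResults",
                                  threshold: float = 0.1):
        return check_convergence(self.trace, other.trace, threshold)

    def top_edges(self, k: int = 15) -> pd.DataFrame:
        names = self.trace.node_names
        p = self.edge_posterior.directed
        n = len(names)
        rows = [
            {"parent": names[i], "child": names[j], "posterior": p[i, j]}
            for i in range(n) for j in range(n) if i != j
        ]
        df = pd.DataFrame(rows).sort_values("posterior", ascending=False)
        return df.head(k).reset_index(drop=True)

    def summary(self, k_edges: int = 10) -> str:
        t = self.trace
        lines = [
            "Bayesian-network structure inference results",
            "=" * 46,
            f"method:            {t.method}",
            f"nodes:             {len(t.node_names)}",
            f"steps:             {t.config.n_steps} "
            f"(burn-in {t.config.burn_in_steps}, retained {t.n_samples})",
            f"fan-in bound:      {t.config.fan_in}",
            f"seed:              {t.config.seed}",
            "acceptance rates:  "
            + ", ".join(f"{k}={v:.3f}" for k, v in t.acceptance_rates.items()
                        if not np.isnan(v)),
        ]
        if t.method == "bn-i":
            lines.append(f"intervened nodes:  {', '.join(sorted(t.intervened))}")
        if t.method == "bn-e" and t.beta_samples.size:
            s = self.beta_summary()
            lines.append(
                f"beta posterior:    median {s.median:.3f} "
                f"(90% interval {s.q05:.3f} - {s.q95:.3f})"
            )
        lines.append("")
        lines.append(f"top {k_edges} edges by posterior probability:")
        lines.append(self.top_edges(k_edges).to_string(index=False))
        return "\n".join(lines)
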