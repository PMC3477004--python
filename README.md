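# bninfer

Bayesian-network structure inference for continuous (linear-Gaussian) data,
with three inference schemes that differ in how they use information beyond
the raw observations:

- **BN** — plain structure MCMC over directed acyclic graphs (DAGs) with the
  BGe marginal-likelihood score.
- **BN-I** — intervention-aware inference: records in which a node was
  externally clamped are excluded from that node's local score, which breaks
  Markov equivalence and lets interventional data resolve edge directions.
- **BN-E** — inference with informative structure priors: a Gibbs prior
  `P(M | β) ∝ exp(−β E(M))` over structures, where the energy `E(M)` counts
  disagreements between the structure `M` and a prior belief matrix `B`, and
  the inverse temperature `β` is sampled jointly with the structure so the
  data decide how much the prior is trusted.

The package ships the 11-node Raf signalling pathway (the consensus network
of the Sachs et al. flow-cytometry study) as a gold standard, a matching
synthetic-data generator with interventional designs, and ROC-AUC evaluation
of edge posteriors under directed (DGE) and undirected (UGE) criteria.

## Worked example

Simulate interventional data from the Raf gold standard and infer the
network with the correct prior (BN-E with belief matrix `B100`, which equals
the true adjacency matrix):

```python
import numpy as np
from bninfer import (
    NetworkInference, draw_weights, make_b100, paper_design,
    raf_gold_standard, simulate_gaussian,
)

gold = raf_gold_standard()
design = paper_design()        # 16 observational + 6 x 14 clamped records
weights = draw_weights(gold, seed=7)
data, mask = simulate_gaussian(gold, weights, design, seed=7)

model = NetworkInference(data, method="bn-e", belief=make_b100(gold.network),
                         n_steps=100_000, seed=3)
res = model.fit()
print(res.summary(k_edges=8))
print()
print(f"DGE AUC vs gold standard: {res.auc(gold, 'dge'):.3f}")
```

Output:

```
Bayesian-network structure inference results
==============================================
method:            bn-e
nodes:             11
steps:             100000 (burn-in 50000, retained 50000)
fan-in bound:      3
seed:              3
acceptance rates:  add=0.058, delete=0.054, reverse=0.100, beta=0.780
beta posterior:    median 7.320 (90% interval 3.153 - 28.118)

top 8 edges by posterior probability:
parent child  posterior
   Raf   Mek        1.0
   Mek   Erk        1.0
  PIP2   PKC        1.0
   Erk   Akt        1.0
   PKA   P38        1.0
   PKA   Jnk        1.0
   PKC   P38        1.0
   PKC   Jnk        1.0

DGE AUC vs gold standard: 0.983
```

The sampled inverse temperature stays high (median β ≈ 7.3): the data agree
with the prior, so the chain keeps it switched on. Re-running with a
half-wrong prior (`make_b50`) collapses β towards zero and the AUC towards
the plain-BN value — the mechanism that makes BN-E robust to bad prior
knowledge.

For intervention-aware inference without a prior, pass the mask instead:

```python
model = NetworkInference(data, method="bn-i", mask=mask, n_steps=100_000, seed=3)
```

Every `fit()` returns a `NetworkInferenceResults` with `directed_posterior`
and `skeleton_posterior` DataFrames, `beta_samples`, `top_edges()`,
`auc(gold, "dge"|"uge")`, `summary()`, and a two-chain convergence check
(`check_convergence_against`).

## Command line

The `bninfer` CLI wraps the same pipeline:

```
bninfer simulate   # synthetic dataset(s) + intervention mask + design JSON
bninfer infer      # run one sampler twice (two seeds), write traces +
                   # convergence report (exit code 3 if the chains disagree)
bninfer eval       # AUC of a saved edge posterior against a gold standard
bninfer compare    # full benchmark: replicates x {BN, BN-I, BN-E(B100), BN-E(B50)}
bninfer fixtures   # emit the Raf gold standard and its B100/B50 belief matrices
```

Exit codes: 0 success, 2 input error, 3 convergence-check failure. Every
output directory gets a `manifest.json` with input hashes and the resolved
configuration.

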