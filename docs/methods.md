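# Methods

This note records the statistical model, the algorithms, and the concrete
numerical and design choices made in `bninfer`, in enough detail to audit or
re-implement them.

## Model

Data are modelled as i.i.d. records from a linear-Gaussian Bayesian network:
a DAG `M` over `n` named nodes, where each node is a linear function of its
parents plus Gaussian noise. Inference targets the posterior over structures

```
P(M | D) ∝ P(D | M) · P(M)
```

with the parameters integrated out analytically (the BGe score) and `P(M)`
either flat over DAGs (BN, BN-I) or a Gibbs prior encoding prior edge
beliefs (BN-E).

### BGe score

`P(D | M)` is the Gaussian marginal likelihood under a Normal-Wishart prior
on (mean `μ`, precision `W`):

- `μ | W ~ N(ν, (α_μ W)⁻¹)`, `W ~ Wishart(α_w, T₀⁻¹)` with `T₀ = t₀ I`.
- Defaults (for standardized data): `ν = 0`, `α_μ = 1`, `α_w = n + 2`,
  `t₀ = α_μ (α_w − n − 1)/(α_μ + 1) = 0.5`.

The score decomposes over nodes. For a column subset `S` with `l = |S|` and
`m` effective records, the subset log marginal likelihood is

```
f(S) = −(l·m/2)·log π + (l/2)·log(α_μ/(α_μ+m))
     + log Γ_l((α_w,l + m)/2) − log Γ_l(α_w,l / 2)
     + (α_w,l·l/2)·log t₀ − ((α_w,l + m)/2)·log det T_m
```

with `α_w,l = α_w − n + l` and
`T_m = t₀ I + Σ(x−x̄)(x−x̄)ᵀ + (α_μ m/(α_μ+m)) (ν−x̄)(ν−x̄)ᵀ`.
The local score of child `c` with parent set `π` is `f(π ∪ {c}) − f(π)`, and
the network score is the sum of local scores. Columns are z-scored before
scoring (statistics over *all* records, clamped ones included) so the score
is scale-free.

Local scores are memoized by `(child, parent set)`; record subsets are copied
to a canonical contiguous layout before summation so cached and cold values
are bit-identical.

### Interventions (BN-I)

A clamp (external fixing of a node's value) severs the node from its
parents in that record. Accordingly, a record is excluded from the clamped
node's *own* local score only; it still informs every other node. An empty
effective record set scores 0 (unit evidence). This asymmetry breaks the
score equivalence of Markov-equivalent DAGs, so interventional data can
orient edges that observational data cannot.

### Gibbs structure prior (BN-E)

Prior knowledge enters as a belief matrix `B ∈ [0,1]ⁿˣⁿ` (0.5 = no
information). The energy of a structure is the total off-diagonal
disagreement `E(M) = Σ_{i≠j} |B_ij − M_ij|`, zero iff `M` matches `B`
exactly, and the prior is

```
P(M | β) = exp(−β E(M)) / Z(β) .
```

`E` decomposes per child: `ε(c, π) = base_c + Σ_{i∈π} (1 − 2 B_ic)` with
`base_c = Σ_i B_ic`, so the partition function is approximated by the
per-node product over fan-in-restricted parent sets,
`Z(β) = Π_c Σ_{|π|≤3} exp(−β ε(c, π))`. This sums over parent-set
combinations that include cyclic graphs, so it is an *upper bound* on the
DAG-only sum (verified exhaustively in tests for n ≤ 4). The inverse
temperature `β` gets a uniform prior on `[0, β_max]` (default `β_max = 30`)
and is sampled, letting the data switch the prior knowledge on or off.

Benchmark belief matrices: `B100` equals the gold adjacency (energy 0);
`B50` flips exactly `⌊n(n−1)/2⌋` seeded ordered off-diagonal entries of
`B100`, i.e. half the prior is wrong.

## Sampling

Structure MCMC over DAGs with fan-in bound 3: at each step a move is drawn
uniformly from the valid single-edge changes (add / delete / reverse) of the
current DAG, and accepted with the Metropolis-Hastings probability

```
min(1, exp(Δ log P(D|M) + Δ log P(M)) · |N(old)| / |N(new)|)
```

where `|N(·)|` is the neighborhood size (the Hastings correction for the
non-symmetric proposal). Graphs are held as per-node parent bitmasks;
acyclicity of additions and reversals is checked with bitmask descendant
sets, and only changed local scores are recomputed (lazy per-child score
tables keyed by parent bitmask).

**BN-E sub-moves.** The chain strictly alternates a structure sub-move (at
fixed β, prior log-ratio `−β ΔE` with `ΔE` computed incrementally) and a β
sub-move. β proposals are uniform in `± β_step` (default 1.0), reflected at
the boundaries of `[0, β_max]`; the β acceptance ratio is
`exp(−(β' − β) E(M)) · Z(β)/Z(β')` — the partition functions do not cancel
and are evaluated (memoized per β) from the per-node parent-set sums.

**Initialization.** Chains start from the empty graph. The initial β is 0
(the flat prior). Starting hot (e.g. `β_max/2`) can anneal the structure
chain into the prior's minimum-energy mode before the data act; with a
half-wrong prior this occasionally traps a finite chain in a wrong mode
(observable as two-run disagreement). Starting at β = 0 lets β climb freely
during burn-in and is neutral for a correct prior.

**Defaults.** 5×10⁵ steps, first half discarded as burn-in, thinned
snapshots every 100 steps. After burn-in every visited structure is counted;
at the end each unique structure is converted to its equivalence class and
the counts accumulated into edge posteriors.

### Equivalence classes and edge posteriors

BGe cannot distinguish Markov-equivalent DAGs on observational data, so
posterior mass is reported at the class level: each sampled DAG is converted
to its CPDAG (v-structure orientation followed by Meek rules R1–R3; R4 is
unneeded without background-knowledge edges). For BN-I the refinement is
TS-equivalence: intervened nodes keep their exact parent sets (implemented
by attaching dummy parents to intervened nodes before completion, then
stripping them). An undirected CPDAG edge contributes to *both* directions
of the directed-edge posterior (superposition of the two orientations); a
separate symmetric accumulator tracks the skeleton posterior. Accumulating
raw DAGs instead is available as a sensitivity option (`--raw-dags`).

### Convergence diagnostics

`check_convergence` compares edge posteriors of two independently seeded
chains (max absolute difference below a threshold, default 0.1). Agreement
between two runs is a necessary but not a sufficient condition for
convergence; the CLI `infer` command always runs two seeds and exits with
code 3 on disagreement.

## Evaluation

Edge posteriors are scored against a gold standard by ROC AUC:

- **DGE** (directed): one score per ordered node pair, positives = gold
  directed edges.
- **UGE** (undirected): one score per unordered pair from the skeleton
  posterior, positives = gold skeleton.

AUC is computed exactly via the mid-rank Mann-Whitney statistic (ties get
mid-ranks), cross-checked in tests against an off-the-shelf implementation.
A perfect ranking gives 1.00; uniform-random scores average 0.50 (the
baseline recomputed by `scripts/acceptance.py`).

β posteriors are summarized by quantiles and a Gaussian KDE renormalized on
`[0, β_max]`.

## Synthetic benchmark

The bundled gold standard is the 11-node, 20-edge consensus Raf signalling
pathway of the flow-cytometry literature (`src/bninfer/data/raf_gold.tsv`).
The generator draws edge weights with `|w| ~ Uniform[0.5, 2]` and random
sign, simulates records in topological order with noise σ = 0.1, and clamps
intervened nodes to ±1 (down/up). The benchmark design uses 16 observational
records plus 14 records for each of 6 intervention blocks (Akt, PKC, PIP2,
Mek inhibited; PKC, PKA activated — PKC appears as two distinct blocks), 100
records total. Replicate datasets draw fresh weights *and* fresh noise from
seeds derived from one base seed.

A nonlinear generator (`simulate_sigmoid`, tanh squashing of the same linear
predictor) is provided only as a clearly labelled synthetic stand-in and is
excluded from all quantitative checks.

## Numerical choices

- All linear algebra in float64; log-determinants via `slogdet` with an
  explicit positive-definiteness check.
- `log Z(β)` via a vectorized, max-shifted log-sum-exp over a precomputed
  (node × parent-set) energy matrix.
- Seeds: `numpy.random.default_rng`; replicate seeds from
  `SeedSequence.spawn`, reduced mod 2³¹.

## Limitations

- Exhaustive enumeration (the exact-posterior oracle) is limited to n ≤ 5.
- The partition-function approximation is an upper bound, not the DAG-exact
  normalizer; this follows the per-node factorization and affects only the
  β sub-move.
- Single-chain Metropolis-Hastings only (no order-MCMC, edge-reversal moves,
  or parallel tempering); on 100-record, 11-node problems with a misleading
  prior, occasional slow mixing is visible at reduced step counts and is
  flagged by the two-run convergence check.
- No missing data; columns must be non-constant (standardization).
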