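"""Evaluation: edge posteriors, DGE/UGE ROC-AUC, beta summaries, comparisons."""

import numpy as np
import pytest
import sklearn.metrics
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bninfer import (
    BeliefMatrix, Dataset, EdgePosterior, McmcConfig, MethodSpec, Network,
    auc_from_scores, beta_posterior_summary, compare_methods, dag_to_cpdag,
    edge_posteriors, roc_auc, run_mcmc,
)
from bninfer.evaluate import EvaluationError
from bninfer.mcmc import Trace
from bninfer.simulate import GoldStandard

from conftest import NAMES3, chain3_dataset


def _single_sample_trace(net: Network) -> Trace:
    """A trace whose single retained sample is the CPDAG of ``net``."""
    d, s = dag_to_cpdag(net).edge_matrices()
    return Trace(
        node_names=net.node_names, method="bn", config=McmcConfig(n_steps=2),
        edge_count_accumulator=d, skeleton_accumulator=s, n_samples=1,
        beta_samples=np.array([]), log_score_series=np.zeros(2),
        acceptance_rates={}, snapshots=[],
    )


class TestEdgePosteriors:
    def test_single_vstructure_sample(self):
        post = edge_posteriors(
            _single_sample_trace(
                Network.from_edges(NAMES3, [("A", "C"), ("B", "C")])
            )
        )
        assert post.directed[0, 2] == 1.0 and post.directed[2, 0] == 0.0
        assert post.skeleton[0, 2] == post.skeleton[2, 0] == 1.0
        assert post.skeleton[0, 1] == 0.0

    def test_undirected_chain_counts_both_directions(self):
        """A reversible edge is the superposition of both orientations."""
        post = edge_posteriors(
            _single_sample_trace(
                Network.from_edges(NAMES3, [("A", "B"), ("B", "C")])
            )
        )
        assert post.directed[0, 1] == post.directed[1, 0] == 1.0
        assert post.directed[1, 2] == post.directed[2, 1] == 1.0

    def test_long_run_matches_enumeration(self, data3):
        from bninfer import exhaustive_edge_posteriors

        exact_d, exact_s = exhaustive_edge_posteriors(data3, "bn")
        trace = run_mcmc(data3, "bn", McmcConfig(n_steps=60_000, seed=1))
        post = edge_posteriors(trace)
        assert np.abs(post.directed - exact_d).max() < 0.05
        assert np.abs(post.skeleton - exact_s).max() < 0.05

    def test_empty_trace_rejected(self):
        t = _single_sample_trace(Network.empty(NAMES3))
        t.n_samples = 0
        with pytest.raises(EvaluationError):
            edge_posteriors(t)


class TestAuc:
    def test_perfect_predictor_is_exactly_one(self, raf):
        adj = raf.network.adjacency.astype(float)
        post = EdgePosterior(adj, ((adj + adj.T) > 0).astype(float), 1,
                             raf.network.node_names)
        assert roc_auc(post, raf, "dge").auc == 1.0
        assert roc_auc(post, raf, "uge").auc == 1.0

    def test_random_predictor_near_half(self, raf, rng):
        n = raf.network.n_nodes
        aucs = []
        for _ in range(300):
            scores = rng.random((n, n))
            np.fill_diagonal(scores, 0.0)
            post = EdgePosterior(scores, np.maximum(scores, scores.T), 1,
                                 raf.network.node_names)
            aucs.append(roc_auc(post, raf, "dge").auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_tied_scores_use_midranks(self):
        """Hand-computed Mann-Whitney value on a 4-candidate ranking with a tie:
        positives score (0.9, 0.5), negatives (0.5, 0.1); pair wins 3.5 of 4."""
        auc = auc_from_scores([0.9, 0.5, 0.5, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(3.5 / 4.0)

    def test_matches_sklearn_on_random_problems(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(100):
            n = int(rng.integers(10, 60))
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
            scores = np.round(rng.random(n), 2)  # rounding induces ties
            if labels.all() or not labels.any():
                continue
            assert auc_from_scores(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, raf, rng):
        n = raf.network.n_nodes
        scores = rng.random((n, n))
        post1 = EdgePosterior(scores, np.maximum(scores, scores.T) * 0 + 0.5, 1,
                              raf.network.node_names)
        warped = 1 / (1 + np.exp(-7 * scores))
        post2 = EdgePosterior(warped / warped.max(),
                              post1.skeleton, 1, raf.network.node_names)
        a1 = roc_auc(post1, raf, "dge").auc
        a2 = roc_auc(post2, raf, "dge").auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_curve_is_monotone(self, raf, rng):
        n = raf.network.n_nodes
        scores = rng.random((n, n))
        post = EdgePosterior(scores, np.maximum(scores, scores.T), 1,
                             raf.network.node_names)
        res = roc_auc(post, raf, "dge")
        assert np.all(np.diff(res.tp_fraction) >= 0)
        assert np.all(np.diff(res.fp_fraction) >= 0)
        assert res.tp_fraction[-1] == 1.0 and res.fp_fraction[-1] == 1.0

    def test_degenerate_gold_rejected(self):
        post = EdgePosterior(np.zeros((3, 3)), np.zeros((3, 3)), 1, NAMES3)
        empty = GoldStandard(Network.empty(NAMES3))
        with pytest.raises(EvaluationError):
            roc_auc(post, empty, "dge")

    def test_uge_mode_switch(self, raf, rng):
        n = raf.network.n_nodes
        directed = rng.random((n, n))
        skeleton = np.maximum(directed, directed.T)
        post = EdgePosterior(directed, skeleton, 1, raf.network.node_names)
        a_skel = roc_auc(post, raf, "uge", uge_mode="skeleton").auc
        a_max = roc_auc(post, raf, "uge", uge_mode="max").auc
        assert a_skel == pytest.approx(a_max)  # identical here by construction


class TestBetaSummary:
    def _bne_trace(self, samples, beta_max=10.0):
        return Trace(
            node_names=NAMES3, method="bn-e",
            config=McmcConfig(n_steps=2, beta_max=beta_max),
            edge_count_accumulator=np.zeros((3, 3)),
            skeleton_accumulator=np.zeros((3, 3)),
            n_samples=len(samples), beta_samples=np.asarray(samples, float),
            log_score_series=np.zeros(2), acceptance_rates={}, snapshots=[],
        )

    def test_constant_chain_is_a_spike(self):
        s = beta_posterior_summary(self._bne_trace([2.5] * 100))
        assert s.median == 2.5
        k = np.argmax(s.density)
        assert s.grid[k] == pytest.approx(2.5, abs=s.grid[1] - s.grid[0])

    def test_density_integrates_to_one(self, rng):
        samples = rng.uniform(1, 6, size=4000)
        s = beta_posterior_summary(self._bne_trace(samples))
        mass = np.trapezoid(s.density, s.grid)
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_plain_bn_trace_rejected(self, data3):
        t = run_mcmc(data3, "bn", McmcConfig(n_steps=500, seed=1))
        with pytest.raises(EvaluationError):
            beta_posterior_summary(t)


class TestCompareMethods:
    def test_duplicated_dataset_gives_zero_sd(self, data3):
        gold = GoldStandard(
            Network.from_edges(NAMES3, [("A", "B"), ("B", "C")])
        )
        cfg = McmcConfig(n_steps=3000, seed=1, fan_in=2)
        result = compare_methods(
            [(data3, None), (data3, None)],
            [MethodSpec("BN", "bn")], gold, cfg, seeds=[7, 7],
        )
        assert np.all(result.table["sd_auc"] == 0.0)
        assert set(result.table["criterion"]) == {"DGE", "UGE"}

    def test_gold_mismatch_rejected(self, data3):
        gold = GoldStandard(Network.empty(("X", "Y", "Z")))
        with pytest.raises(EvaluationError):
            compare_methods([(data3, None)], [MethodSpec("BN", "bn")],
                            gold, McmcConfig(n_steps=100))


class TestAucProperties:
    """Property-based invariants of the Mann-Whitney AUC implementation."""

    @given(
        # quantized scores: with unrestricted floats, scale*x + shift can
        # round distinct scores to a tie, making the transform non-strict
        scores=hnp.arrays(
            np.float64, 12,
            elements=st.integers(0, 10**6).map(lambda k: k / 10**6),
        ),
        labels=hnp.arrays(np.bool_, 12),
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_invariant_under_strictly_increasing_transforms(
        self, scores, labels, scale, shift
    ):
        """AUC depends only on the ranking, so any strictly increasing
        transform of the scores leaves it unchanged; it also always matches
        the off-the-shelf implementation."""
        assume(labels.any() and not labels.all())
        base = auc_from_scores(scores, labels)
        assert auc_from_scores(scale * scores + shift, labels) == pytest.approx(
            base, abs=1e-12
        )
        assert base == pytest.approx(
            sklearn.metrics.roc_auc_score(labels, scores), abs=1e-12
        )

    @given(
        scores=hnp.arrays(np.float64, 10,
                          elements=st.floats(0.0, 1.0, width=64)),
        labels=hnp.arrays(np.bool_, 10),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_complement_symmetry(self, scores, labels):
        """Flipping the labels mirrors the AUC around one half."""
        assume(labels.any() and not labels.all())
        assert auc_from_scores(scores, labels) + auc_from_scores(
            scores, ~labels
        ) == pytest.approx(1.0, abs=1e-12)
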