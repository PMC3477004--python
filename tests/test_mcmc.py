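"""Samplers: acceptance formulas, beta proposal, traces, convergence."""

import math

import numpy as np
import pytest

from bninfer import (
    BeliefMatrix, GibbsPrior, McmcConfig, Network,
    check_convergence, energy, exhaustive_edge_posteriors, joint_acceptance,
    log_marginal_likelihood, neighbor_moves, propose_beta, run_mcmc,
    structure_acceptance,
)
from bninfer.graphs import apply_move
from bninfer.mcmc import McmcError
from bninfer.scoring import InterventionMask

from conftest import NAMES3, chain3_dataset


class TestStructureAcceptance:
    def test_degenerate_self_move_accepts(self, data3):
        net = Network.empty(NAMES3)
        assert structure_acceptance(net, net, data3) == 1.0

    def test_matches_independent_formula(self, data3, rng):
        """Term-by-term reassembly of the Metropolis-Hastings ratio."""
        net = Network.from_edges(NAMES3, [("A", "B")])
        moves, n_old = neighbor_moves(net, fan_in=2)
        for k in rng.choice(len(moves), size=5, replace=False):
            new = apply_move(net, moves[k])
            _, n_new = neighbor_moves(new, fan_in=2)
            expected = min(
                1.0,
                math.exp(
                    log_marginal_likelihood(new, data3)
                    - log_marginal_likelihood(net, data3)
                )
                * n_old / n_new,
            )
            got = structure_acceptance(net, new, data3, fan_in=2)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_prior_log_ratio_shifts_acceptance(self, data3):
        net = Network.empty(NAMES3)
        new = Network.from_edges(NAMES3, [("A", "B")])
        base = structure_acceptance(net, new, data3)
        pushed = structure_acceptance(net, new, data3, prior_log_ratio=-50.0)
        assert pushed <= base and pushed == pytest.approx(
            min(1.0, base * math.exp(-50.0)) if base < 1 else pushed, rel=1e-6
        )


class TestProposeBeta:
    def test_reflection_keeps_range(self, rng):
        cfg = McmcConfig(n_steps=10, beta_max=5.0, beta_step=2.0)
        for beta in (0.0, 0.3, 4.9, 5.0):
            draws = [propose_beta(beta, cfg, rng) for _ in range(2000)]
            assert all(0.0 <= d <= 5.0 for d in draws)

    def test_reflection_at_zero_folds_into_positive_range(self, rng):
        cfg = McmcConfig(n_steps=10, beta_max=30.0, beta_step=1.0)
        draws = np.array([propose_beta(0.0, cfg, rng) for _ in range(5000)])
        assert draws.max() <= 1.0 + 1e-12
        assert draws.min() >= 0.0

    def test_proposal_symmetry(self, rng):
        """Empirical density of a->b matches b->a (detailed-balance input)."""
        cfg = McmcConfig(n_steps=10, beta_max=4.0, beta_step=1.5)
        a, b, h = 0.4, 1.2, 0.12
        n = 100_000
        from_a = np.array([propose_beta(a, cfg, rng) for _ in range(n)])
        from_b = np.array([propose_beta(b, cfg, rng) for _ in range(n)])
        p_ab = np.mean(np.abs(from_a - b) <= h)
        p_ba = np.mean(np.abs(from_b - a) <= h)
        se = math.sqrt(p_ab * (1 - p_ab) / n + p_ba * (1 - p_ba) / n)
        assert abs(p_ab - p_ba) < 4 * se + 1e-9

    def test_zero_step_pins_beta(self, rng):
        cfg = McmcConfig(n_steps=10, beta_max=5.0, beta_step=0.0, beta_init=2.0)
        assert propose_beta(2.0, cfg, rng) == 2.0


class TestJointAcceptance:
    @pytest.fixture
    def belief(self, rng):
        return BeliefMatrix(rng.random((3, 3)), NAMES3)

    def test_structure_submove_reduces_to_structure_acceptance(self, data3, belief):
        old = Network.empty(NAMES3)
        new = Network.from_edges(NAMES3, [("A", "B")])
        beta = 1.3
        de = energy(new, belief) - energy(old, belief)
        expected = structure_acceptance(
            old, new, data3, prior_log_ratio=-beta * de
        )
        got = joint_acceptance((old, beta), (new, beta), data3, belief=belief)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_beta_submove_with_zero_energy_is_partition_ratio(self, data3, raf):
        """With E(M) = 0 the exponential term is 1: A = min(1, Z_old/Z_new)."""
        from bninfer import make_b100

        b = make_b100(raf.network)
        gp = GibbsPrior(b, beta_max=10.0, fan_in=3)
        from bninfer.scoring import Dataset

        data = Dataset(np.random.default_rng(0).normal(size=(10, 11)),
                       raf.network.node_names)
        b_old, b_new = 1.0, 2.5
        got = joint_acceptance((raf.network, b_old), (raf.network, b_new),
                               data, gibbs=gp)
        expected = min(
            1.0, math.exp(gp.log_partition(b_old) - gp.log_partition(b_new))
        )
        assert got == pytest.approx(expected, rel=1e-10)

    def test_beta_submove_matches_independent_formula(self, data3, belief):
        gp = GibbsPrior(belief, beta_max=10.0, fan_in=2)
        net = Network.from_edges(NAMES3, [("A", "B"), ("B", "C")])
        b_old, b_new = 2.0, 3.1
        e = energy(net, belief)
        expected = min(
            1.0,
            math.exp(-(b_new - b_old) * e)
            * math.exp(gp.log_partition(b_old) - gp.log_partition(b_new)),
        )
        got = joint_acceptance((net, b_old), (net, b_new), data3, gibbs=gp)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_submove_discipline_enforced(self, data3, belief):
        old = Network.empty(NAMES3)
        new = Network.from_edges(NAMES3, [("A", "B")])
        with pytest.raises(McmcError):
            joint_acceptance((old, 1.0), (new, 2.0), data3, belief=belief)


class TestRunMcmc:
    def test_same_seed_is_bit_reproducible(self, data3):
        cfg = McmcConfig(n_steps=4000, seed=7)
        a = run_mcmc(data3, "bn", cfg)
        b = run_mcmc(data3, "bn", cfg)
        np.testing.assert_array_equal(
            a.edge_count_accumulator, b.edge_count_accumulator
        )
        np.testing.assert_array_equal(a.log_score_series, b.log_score_series)
        for k in ("add", "delete", "reverse"):
            assert a.acceptance_rates[k] == b.acceptance_rates[k]

    def test_bni_with_all_false_mask_equals_bn(self, data3):
        cfg = McmcConfig(n_steps=4000, seed=3)
        mask = InterventionMask.none(data3.n_records, 3)
        bn = run_mcmc(data3, "bn", cfg)
        bni = run_mcmc(data3, "bn-i", cfg, mask=mask)
        np.testing.assert_array_equal(
            bn.edge_count_accumulator, bni.edge_count_accumulator
        )
        np.testing.assert_array_equal(bn.log_score_series, bni.log_score_series)

    def test_method_requirements_enforced(self, data3):
        cfg = McmcConfig(n_steps=100)
        with pytest.raises(McmcError):
            run_mcmc(data3, "bn-i", cfg)
        with pytest.raises(McmcError):
            run_mcmc(data3, "bn-e", cfg)

    def test_stationary_frequencies_match_exact_posterior(self, data3):
        """Detailed balance + ergodicity: DAG visit frequencies converge to
        the enumerated posterior over all 25 structures."""
        cfg = McmcConfig(n_steps=100_000, seed=5, fan_in=2)
        trace = run_mcmc(data3, "bn", cfg)
        from bninfer import BgeScorer, enumerate_dags

        scorer = BgeScorer(data3)
        logw = {}
        for net in enumerate_dags(3, 2):
            named = Network(NAMES3, net.adjacency)
            logw[tuple(named.parent_masks())] = scorer.score_network(named)
        mx = max(logw.values())
        z = sum(math.exp(v - mx) for v in logw.values())
        exact = {k: math.exp(v - mx) / z for k, v in logw.items()}
        total = sum(trace.structure_counts.values())
        for key, p in exact.items():
            freq = trace.structure_counts.get(key, 0) / total
            assert freq == pytest.approx(p, abs=0.05)

    def test_beta_chain_stays_in_range_and_orders_by_prior_quality(self, data3):
        """Good prior knowledge sustains larger beta than corrupted knowledge."""
        gold = Network.from_edges(NAMES3, [("A", "B"), ("B", "C")])
        from bninfer import make_b100

        b100 = make_b100(gold)
        # fully wrong beliefs: complement of the correct matrix
        wrong = BeliefMatrix(1.0 - b100.entries, NAMES3)
        cfg = McmcConfig(n_steps=30_000, seed=9, beta_max=30.0)
        t_good = run_mcmc(data3, "bn-e", cfg, belief=b100)
        t_bad = run_mcmc(data3, "bn-e", cfg, belief=wrong)
        for t in (t_good, t_bad):
            assert t.beta_samples.min() >= 0.0
            assert t.beta_samples.max() <= cfg.beta_max
        assert np.median(t_good.beta_samples) > np.median(t_bad.beta_samples)

    def test_bne_at_beta_zero_reproduces_bn(self, data3):
        cfg_bn = McmcConfig(n_steps=40_000, seed=2, fan_in=2)
        cfg_bne = McmcConfig(n_steps=80_000, seed=2, fan_in=2,
                             beta_step=0.0, beta_init=0.0)
        b = BeliefMatrix.uninformative(NAMES3)
        p_bn = run_mcmc(data3, "bn", cfg_bn).directed_posterior
        p_bne = run_mcmc(data3, "bn-e", cfg_bne, belief=b).directed_posterior
        assert np.abs(p_bn - p_bne).max() < 0.05


class TestCheckConvergence:
    def test_trace_against_itself_passes(self, data3):
        t = run_mcmc(data3, "bn", McmcConfig(n_steps=2000, seed=1))
        report = check_convergence(t, t)
        assert report.max_abs_diff == 0.0
        assert report.passed
        assert "necessary but not a sufficient" in str(report)

    def test_two_long_runs_agree(self, data3):
        cfg = McmcConfig(n_steps=50_000, fan_in=2)
        a = run_mcmc(data3, "bn", McmcConfig(n_steps=50_000, seed=1, fan_in=2))
        b = run_mcmc(data3, "bn", McmcConfig(n_steps=50_000, seed=2, fan_in=2))
        report = check_convergence(a, b, threshold=0.1)
        assert report.passed
        assert len(report.scatter) == 6  # ordered off-diagonal pairs

    def test_short_runs_on_large_system_fail(self, raf_dataset):
        data, _ = raf_dataset
        a = run_mcmc(data, "bn", McmcConfig(n_steps=300, seed=1))
        b = run_mcmc(data, "bn", McmcConfig(n_steps=300, seed=2))
        report = check_convergence(a, b, threshold=0.1)
        assert not report.passed

    def test_shape_mismatch_rejected(self, data3, raf_dataset):
        t3 = run_mcmc(data3, "bn", McmcConfig(n_steps=500, seed=1))
        t11 = run_mcmc(raf_dataset[0], "bn", McmcConfig(n_steps=500, seed=1))
        with pytest.raises(McmcError):
            check_convergence(t3, t11)


class TestTracePersistence:
    def test_save_writes_posterior_beta_and_metadata(self, tmp_path, data3):
        b = BeliefMatrix.uninformative(NAMES3)
        t = run_mcmc(data3, "bn-e", McmcConfig(n_steps=2000, seed=4), belief=b)
        t.save(tmp_path / "run")
        import json

        assert (tmp_path / "run" / "posterior_directed.csv").exists()
        assert (tmp_path / "run" / "beta_samples.tsv").exists()
        meta = json.loads((tmp_path / "run" / "run_metadata.json").read_text())
        assert meta["method"] == "bn-e"
        assert meta["n_samples"] == t.n_samples
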