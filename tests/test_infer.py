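"""Poisson likelihood, ILP solving, and the brute-force oracle."""

import math

import numpy as np
import pytest

from prego import (Adjacency, DepthProfile, InputError, LikelihoodParams,
                   balance_residuals, brute_force_oracle, build_graph,
                   detect_telomere_loss, expected_depth, neg_log_likelihood,
                   solve_multiplicities)
from prego.infer import STATUS_INFEASIBLE, STATUS_OPTIMAL

from conftest import make_intervals, random_small_instance


class TestExpectedDepth:
    def test_at_tau_collapses_to_lander_waterman(self):
        p = LikelihoodParams(lam=[1000 * 100 / 1000.0], tau=2.0)
        assert expected_depth(p, 0, 2) == pytest.approx(100.0)

    def test_zero_multiplicity(self):
        p = LikelihoodParams(lam=[100.0])
        assert expected_depth(p, 0, 0) == 0.0

    def test_direct_evaluation(self):
        # N=450, L_j=30, L_R=300 -> lambda=45; mu=3, tau=2 -> 67.5
        p = LikelihoodParams(lam=[450 * 30 / 300.0], tau=2.0)
        assert expected_depth(p, 0, 3) == pytest.approx(67.5)

    def test_zero_reference_length_rejected(self):
        profile = DepthProfile(np.array([1.0]), np.array([1.0]))
        profile.lengths = np.array([1.0])
        with pytest.raises(InputError):
            LikelihoodParams(lam=[0.0])


class TestNegLogLikelihood:
    def test_single_interval_value(self):
        p = LikelihoodParams(lam=[10.0], tau=2.0)
        val = neg_log_likelihood(p, [2], [10.0])
        assert val == pytest.approx(10 - 10 * math.log(10), abs=1e-9)

    def test_empty_counts_zero_mu(self):
        p = LikelihoodParams(lam=[5.0, 7.0], tau=2.0)
        assert neg_log_likelihood(p, [0, 0], [0.0, 0.0]) == pytest.approx(0.0)

    def test_discrete_optimum_neighbors_continuous_one(self):
        # per-term continuous minimizer is mu = tau * r / lambda; the best
        # integer is one of its two neighbors
        rng = np.random.default_rng(7)
        for _ in range(20):
            lam = float(rng.uniform(20, 200))
            r = float(rng.uniform(0, 400))
            p = LikelihoodParams(lam=[lam], tau=2.0)
            cont = 2.0 * r / lam
            hi = math.ceil(cont) + 3
            values = [neg_log_likelihood(p, [m], [r]) for m in range(hi + 1)]
            best = int(np.argmin(values))
            assert best in (math.floor(cont), math.ceil(cont))

    def test_negative_counts_rejected(self):
        p = LikelihoodParams(lam=[10.0])
        with pytest.raises(InputError):
            neg_log_likelihood(p, [1], [-1.0])

    def test_zero_mu_uses_epsilon_surrogate(self):
        p = LikelihoodParams(lam=[10.0], tau=2.0, epsilon_copies=0.05)
        val = neg_log_likelihood(p, [0], [4.0])
        assert val == pytest.approx(-4 * math.log(10 * 0.05 / 2), abs=1e-9)


class TestSolve:
    def test_toy_instance_copy_numbers(self, toy_graph, toy_depth, toy_counts):
        res = solve_multiplicities(toy_graph, toy_depth)
        assert res.solver_status == STATUS_OPTIMAL
        assert list(res.interval_copy_numbers(toy_graph)) == toy_counts

    def test_toy_has_co_optimal_unused_variant_solution(self, toy_graph,
                                                        toy_depth):
        # rerouting the inversion pair through reference edges leaves the
        # objective unchanged, so an all-variants-used optimum and one with
        # zeroed variant edges coexist
        params = LikelihoodParams.from_profile(toy_depth, mu_max=2)
        oracle = brute_force_oracle(toy_graph, toy_depth, params)
        used = set()
        for mu in oracle.co_optimal:
            used.add(tuple(sorted(
                (eid, m) for eid, m in mu.items()
                if toy_graph.edges[eid].kind == "V")))
        assert len(used) >= 2

    def test_no_variants_flat_depth_recovers_tau(self):
        ivs = make_intervals(3)
        g = build_graph(ivs, [])
        depth = DepthProfile.from_intervals(ivs, [100, 100, 100])
        res = solve_multiplicities(g, depth)
        assert all(m == 2 for m in res.mu.values())

    def test_perfect_data_mode_fixes_counts(self, toy_graph, toy_depth,
                                            toy_counts):
        res = solve_multiplicities(toy_graph, toy_depth,
                                   fixed_interval_counts=toy_counts)
        assert res.solver_status == STATUS_OPTIMAL
        assert list(res.interval_copy_numbers(toy_graph)) == toy_counts

    def test_inconsistent_fixed_counts_reported_infeasible(self):
        # two intervals, no variant edge: balance forces equal counts
        ivs = make_intervals(2)
        g = build_graph(ivs, [])
        depth = DepthProfile.from_intervals(ivs, [100, 100])
        res = solve_multiplicities(g, depth, fixed_interval_counts=[1, 2])
        assert res.solver_status == STATUS_INFEASIBLE

    def test_solver_matches_oracle_on_random_small_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            graph, depth, params = random_small_instance(rng)
            res = solve_multiplicities(graph, depth, params)
            oracle = brute_force_oracle(graph, depth, params)
            assert res.solver_status == oracle.best.solver_status
            if res.solver_status == STATUS_OPTIMAL:
                assert res.objective_value == pytest.approx(
                    oracle.best.objective_value, abs=1e-6)
                assert all(v == 0 for v in
                           balance_residuals(graph, res.mu).values())

    def test_prefer_sparse_zeroes_trivial_reroutes(self, toy_graph, toy_depth):
        res = solve_multiplicities(toy_graph, toy_depth, prefer_sparse=True)
        plain = solve_multiplicities(toy_graph, toy_depth)
        total = sum(res.mu[e.id] for e in toy_graph.edges_of_kind("V"))
        total_plain = sum(plain.mu[e.id] for e in toy_graph.edges_of_kind("V"))
        assert total <= total_plain
        assert res.objective_value == pytest.approx(plain.objective_value,
                                                    abs=1e-6)

    def test_monotone_consistency_under_depth_doubling(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            graph, depth, params = random_small_instance(rng)
            o1 = brute_force_oracle(graph, depth, params)
            depth2 = DepthProfile(depth.r * 2, depth.lengths, depth.tau)
            params2 = LikelihoodParams(params.lam * 2, params.tau,
                                       params.mu_max, params.epsilon_copies)
            o2 = brute_force_oracle(graph, depth2, params2)
            key = lambda mu: tuple(sorted(mu.items()))
            assert {key(m) for m in o1.co_optimal} == \
                {key(m) for m in o2.co_optimal}

    def test_sigma_extension_preserves_feasibility(self):
        ivs = make_intervals(2)
        g = build_graph(ivs, [])
        depth = DepthProfile.from_intervals(ivs, [10_000, 100])
        base = solve_multiplicities(g, depth)
        assert base.solver_status == STATUS_OPTIMAL
        g2 = detect_telomere_loss(g, depth, 0.5)
        assert g2.has_sigma
        res = solve_multiplicities(g2, depth)
        assert res.solver_status == STATUS_OPTIMAL
        # the sigma edge lets the two intervals carry different copy numbers
        c = res.interval_copy_numbers(g2)
        assert c[0] > c[1]


class TestBalanceResiduals:
    def test_simple_arithmetic(self):
        ivs = make_intervals(2)
        g = build_graph(ivs, [Adjacency((1, "end"), (2, "end"))])
        mu = {e.id: 0 for e in g.edges}
        mu[g.interval_edge(1).id] = 2
        mu[g.reference_edge_at(("t", 1)).id] = 1
        res = balance_residuals(g, mu)
        assert res[("t", 1)] == 1

    def test_self_loop_counts_twice(self):
        ivs = make_intervals(2)
        g = build_graph(ivs, [Adjacency((1, "end"), (1, "end"))])
        loop = [e for e in g.edges_of_kind("V") if e.is_loop][0]
        mu = {e.id: 0 for e in g.edges}
        mu[g.interval_edge(1).id] = 3
        mu[g.reference_edge_at(("t", 1)).id] = 1
        mu[loop.id] = 1
        assert balance_residuals(g, mu)[("t", 1)] == 0


def test_oracle_refuses_oversized_state_space():
    ivs = make_intervals(3)
    g = build_graph(ivs, [Adjacency((1, "end"), (3, "start"))])
    depth = DepthProfile.from_intervals(ivs, [100, 100, 100])
    params = LikelihoodParams.from_profile(depth, mu_max=4)
    with pytest.raises(InputError):
        brute_force_oracle(g, depth, params, state_guard=10)


def test_oracle_single_interval_recovers_tau():
    ivs = make_intervals(1)
    g = build_graph(ivs, [])
    depth = DepthProfile.from_intervals(ivs, [100.0])
    params = LikelihoodParams.from_profile(depth, mu_max=4)
    oracle = brute_force_oracle(g, depth, params)
    assert oracle.best.mu == {0: 2}
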