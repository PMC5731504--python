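"""Proposal distributions, acceptance rule, and the annealing loop."""

import math

import numpy as np
import pytest

from complexsampler import (
    PPINetwork,
    ScoreParams,
    SamplerParams,
    run_sampler,
)
from complexsampler.sampler import (
    MOVE_ADD_CLUSTER,
    MOVE_NOOP,
    acceptance_probability,
    cool,
    propose_add_cluster,
    propose_add_protein,
    propose_gamma,
    propose_remove_cluster,
    propose_remove_protein,
)
from complexsampler import scoring
from complexsampler.network_io import induced_subgraph_connected

N_DRAWS = 100_000
ALPHA = (0.25, 0.25, 0.25, 0.25)


class TestProposeAddCluster:
    def test_single_edge_probabilities(self, rng):
        net = PPINetwork([("A", "B", 1.0)])
        prop = propose_add_cluster(net, [], rng, ALPHA)
        assert prop.candidate == (frozenset("AB"),)
        assert prop.q_forward == pytest.approx(0.25)
        assert prop.q_reverse == pytest.approx(0.25)

    def test_duplicate_cluster_is_noop(self, rng):
        net = PPINetwork([("A", "B", 1.0)])
        prop = propose_add_cluster(net, [frozenset("AB")], rng, ALPHA)
        assert prop.move_kind == MOVE_NOOP
        assert prop.candidate == (frozenset("AB"),)

    def test_edge_choice_proportional_to_weight(self, rng):
        net = PPINetwork([("A", "B", 1.0), ("C", "D", 3.0)])
        hits = 0
        for _ in range(N_DRAWS):
            prop = propose_add_cluster(net, [], rng, ALPHA)
            if prop.added == frozenset("AB"):
                hits += 1
        assert hits / N_DRAWS == pytest.approx(0.25, abs=0.01)


class TestProposeAddProtein:
    def test_single_candidate(self, rng):
        net = PPINetwork([("A", "B", 1.0), ("B", "C", 0.4)])
        prop = propose_add_protein(net, [frozenset("AB")], rng, ALPHA)
        assert prop.added == frozenset("ABC")
        assert prop.q_forward == pytest.approx(0.25 * 1.0 * 1.0)

    def test_empty_cluster_set_is_noop(self, rng):
        net = PPINetwork([("A", "B", 1.0)])
        assert propose_add_protein(net, [], rng, ALPHA).move_kind == MOVE_NOOP

    def test_neighbor_choice_proportional_to_connection(self, rng):
        # u connects with weight 0.2, v with 0.6 -> u picked 1/4 of the time
        net = PPINetwork([("A", "B", 1.0), ("A", "U", 0.2), ("B", "V", 0.6)])
        x = frozenset("AB")
        hits = 0
        for _ in range(N_DRAWS):
            prop = propose_add_protein(net, [x], rng, ALPHA)
            if "U" in prop.added:
                hits += 1
        assert hits / N_DRAWS == pytest.approx(0.25, abs=0.01)


class TestProposeRemoveCluster:
    def test_single_dimer(self, rng):
        net = PPINetwork([("A", "B", 1.0)])
        prop = propose_remove_cluster(net, [frozenset("AB")], rng, ALPHA)
        assert prop.candidate == ()
        assert prop.q_forward == pytest.approx(0.25)

    def test_no_dimers_is_noop(self, rng):
        net = PPINetwork([("A", "B", 1.0), ("B", "C", 1.0)])
        prop = propose_remove_cluster(net, [frozenset("ABC")], rng, ALPHA)
        assert prop.move_kind == MOVE_NOOP

    def test_inverse_weight_selection(self, rng):
        net = PPINetwork([("A", "B", 0.5), ("C", "D", 1.0)])
        X = [frozenset("AB"), frozenset("CD")]
        hits = 0
        for _ in range(N_DRAWS):
            prop = propose_remove_cluster(net, X, rng, ALPHA)
            if prop.removed == frozenset("AB"):
                hits += 1
        assert hits / N_DRAWS == pytest.approx(2 / 3, abs=0.01)


class TestProposeRemoveProtein:
    def test_only_dimers_is_noop(self, rng):
        net = PPINetwork([("A", "B", 1.0)])
        prop = propose_remove_protein(net, [frozenset("AB")], rng, ALPHA)
        assert prop.move_kind == MOVE_NOOP

    def test_inverse_connection_selection(self, rng):
        # triangle with w(A,x)=0.2, w(B,x)=w(C,x)=0.4:
        # 1/0.2 against 2/0.4 -> A removed half the time
        net = PPINetwork([("A", "B", 0.1), ("A", "C", 0.1), ("B", "C", 0.3)])
        x = frozenset("ABC")
        hits = 0
        for _ in range(N_DRAWS):
            prop = propose_remove_protein(net, [x], rng, ALPHA)
            if prop.added == frozenset("BC"):
                hits += 1
        assert hits / N_DRAWS == pytest.approx(0.5, abs=0.01)


class TestReversibilityBookkeeping:
    def test_reverse_density_recomputed_from_candidate(self, rng):
        """For add moves, re-deriving the reverse probability from the
        candidate state by the paired remove formula reproduces q_reverse."""
        net = PPINetwork([("A", "B", 1.0), ("B", "C", 0.8), ("C", "D", 0.6),
                          ("D", "A", 0.9), ("A", "C", 0.5)])
        X = []
        checked = 0
        for _ in range(10_000):
            kind = rng.integers(2)
            if kind == 0:
                prop = propose_add_cluster(net, X, rng, ALPHA)
            else:
                prop = propose_add_protein(net, X, rng, ALPHA)
            if prop.move_kind == MOVE_NOOP:
                continue
            cand = list(prop.candidate)
            if kind == 0:
                u, v = prop.added
                w = net.weight(u, v)
                inv_sum = sum(1.0 / net.weight(*c) for c in cand
                              if len(c) == 2)
                expected = 0.25 * (1.0 / w) / inv_sum
            else:
                u = next(iter(prop.added - prop.removed))
                x_new = prop.added
                mw = {v: sum(net.weight(v, t) for t in x_new)
                      for v in x_new}
                n_ge3 = sum(1 for c in cand if len(c) >= 3)
                expected = (0.25 / n_ge3) * (1.0 / mw[u]) \
                    / sum(1.0 / w for w in mw.values())
            assert prop.q_reverse == pytest.approx(expected, rel=1e-12)
            checked += 1
            # keep the state small but non-trivial
            if len(cand) <= 3 and all(len(c) <= 3 for c in cand):
                X = cand
        assert checked > 1000


class TestGammaProposal:
    def test_moments(self, rng):
        sd = math.sqrt(0.001)
        draws = np.array([propose_gamma(2.5, sd, 1e-10, rng)
                          for _ in range(N_DRAWS)])
        assert draws.mean() == pytest.approx(2.5, abs=0.001)
        assert draws.std() == pytest.approx(sd, rel=0.02)

    def test_floor_clamps(self, rng):
        class NegRng:
            def standard_normal(self):
                return -1e6
        assert propose_gamma(1e-10, 0.03, 1e-10, NegRng()) == 1e-10


class TestAcceptanceProbability:
    def test_closed_forms(self):
        assert acceptance_probability(1.0, 1.0, 1.0, 0.3, 0.3) == 1.0
        assert acceptance_probability(1.0, math.inf, 1.0, 0.3, 0.3) == 0.0
        t = 0.7
        a = acceptance_probability(0.0, t * math.log(2), t, 0.3, 0.3)
        assert a == pytest.approx(0.5)

    def test_hastings_ratio_applied(self):
        a = acceptance_probability(1.0, 1.0, 1.0, 0.5, 0.25,
                                   use_hastings=True)
        assert a == pytest.approx(0.5)
        a = acceptance_probability(1.0, 1.0, 1.0, 0.5, 0.25,
                                   use_hastings=False)
        assert a == 1.0

    def test_impossible_reverse_forces_rejection(self):
        assert acceptance_probability(5.0, 0.0, 1.0, 0.3, 0.0) == 0.0

    def test_temperature_domain(self):
        with pytest.raises(ValueError):
            acceptance_probability(0.0, 0.0, 0.0, 1.0, 1.0)


class TestCooling:
    def test_geometric_schedule(self):
        assert cool(1.0, 0.999999) == pytest.approx(0.999999)
        t = 1.0
        for _ in range(100):
            t = cool(t, 0.999999)
        assert t == pytest.approx(0.999999 ** 100)
        assert cool(0.5, 1.0) == 0.5  # fixed-temperature mode


class TestRunSampler:
    def test_deterministic_given_seed(self):
        net = PPINetwork([("A", "B", 1.0), ("B", "C", 0.5)])
        pp = SamplerParams(n_iterations=5000, seed=11, trace_every=100)
        r1 = run_sampler(net, ScoreParams(), pp)
        r2 = run_sampler(net, ScoreParams(), pp)
        assert r1.best_score == r2.best_score
        assert r1.trace == r2.trace
        assert r1.best_clusters == r2.best_clusters
        assert r1.best_gamma == r2.best_gamma

    def test_single_edge_network_finds_the_dimer(self):
        # two-state space: the lone dimer gains density and histogram mass
        net = PPINetwork([("A", "B", 1.0)])
        res = run_sampler(net, ScoreParams(),
                          SamplerParams(n_iterations=10_000, seed=3))
        assert set(res.best_clusters) == {frozenset("AB")}
        assert res.best_score < scoring.total_score(
            net, [], 2.5, ScoreParams()).total

    def test_best_score_bounds_the_trace(self):
        net = PPINetwork([("A", "B", 1.0), ("B", "C", 0.5), ("C", "D", 0.9)])
        res = run_sampler(net, ScoreParams(),
                          SamplerParams(n_iterations=20_000, seed=5,
                                        trace_every=500))
        assert res.best_score <= min(f for _, f in res.trace)
        assert math.isfinite(res.best_score)

    def test_visited_states_always_feasible(self, square_net):
        sp = ScoreParams(s_max=3, c_clu_dis=1.0, c_clu_size=5.0,
                         c_pro_num=0.01)
        pp = SamplerParams(n_iterations=20_000, seed=9, gamma_step_sd=0.0,
                           cooling_factor=1.0, collect_state_counts=True)
        res = run_sampler(square_net, sp, pp)
        for state in res.state_counts:
            for x in state:
                assert 2 <= len(x) <= 3
                assert induced_subgraph_connected(square_net, x)
            bd = scoring.total_score(square_net, state, 2.5, sp)
            assert math.isfinite(bd.total)

    def test_incremental_scoring_matches_full_recompute(self):
        net = PPINetwork([("A", "B", 1.0), ("B", "C", 0.7), ("C", "D", 0.8),
                          ("D", "E", 0.9), ("E", "A", 0.6), ("B", "D", 0.4)])
        pp = SamplerParams(n_iterations=30_000, seed=21,
                           consistency_check_every=1000)
        res = run_sampler(net, ScoreParams(s_max=4), pp)
        assert res.max_consistency_error <= 1e-8

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SamplerParams(move_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SamplerParams(cooling_factor=0.0)
        with pytest.raises(ValueError):
            SamplerParams(n_iterations=0)
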