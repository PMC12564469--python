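"""Average models, robustness metrics, common network, trial loop."""

import numpy as np
import pytest

import g4causal as g
from g4causal.consensus import (ConsensusNetwork, accuracy_coverage,
                                average_model, common_network,
                                resolve_directions, robustness_auc,
                                run_trials, select_n)
from g4causal.graphs import PDAG
from g4causal.prep import SamplingConfig

from oracles import riemann_auc


def pdag(nodes, directed=(), undirected=()):
    return PDAG(nodes, directed=directed, undirected=undirected)


class TestAverageModel:
    def test_edge_in_five_of_ten_kept_at_n5(self):
        with_edge = [pdag("ab", undirected=[("a", "b")]) for _ in range(5)]
        without = [pdag("ab") for _ in range(5)]
        avg = average_model(with_edge + without, 5)
        assert avg.adjacent("a", "b")
        assert not average_model(with_edge + without, 6).adjacent("a", "b")

    def test_boundary_ns_are_union_and_intersection(self):
        c1 = pdag("abc", undirected=[("a", "b")])
        c2 = pdag("abc", undirected=[("a", "b"), ("b", "c")])
        union = average_model([c1, c2], 1)
        inter = average_model([c1, c2], 2)
        assert union.skeleton_edges() == c2.skeleton_edges()
        assert inter.skeleton_edges() == c1.skeleton_edges()

    def test_orientation_majority(self):
        cands = [pdag("ab", directed=[("a", "b")]),
                 pdag("ab", directed=[("a", "b")]),
                 pdag("ab", directed=[("b", "a")])]
        avg = average_model(cands, 1)
        assert avg.has_directed("a", "b")

    def test_orientation_tie_goes_undirected(self):
        cands = [pdag("ab", directed=[("a", "b")]),
                 pdag("ab", directed=[("b", "a")])]
        avg = average_model(cands, 1)
        assert avg.has_undirected("a", "b")

    def test_skeleton_shrinks_as_n_grows(self):
        rng = np.random.default_rng(3)
        cands = [g.random_dag(list("abcde"), 0.5, rng) for _ in range(10)]
        sizes = [len(average_model(cands, n).skeleton_edges())
                 for n in range(1, 11)]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            average_model([pdag("ab")], 2)


class TestAccuracyCoverage:
    def test_worked_example_two_thirds_and_one(self):
        cons = pdag("abc", undirected=[("a", "b"), ("b", "c")])
        cand = pdag("abc", undirected=[("a", "b"), ("b", "c"), ("a", "c")])
        acc, cov = accuracy_coverage([cand], cons)
        assert acc == pytest.approx(2 / 3)
        assert cov == pytest.approx(1.0)

    def test_mean_over_candidates(self):
        cons = pdag("abc", undirected=[("a", "b"), ("b", "c")])
        c1 = pdag("abc", undirected=[("a", "b"), ("b", "c"), ("a", "c")])
        c2 = pdag("abc", undirected=[("a", "b")])
        acc, cov = accuracy_coverage([c1, c2], cons)
        assert acc == pytest.approx((2 / 3 + 1) / 2)
        assert cov == pytest.approx((1 + 1 / 2) / 2)

    def test_candidate_equal_to_consensus_is_perfect(self):
        cons = pdag("abc", directed=[("a", "b")], undirected=[("b", "c")])
        assert accuracy_coverage([cons.copy()], cons) == (1.0, 1.0)

    def test_empty_sets_score_one_by_convention(self):
        empty = pdag("abc")
        some = pdag("abc", undirected=[("a", "b")])
        acc, cov = accuracy_coverage([empty], some)
        assert acc == 1.0 and cov == 0.0
        acc, cov = accuracy_coverage([some], empty)
        assert acc == 0.0 and cov == 1.0

    def test_skeleton_vs_directed_matching(self):
        cons = pdag("abc", directed=[("a", "b")])
        cand = pdag("abc", directed=[("b", "a")])
        assert accuracy_coverage([cand], cons)[0] == 1.0
        assert accuracy_coverage([cand], cons,
                                 directed_match=True)[0] == 0.0


class TestRobustnessAuc:
    def test_constant_coverage_ceiling(self):
        assert robustness_auc([(0, 1), (1, 1)]) == pytest.approx(1.0)

    def test_diagonal(self):
        assert robustness_auc([(0, 0), (1, 1)]) == pytest.approx(0.5)

    def test_degenerate_accuracy_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            robustness_auc([(0.5, 0.2), (0.5, 0.9)])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_fine_grid_riemann_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = [(a, rng.random()) for a in
               np.sort(rng.random(int(rng.integers(3, 9))))]
        if len({round(a, 12) for a, _ in pts}) < 2:
            pytest.skip("degenerate draw")
        assert robustness_auc(pts) == pytest.approx(riemann_auc(pts),
                                                    abs=1e-5)


class TestCommonNetwork:
    def test_identical_models_give_frequency_one(self):
        m = pdag("abc", directed=[("a", "b")], undirected=[("b", "c")])
        net = common_network([m.copy() for _ in range(4)])
        assert net.graph.has_directed("a", "b")
        assert net.direction_freq[("a", "b")] == pytest.approx(1.0)
        assert net.direction_freq[("b", "c")] == pytest.approx(0.5)

    def test_edge_absent_from_one_model_excluded(self):
        m1 = pdag("abc", undirected=[("a", "b"), ("b", "c")])
        m2 = pdag("abc", undirected=[("a", "b")])
        net = common_network([m1, m2])
        assert net.graph.skeleton_edges() == {frozenset("ab")}

    def test_direction_frequency_30_of_50(self):
        fwd = [pdag("ab", directed=[("a", "b")]) for _ in range(30)]
        rev = [pdag("ab", directed=[("b", "a")]) for _ in range(20)]
        net = common_network(fwd + rev)
        assert net.direction_freq[("a", "b")] == pytest.approx(0.6)

    def test_skeleton_subset_of_every_model(self):
        rng = np.random.default_rng(11)
        models = [g.random_dag(list("abcd"), 0.6, rng) for _ in range(6)]
        net = common_network(models)
        for m in models:
            assert net.graph.skeleton_edges() <= m.skeleton_edges()


class TestResolveDirections:
    def net(self, freq):
        graph = pdag("ab", undirected=[("a", "b")])
        return ConsensusNetwork(graph, {("a", "b"): freq})

    def test_majority_direction_kept(self):
        out = resolve_directions(self.net(0.6), ())
        assert out.has_directed("a", "b")
        out = resolve_directions(self.net(0.4), ())
        assert out.has_directed("b", "a")

    def test_exact_tie_stays_undirected(self):
        out = resolve_directions(self.net(0.5), ())
        assert out.has_undirected("a", "b")

    def test_edges_into_protected_node_undirected(self):
        graph = pdag(["x", "Stability"], undirected=[("x", "Stability")])
        net = ConsensusNetwork(graph, {("Stability", "x"): 0.1})
        # frequency favours x -> Stability; protection undirects it
        out = resolve_directions(net, ("Stability",))
        assert out.has_undirected("x", "Stability")
        out = resolve_directions(net, ())
        assert out.has_directed("x", "Stability")


class TestSelectN:
    def test_closest_to_upper_right_corner(self):
        pts = {1: (0.2, 1.0), 5: (0.9, 0.95), 10: (1.0, 0.3)}
        assert select_n(pts) == 5

    def test_tie_prefers_smaller_n(self):
        pts = {3: (0.9, 0.8), 7: (0.8, 0.9)}
        assert select_n(pts) == 3


class TestRunTrials:
    def test_degenerate_single_trial_single_set(self, small_dataset):
        rec, models = run_trials(
            small_dataset, SamplingConfig(strategy="equal", k=500),
            ci_config=g.CITestConfig(seed=0), n_sample_sets=1, n_trials=1,
            n_grid=[1], master_seed=5)
        assert len(models[1]) == 1
        acc = rec.frame.acc_mean.iloc[0]
        cov = rec.frame.cov_mean.iloc[0]
        # average of one candidate is that candidate
        assert acc == 1.0 and cov == 1.0

    def test_fixed_master_seed_reproduces_record(self, small_dataset):
        kwargs = dict(ci_config=g.CITestConfig(seed=0), n_sample_sets=2,
                      n_trials=2, n_grid=[1, 2], master_seed=17)
        cfg = SamplingConfig(strategy="equal", k=400)
        rec1, m1 = run_trials(small_dataset, cfg, **kwargs)
        rec2, m2 = run_trials(small_dataset, cfg, **kwargs)
        assert rec1.frame.equals(rec2.frame)
        assert m1 == m2

    def test_monotonicity_in_n_on_synthetic_run(self, small_dataset):
        rec, models = run_trials(
            small_dataset, SamplingConfig(strategy="equal", k=700),
            ci_config=g.CITestConfig(seed=1), n_sample_sets=4, n_trials=2,
            n_grid=[1, 2, 3, 4], master_seed=2)
        frame = rec.frame.sort_values("N")
        # consensus = same-trial average model at N: its edge set shrinks
        # with N, so accuracy can only fall and coverage only rise
        assert frame.acc_mean.is_monotonic_decreasing
        assert frame.cov_mean.is_monotonic_increasing
        # per-trial average models shrink with N as well
        for t in range(2):
            sizes = [len(models[n][t].skeleton_edges()) for n in (1, 2, 3, 4)]
            assert sizes == sorted(sizes, reverse=True)
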