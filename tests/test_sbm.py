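"""Description-length objective, MCMC sampler, and inference behavior."""

import dataclasses
import math

import numpy as np
import pytest

import gosgraph as gg
from gosgraph.annotations import CATEGORIES
from gosgraph.sbm import MixedSideGroupError, _State, _set_partitions

from conftest import random_small_graph


def _k22() -> gg.OpinionGraph:
    g = gg.OpinionGraph()
    a = g.add_initial_opinion("a")
    b = g.add_initial_opinion("b")
    g.add_respondent_response([a, b], [a, b])
    g.add_respondent_response([a, b], [a, b])
    return g


def _one_group_per_side(graph) -> gg.Partition:
    return gg.Partition(
        {v: 0 for v in graph.opinions} | {v: 1 for v in graph.respondents}
    )


def _singletons(graph) -> gg.Partition:
    ids = list(graph.opinions) + list(graph.respondents)
    return gg.Partition({v: i for i, v in enumerate(ids)})


class TestObjective:
    def test_golden_k22_one_group(self):
        """Hand-derived description length of K22 with one group per side.

        Per side: ln 2 + ln C(1,0) + ln(2!/2!) = ln 2.  One block cell holding
        all four edges: edge-count term ln C(4,4) = 0; graph term
        ln C(2*2, 4) = 0.  Total = 2 ln 2.
        """
        bd = gg.objective(_k22(), _one_group_per_side(_k22()))
        assert bd.total == pytest.approx(2 * math.log(2), abs=1e-12)
        assert bd.dl_graph_given_partition == 0.0
        assert bd.dl_edge_counts == 0.0

    def test_golden_k22_singletons(self):
        """Singleton groups: 4 ln 2 (partitions) + ln C(7,4) (edge counts)."""
        bd = gg.objective(_k22(), _singletons(_k22()))
        assert bd.total == pytest.approx(4 * math.log(2) + math.log(35), abs=1e-12)
        assert bd.dl_graph_given_partition == 0.0

    def test_zero_edges_zero_graph_term(self):
        g = gg.OpinionGraph()
        for i in range(3):
            g.add_initial_opinion(f"o{i}")
        bd = gg.objective(g, gg.Partition({v: 0 for v in g.opinions}))
        assert bd.dl_graph_given_partition == 0.0
        assert bd.dl_edge_counts == 0.0

    def test_relabeling_invariance(self, small_survey):
        graph, truth, _ = small_survey
        part = gg.Partition(
            {v: truth.opinion_group_of[v] for v in graph.opinions}
            | {v: 10 + truth.archetype_of[v] for v in graph.respondents}
        )
        shifted = gg.Partition({v: 7 * g + 3 for v, g in part.group_of.items()})
        assert gg.objective(graph, part).total == pytest.approx(
            gg.objective(graph, shifted).total, abs=1e-9
        )

    def test_mixed_side_group_rejected(self, toy_graph):
        bad = gg.Partition({v: 0 for v in list(toy_graph.opinions) + list(toy_graph.respondents)})
        with pytest.raises(MixedSideGroupError):
            gg.objective(toy_graph, bad)

    @staticmethod
    def _block_graph(n_resp_per_block):
        """2x2 planted blocks: 4 opinions, each respondent supports its block."""
        g = gg.OpinionGraph()
        ops = [g.add_initial_opinion(f"o{i}") for i in range(4)]
        rids = [
            g.add_respondent_response(ops, ops[2 * b : 2 * b + 2])
            for b in range(2)
            for _ in range(n_resp_per_block)
        ]
        planted = gg.Partition(
            {o: i // 2 for i, o in enumerate(ops)}
            | {r: 2 + i // n_resp_per_block for i, r in enumerate(rids)}
        )
        return g, planted

    def test_planted_blocks_beat_single_group_above_threshold(self):
        """With 3+ respondents per block the planted 2x2 partition scores
        below one-group-per-side; at 2 per block the evidence is too thin and
        the parsimonious single grouping wins (confirmed by enumeration)."""
        for r, planted_wins in ((2, False), (3, True), (4, True)):
            g, planted = self._block_graph(r)
            tp = gg.objective(g, planted).total
            ts = gg.objective(g, _one_group_per_side(g)).total
            assert (tp < ts) == planted_wins, f"{r} respondents per block"
        g, planted = self._block_graph(2)
        part, bd = gg.exhaustive_map(g)
        assert part.B == 2  # global optimum is the parsimonious grouping

    def test_breakdown_consistency_and_nonnegativity(self, small_survey):
        graph, truth, _ = small_survey
        part = gg.Partition(
            {v: truth.opinion_group_of[v] for v in graph.opinions}
            | {v: 5 + truth.archetype_of[v] for v in graph.respondents}
        )
        bd = gg.objective(graph, part)
        assert bd.dl_partition >= 0
        assert bd.dl_edge_counts >= 0
        assert bd.dl_graph_given_partition >= 0
        assert bd.total == pytest.approx(
            bd.dl_partition + bd.dl_edge_counts + bd.dl_graph_given_partition
            - bd.log_prior_annotations,
            abs=1e-9,
        )


class TestIncrementalConsistency:
    def _random_state(self, priors=None):
        rng = np.random.default_rng(2)
        cfg = gg.SimulationConfig(
            n_respondents=40, n_initial_opinions=12, n_opinion_groups=2,
            affinity=((0.9, 0.1), (0.1, 0.9)), archetype_weights=(0.5, 0.5),
            support_intensity=6.0, seed=14,
        )
        graph, truth = gg.simulate_survey(cfg)
        if priors:
            ann = gg.simulate_annotators(truth, cfg, rng)
            space = gg.build_label_space(ann)
            pv = gg.build_prior_vectors(ann, space, opinion_ids=graph.opinions)
        else:
            pv = None
        state = _State(graph, pv)
        state.set_partition([int(rng.integers(3)) for _ in range(state.N)])
        return state, rng

    @pytest.mark.parametrize("with_priors", [False, True])
    def test_delta_move_matches_recompute(self, with_priors):
        state, rng = self._random_state(with_priors)
        for _ in range(60):
            v = int(rng.integers(state.N))
            lst = state.side_groups[state.side(v)]
            s = None if rng.random() < 0.2 else lst[int(rng.integers(len(lst)))]
            if s == state.b[v] or (s is None and state.n[state.b[v]] == 1):
                continue
            before = state.compute_total()
            d = state.delta_move(v, s)
            state.apply_move(v, s)
            assert state.compute_total() - before == pytest.approx(d, abs=1e-8)

    @pytest.mark.parametrize("with_priors", [False, True])
    def test_delta_merge_matches_recompute(self, with_priors):
        state, rng = self._random_state(with_priors)
        state.refresh_labels()
        for side in (0, 1):
            lst = state.side_groups[side]
            if len(lst) >= 2:
                before = state.compute_total()
                d = state.delta_merge(lst[0], lst[1])
                state.apply_merge(lst[0], lst[1])
                state.refresh_labels()
                assert state.compute_total() - before == pytest.approx(d, abs=1e-8)

    def test_long_chain_total_drift_free(self):
        state, rng = self._random_state(priors=True)
        state.total = state.compute_total()
        for _ in range(2000):
            state.step(rng, beta=1.0)
        assert state.total == pytest.approx(state.compute_total(), abs=1e-7)


class TestMCMC:
    def test_stationary_distribution_matches_boltzmann(self):
        """Empirical chain frequencies on K22 match exp(-total)/Z."""
        g = _k22()
        st = _State(g)
        states: dict[tuple, float] = {}

        def key_of(b):
            return tuple(
                tuple(sorted(vs))
                for vs in sorted(
                    [sorted(i for i in range(4) if b[i] == x) for x in set(b)]
                )
            )

        for po in _set_partitions([0, 1]):
            for pr in _set_partitions([2, 3]):
                groups = [0] * 4
                gi = 0
                for blk in po + pr:
                    for v in blk:
                        groups[v] = gi
                    gi += 1
                st.set_partition(groups)
                states[key_of(st.b)] = st.total
        Z = sum(math.exp(-t) for t in states.values())
        exact = {k: math.exp(-t) / Z for k, t in states.items()}

        sampler = gg.MCMCSampler(g, _singletons(g))
        rng = np.random.default_rng(0)
        counts = {k: 0 for k in states}
        n_steps = 60_000
        for _ in range(n_steps):
            sampler.step(rng, beta=1.0)
            counts[key_of(sampler.state.b)] += 1
        for k in states:
            assert counts[k] / n_steps == pytest.approx(exact[k], abs=0.02)

    def test_zero_temperature_never_worsens(self):
        rng = np.random.default_rng(3)
        g = random_small_graph(rng)
        part, bd = gg.exhaustive_map(g)
        sampler = gg.MCMCSampler(g, part)
        for _ in range(500):
            sampler.step(rng, beta=1e8)
        assert sampler.total <= bd.total + 1e-9

    def test_mcmc_step_wrapper_runs(self, toy_graph):
        rng = np.random.default_rng(0)
        part = _singletons(toy_graph)
        new, accepted = gg.mcmc_step(toy_graph, part, None, rng, beta=1.0)
        assert accepted in (True, False)
        assert set(new.group_of) == set(part.group_of)


class TestInfer:
    def test_uniform_priors_equal_no_priors(self):
        rng = np.random.default_rng(5)
        g = random_small_graph(rng)
        space = gg.LabelSpace((("a1", CATEGORIES[0]), ("a1", CATEGORIES[1])))
        from gosgraph.annotations import PriorVectors

        pv = PriorVectors(space)
        for oid in g.opinions:
            pv[oid] = np.full(2, 0.5)
        p0, b0 = gg.infer(g, seed=4)
        p1, b1 = gg.infer(g, priors=pv, seed=4)
        assert b0.total == pytest.approx(b1.total, abs=1e-9)

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(8)
        g = random_small_graph(rng)
        _, b1 = gg.infer(g, n_sweeps=5, n_restarts=1, seed=2)
        _, b5 = gg.infer(g, n_sweeps=5, n_restarts=5, seed=2)
        assert b5.total <= b1.total + 1e-12

    def test_vertex_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        g1 = random_small_graph(rng)
        g2 = gg.OpinionGraph()
        renamed = {}
        for oid in g1.opinions:
            renamed[oid] = g2.add_initial_opinion(g1.opinions[oid].text)
        all_ops = list(renamed.values())
        for rid in g1.respondents:
            sup = [renamed[o] for o in g1.opinions_of(rid)]
            g2.add_respondent_response(all_ops, sup)
        _, b1 = gg.infer(g1, seed=6)
        _, b2 = gg.infer(g2, seed=6)
        assert b1.total == pytest.approx(b2.total, abs=1e-9)

    def test_determinism(self):
        rng = np.random.default_rng(10)
        g = random_small_graph(rng)
        p1, b1 = gg.infer(g, seed=3)
        p2, b2 = gg.infer(g, seed=3)
        assert p1.group_of == p2.group_of
        assert b1.total == b2.total

    def test_empty_graph_and_bad_budget_rejected(self):
        with pytest.raises(ValueError):
            gg.infer(gg.OpinionGraph())
        with pytest.raises(ValueError):
            gg.infer(_k22(), n_sweeps=0)

    def test_degree_corrected_variant_runs_and_is_invariant(self):
        rng = np.random.default_rng(11)
        g = random_small_graph(rng)
        part, bd = gg.infer(g, seed=1, degree_corrected=True)
        shifted = gg.Partition({v: g_ + 5 for v, g_ in part.group_of.items()})
        assert gg.objective(g, shifted, degree_corrected=True).total == pytest.approx(
            bd.total, abs=1e-9
        )

    def test_ari_degrades_with_contrast(self):
        """Recovery weakens monotonically as affinity contrast shrinks."""
        from sklearn.metrics import adjusted_rand_score

        mean_ari = []
        for contrast in (0.95, 0.80, 0.65):
            aris = []
            for seed in range(3):
                cfg = gg.SimulationConfig(
                    n_respondents=600, n_initial_opinions=100, n_opinion_groups=2,
                    affinity=((contrast, 1 - contrast), (1 - contrast, contrast)),
                    archetype_weights=(0.5, 0.5), support_intensity=8.0,
                    seed=50 + seed,
                )
                graph, truth = gg.simulate_survey(cfg)
                part, _ = gg.infer(graph, n_sweeps=10, n_restarts=2, seed=seed)
                resp = list(graph.respondents)
                aris.append(adjusted_rand_score(
                    [truth.archetype_of[r] for r in resp],
                    [part.group_of[r] for r in resp],
                ))
            mean_ari.append(np.mean(aris))
        assert mean_ari[0] > mean_ari[1] > mean_ari[2] - 0.05
        assert mean_ari[0] >= 0.9

    def test_perfect_annotations_refine_to_true_categories(self):
        """With error-free annotators, opinion groups reach at least the
        number of distinct true categories present."""
        cfg = dataclasses.replace(
            gg.preset_scenarios("ten_category_full"),
            n_respondents=400, n_initial_opinions=60,
            annotator_error=0.0, seed=23,
        )
        graph, truth = gg.simulate_survey(cfg)
        ann = gg.simulate_annotators(truth, cfg, np.random.default_rng(1))
        space = gg.build_label_space(ann)
        priors = gg.build_prior_vectors(ann, space, opinion_ids=graph.opinions)
        part, _ = gg.infer(graph, priors=priors, n_sweeps=10, n_restarts=2, seed=2)
        n_cats = len(set(truth.true_category_of.values()))
        n_opinion_groups = len({part.group_of[o] for o in graph.opinions})
        assert n_opinion_groups >= n_cats


class TestExhaustive:
    def test_refuses_large_graphs(self, small_survey):
        graph, _, _ = small_survey
        with pytest.raises(ValueError):
            gg.exhaustive_map(graph)

    def test_k22_minimum_over_enumeration(self):
        g = _k22()
        part, bd = gg.exhaustive_map(g)
        # enumerate the four side-respecting partitions by hand
        ids = list(g.opinions) + list(g.respondents)
        totals = []
        for o_split in (False, True):
            for r_split in (False, True):
                gof = {ids[0]: 0, ids[1]: 1 if o_split else 0}
                gof[ids[2]] = 10
                gof[ids[3]] = 11 if r_split else 10
                totals.append(gg.objective(g, gg.Partition(gof)).total)
        assert bd.total == pytest.approx(min(totals), abs=1e-12)
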