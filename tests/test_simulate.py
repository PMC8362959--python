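"""Simulator: determinism, display law, posting rate, planted structure."""

import dataclasses

import numpy as np
import pytest

import gosgraph as gg
from gosgraph.simulate import ConfigError


def _mini_config(**over):
    base = dict(
        n_respondents=100,
        n_initial_opinions=20,
        n_opinion_groups=2,
        affinity=((0.95, 0.05), (0.05, 0.95)),
        archetype_weights=(0.5, 0.5),
        support_intensity=8.0,
        seed=3,
    )
    base.update(over)
    return gg.SimulationConfig(**base)


class TestConfigValidation:
    def test_unnormalized_affinity_rejected(self):
        with pytest.raises(ConfigError):
            _mini_config(affinity=((0.9, 0.2), (0.05, 0.95)))

    def test_display_size_outside_bounds_rejected(self):
        with pytest.raises(ConfigError):
            _mini_config(display_size_law=((4, 1.0),))

    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigError):
            _mini_config(p_post=1.5)


class TestSampleDisplay:
    def test_small_pool_returned_whole(self):
        rng = np.random.default_rng(0)
        assert set(gg.sample_display(list("abcde"), ((8, 1.0),), rng)) == set("abcde")

    def test_point_mass_24(self):
        rng = np.random.default_rng(0)
        pool = [f"o{i}" for i in range(30)]
        out = gg.sample_display(pool, ((24, 1.0),), rng)
        assert len(out) == len(set(out)) == 24

    def test_uniformity(self):
        """Each of 100 opinions appears with frequency 8/100 over many draws."""
        rng = np.random.default_rng(12)
        pool = [f"o{i}" for i in range(100)]
        counts = {o: 0 for o in pool}
        n_draws = 10_000
        for _ in range(n_draws):
            for o in gg.sample_display(pool, ((8, 1.0),), rng):
                counts[o] += 1
        freqs = np.array([counts[o] / n_draws for o in pool])
        se = np.sqrt(0.08 * 0.92 / n_draws)
        assert np.mean(np.abs(freqs - 0.08) < 3 * se) > 0.95
        assert np.all(np.abs(freqs - 0.08) < 5 * se)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            gg.sample_display([], ((8, 1.0),), np.random.default_rng(0))


class TestSimulateSurvey:
    def test_determinism(self):
        cfg = _mini_config()
        g1, t1 = gg.simulate_survey(cfg)
        g2, t2 = gg.simulate_survey(cfg)
        assert g1.edges == g2.edges
        assert list(g1.opinions) == list(g2.opinions)
        assert t1.opinion_group_of == t2.opinion_group_of
        a1 = gg.simulate_annotators(t1, cfg, np.random.default_rng(5))
        a2 = gg.simulate_annotators(t2, cfg, np.random.default_rng(5))
        assert a1.records == a2.records

    def test_forced_posting(self):
        cfg = _mini_config(p_post=1.0, support_intensity=0.0)
        graph, truth = gg.simulate_survey(cfg)
        assert graph.n_edges == graph.n_respondents == cfg.n_respondents
        for rid in graph.respondents:
            assert len(graph.authored_by(rid)) == 1

    def test_posting_rate_converges(self):
        cfg = _mini_config(n_respondents=2000, p_post=0.08, seed=21)
        graph, truth = gg.simulate_survey(cfg)
        authors = sum(1 for rid in graph.respondents if graph.authored_by(rid))
        frac = authors / graph.n_respondents
        se = np.sqrt(0.08 * 0.92 / graph.n_respondents)
        assert abs(frac - 0.08) < 3 * se

    def test_display_sizes_within_bounds(self, small_survey):
        graph, _, cfg = small_survey
        pool_limit = graph.n_opinions
        for r in graph.respondents.values():
            assert r.displayed is not None
            assert 1 <= len(r.displayed) <= 24
            assert len(r.displayed) <= pool_limit

    def test_graph_invariants_hold(self, small_survey):
        graph, truth, _ = small_survey
        graph.validate()
        assert set(truth.archetype_of) == set(graph.respondents)
        assert set(truth.opinion_group_of) == set(graph.opinions)

    def test_rejection_logged_when_turns_cannot_fill(self):
        cfg = _mini_config(
            n_respondents=60, support_intensity=0.0, p_post=0.05, seed=9
        )
        graph, truth = gg.simulate_survey(cfg)
        assert graph.n_respondents + len(truth.rejected) == 60
        assert len(truth.rejected) > 0

    def test_planted_structure_beats_rewired_null(self):
        """Planted bipartition has higher modularity than degree-preserving rewires."""
        import networkx as nx
        from gosgraph.opinion_graph import to_networkx

        cfg = _mini_config(n_respondents=300, n_initial_opinions=40, seed=17)
        graph, truth = gg.simulate_survey(cfg)
        G = to_networkx(graph)
        comms = [
            {v for v in graph.opinions if truth.opinion_group_of[v] == k}
            | {v for v in graph.respondents if truth.archetype_of[v] == k}
            for k in range(2)
        ]
        q_planted = nx.community.modularity(G, comms)
        rng = np.random.default_rng(5)
        edges = sorted(graph.edges)
        beaten = 0
        for _ in range(99):
            ed = edges[:]
            ed_set = set(ed)
            for _ in range(2 * len(ed)):  # bipartite-preserving double swaps
                i, j = rng.integers(len(ed)), rng.integers(len(ed))
                (r1, o1), (r2, o2) = ed[i], ed[j]
                if r1 != r2 and o1 != o2 and (r1, o2) not in ed_set and (r2, o1) not in ed_set:
                    ed_set.difference_update((ed[i], ed[j]))
                    ed[i], ed[j] = (r1, o2), (r2, o1)
                    ed_set.update((ed[i], ed[j]))
            H = nx.Graph()
            H.add_nodes_from(G.nodes)
            H.add_edges_from(ed)
            if nx.community.modularity(H, comms) < q_planted:
                beaten += 1
        assert beaten >= 95


class TestAnnotatorSimulation:
    def test_perfect_annotators_match_truth(self, small_survey):
        graph, truth, cfg = small_survey
        perfect = dataclasses.replace(cfg, annotator_error=0.0, unannotated_frac=0.0)
        ann = gg.simulate_annotators(truth, perfect, np.random.default_rng(0))
        assert len(ann) == 3 * graph.n_opinions
        for (oid, _), cat in ann.records.items():
            assert cat == truth.true_category_of[oid]

    def test_all_skipped_gives_empty_set(self, small_survey):
        _, truth, cfg = small_survey
        skip = dataclasses.replace(cfg, unannotated_frac=1.0)
        ann = gg.simulate_annotators(truth, skip, np.random.default_rng(0))
        assert len(ann) == 0

    def test_pairwise_agreement_closed_form(self):
        """Independent 10%-error annotators agree at (0.9)^2 + (0.1)^2/9."""
        cfg = _mini_config(
            n_respondents=1200, p_post=0.9, annotator_error=0.1, unannotated_frac=0.0,
            seed=31,
        )
        graph, truth = gg.simulate_survey(cfg)
        ann = gg.simulate_annotators(truth, cfg, np.random.default_rng(8))
        rep = gg.pairwise_agreement(ann)
        expected = 0.9**2 + 0.1**2 / 9
        for row in rep.itertuples():
            se = np.sqrt(expected * (1 - expected) / row.n_shared)
            assert abs(row.agreement - expected) < 3 * se


class TestPresets:
    def test_two_block_definition(self):
        cfg = gg.preset_scenarios("two_block_no_concerns")
        aff = cfg.affinity_array
        assert aff.shape[0] == 2
        assert cfg.no_concerns_group is not None
        assert aff[1, cfg.no_concerns_group] >= 0.9
        assert cfg.archetype_weights[1] < cfg.archetype_weights[0]

    def test_diffuse_definition(self):
        cfg = gg.preset_scenarios("diffuse")
        aff = cfg.affinity_array
        assert aff.shape[0] == 1
        assert aff.max() - aff.min() < 0.05

    def test_ten_category_definition(self):
        cfg = gg.preset_scenarios("ten_category_full")
        assert cfg.n_opinion_groups == 10
        assert cfg.group_categories == gg.CATEGORIES

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            gg.preset_scenarios("nope")
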