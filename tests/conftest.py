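"""Shared fixtures: small deterministic surveys and annotation sets."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import gosgraph as gg

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_two_block_config() -> gg.SimulationConfig:
    """A scaled-down detectable two-block survey (fast enough for unit tests)."""
    return dataclasses.replace(
        gg.preset_scenarios("two_block_no_concerns"),
        n_respondents=150,
        n_initial_opinions=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_survey(small_two_block_config):
    graph, truth = gg.simulate_survey(small_two_block_config)
    return graph, truth, small_two_block_config


@pytest.fixture(scope="session")
def small_annotations(small_survey):
    graph, truth, cfg = small_survey
    rng = np.random.default_rng(99)
    return gg.simulate_annotators(truth, cfg, rng)


@pytest.fixture()
def toy_graph() -> gg.OpinionGraph:
    """Two initial opinions; one respondent supports both; one supports one
    and posts a new opinion.  Final counts: 3 opinions, 2 respondents, 4 edges."""
    g = gg.OpinionGraph()
    a = g.add_initial_opinion("worried about infection")
    b = g.add_initial_opinion("income dropped")
    g.add_respondent_response(displayed=[a, b], supported=[a, b])
    g.add_respondent_response(displayed=[a, b], supported=[a], new_texts=["cannot travel"])
    return g


def random_small_graph(rng: np.random.Generator) -> gg.OpinionGraph:
    """Random bipartite survey graph with at most 8 vertices."""
    n_o = int(rng.integers(2, 5))
    n_r = int(rng.integers(2, 5))
    g = gg.OpinionGraph()
    ops = [g.add_initial_opinion(f"o{i}") for i in range(n_o)]
    for _ in range(n_r):
        while True:
            sup = [o for o in ops if rng.random() < 0.5]
            if sup:
                break
        g.add_respondent_response(ops, sup)
    return g


def null_bipartite_graph(seed: int, n_each: int = 200, mean_degree: float = 5.0) -> gg.OpinionGraph:
    """Unstructured random bipartite graph (no planted groups)."""
    rng = np.random.default_rng(seed)
    g = gg.OpinionGraph()
    ops = [g.add_initial_opinion(f"op{i}") for i in range(n_each)]
    for _ in range(n_each):
        k = int(np.clip(rng.poisson(mean_degree), 1, 24))
        shown_idx = rng.choice(n_each, size=max(8, k), replace=False)
        shown = [ops[i] for i in shown_idx]
        g.add_respondent_response(shown, shown[:k])
    return g
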