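"""Shared fixtures: tiny profiles, graphs and score tables built in memory."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gta.io import ExpressionProfile
from gta.scoring import GeneScoreTable


def make_profile(values: dict[str, list[float]], n_case: int) -> ExpressionProfile:
    """Profile from gene → value-list, first ``n_case`` samples labeled case."""
    m = len(next(iter(values.values())))
    samples = [f"s{i}" for i in range(m)]
    return ExpressionProfile(
        values=pd.DataFrame.from_dict(values, orient="index",
                                      columns=samples, dtype=float),
        labels=pd.Series([1] * n_case + [2] * (m - n_case), index=samples),
    )


def make_scores(tscores: dict[str, float], m: int = 6) -> GeneScoreTable:
    """Score table with given t-scores and placeholder LLR vectors."""
    genes = list(tscores)
    return GeneScoreTable(
        llr=pd.DataFrame(np.zeros((len(genes), m)), index=genes,
                         columns=[f"s{i}" for i in range(m)]),
        tscore=pd.Series(tscores, dtype=float),
    )


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_weighted_edges_from([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)])
    return g


@pytest.fixture
def profile_2x6() -> ExpressionProfile:
    """Two genes × six samples, 3 case / 3 control, exact textbook moments:

    gene gA fits Normal(2,1) in class 1 and Normal(0,1) in class 2.
    """
    return make_profile(
        {"gA": [1, 2, 3, -1, 0, 1], "gB": [0, 0, 0, 5, 5, 5]}, n_case=3
    )


def random_subgame_inputs(rng: np.random.Generator, n_free: int):
    """A random sub-game graph + t-scores for solver/oracle comparisons.

    Returns (SubGame, GeneScoreTable). The seed S and anchor A are always
    connected; remaining players attach to the anchor (two-step shape)
    and to each other at random.
    """
    from gta.game import SubGame

    players = ["S", "A"] + [f"P{i}" for i in range(n_free - 1)]
    g = nx.Graph()
    g.add_nodes_from(players)
    g.add_edge("S", "A", weight=float(rng.uniform(0.2, 2.0)))
    for p in players[2:]:
        g.add_edge("A", p, weight=float(rng.uniform(0.2, 2.0)))
        for q in players[2:]:
            if q < p and rng.random() < 0.4:
                g.add_edge(p, q, weight=float(rng.uniform(0.2, 2.0)))
    scores = make_scores({p: float(rng.normal(0, 3)) for p in players})
    subgame = SubGame(seed="S", anchor="A",
                      members=tuple(sorted(players)), graph=g)
    return subgame, scores
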