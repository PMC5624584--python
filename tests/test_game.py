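"""Game solver tests against an independent brute-force oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest

from gta.candidates import extract_candidate
from gta.errors import GTAError
from gta.game import (
    SubGame,
    decompose,
    enumerate_states,
    is_equilibrium,
    merge_subgames,
    solve_subgame,
)
from gta.scoring import PayoffParams

from conftest import make_scores, random_subgame_inputs


# ---------------------------------------------------------------- oracle ---

def oracle_payoff(gene, state, graph, tmap, params):
    """Payoff recomputed from first principles, independent of gta.scoring."""
    joined = sorted(g for g, s in state.items() if s == 1)
    k = len(joined)
    de = 0.0
    if k >= 2:
        w = sum(graph[a][b].get("weight", 1.0)
                for i, a in enumerate(joined) for b in joined[i + 1:]
                if graph.has_edge(a, b))
        de = w / (k * (k - 1) / 2)
    ls = 0.0
    if state[gene] == 1:
        ls = sum(tmap[n] for n in graph.neighbors(gene) if state[n] == 1)
    gf = params.alpha * tmap[gene] + params.beta * ls + params.gamma * de
    return gf - params.delta * (k - 1)


def oracle_equilibria(subgame, tmap, params):
    """All pure-strategy equilibria by exhaustive deviation checking."""
    free = sorted(set(subgame.members) - {subgame.seed})
    found = []
    for combo in itertools.product((0, 1), repeat=len(free)):
        state = {subgame.seed: 1, **dict(zip(free, combo))}
        stable = all(
            oracle_payoff(p, {**state, p: 1 - state[p]},
                          subgame.graph, tmap, params)
            <= oracle_payoff(p, state, subgame.graph, tmap, params)
            for p in free
        )
        if stable:
            found.append(state)
    return found


def mean_abs_t(state, tmap):
    joined = [g for g, s in state.items() if s == 1]
    return sum(abs(tmap[g]) for g in joined) / len(joined)


# ----------------------------------------------------------------- tests ---

def fig_shaped_candidate():
    """A seed with 4 one-step and 3 two-step nodes per anchor (12 total)."""
    g = nx.Graph()
    for i in range(4):
        g.add_edge("S", f"A{i}", weight=1.0)
        for j in range(3):
            g.add_edge(f"A{i}", f"T{i}{j}", weight=1.0)
    return extract_candidate(g, "S")


class TestDecompose:
    def test_one_subgame_per_anchor(self):
        subgames = decompose(fig_shaped_candidate())
        assert len(subgames) == 4
        assert all(len(sg.members) == 5 for sg in subgames)

    def test_anchor_without_two_step(self):
        g = nx.Graph()
        g.add_edge("S", "A", weight=1.0)
        subgames = decompose(extract_candidate(g, "S"))
        assert len(subgames) == 1
        assert subgames[0].members == ("A", "S")
        assert subgames[0].free_players == ("A",)

    def test_shared_two_step_duplicated(self):
        g = nx.Graph()
        for e in [("S", "A1"), ("S", "A2"), ("A1", "X"), ("A2", "X")]:
            g.add_edge(*e, weight=1.0)
        subgames = decompose(extract_candidate(g, "S"))
        assert all("X" in sg.members for sg in subgames)

    def test_player_cap_enforced(self):
        g = nx.Graph()
        g.add_edge("S", "A", weight=1.0)
        for i in range(25):
            g.add_edge("A", f"T{i}", weight=1.0)
        with pytest.raises(GTAError, match="free players"):
            decompose(extract_candidate(g, "S"))


class TestEnumerateStates:
    def test_four_free_players_sixteen_states(self):
        subgames = decompose(fig_shaped_candidate())
        states = list(enumerate_states(subgames[0]))
        assert len(states) == 16
        assert all(s["S"] == 1 for s in states)
        assert len({tuple(sorted(s.items())) for s in states}) == 16

    def test_zero_free_players_single_state(self):
        sg = SubGame(seed="S", anchor="S", members=("S",), graph=nx.Graph())
        assert list(enumerate_states(sg)) == [{"S": 1}]

    def test_deterministic_counter_order(self):
        g = nx.Graph()
        g.add_edge("S", "A", weight=1.0)
        g.add_edge("S", "B", weight=1.0)
        sg = SubGame(seed="S", anchor="A", members=("A", "B", "S"), graph=g)
        states = list(enumerate_states(sg))
        assert [(s["A"], s["B"]) for s in states] == \
            [(0, 0), (0, 1), (1, 0), (1, 1)]


class TestIsEquilibrium:
    def test_single_player_wants_to_join(self):
        g = nx.Graph()
        g.add_edge("S", "A", weight=1.0)
        sg = SubGame(seed="S", anchor="A", members=("A", "S"), graph=g)
        scores = make_scores({"S": 5.0, "A": 5.0})
        params = PayoffParams()  # joining gains β·t(S)+γ·DE − δ = 5+1−2 > 0
        assert is_equilibrium({"S": 1, "A": 1}, sg, scores, params)
        assert not is_equilibrium({"S": 1, "A": 0}, sg, scores, params)

    def test_zero_params_every_state_stable(self):
        sg, scores = random_subgame_inputs(np.random.default_rng(3), 4)
        params = PayoffParams(alpha=0, beta=0, gamma=0, delta=0)
        for state in enumerate_states(sg):
            assert is_equilibrium(state, sg, scores, params)

    def test_huge_delta_forces_seed_only(self):
        sg, scores = random_subgame_inputs(np.random.default_rng(4), 5)
        params = PayoffParams(delta=1e6)
        seed_only = {p: 0 for p in sg.free_players}
        seed_only[sg.seed] = 1
        assert is_equilibrium(seed_only, sg, scores, params)
        sol = solve_subgame(sg, scores, params)
        assert [g for g, s in sol.state.items() if s == 1] == [sg.seed]


class TestSolveSubgame:
    @pytest.mark.parametrize("rng_seed", range(30))
    def test_matches_bruteforce_oracle(self, rng_seed):
        rng = np.random.default_rng(rng_seed)
        n_free = int(rng.integers(1, 8))
        sg, scores = random_subgame_inputs(rng, n_free)
        tmap = {p: scores.t(p) for p in sg.members}
        params = PayoffParams()
        sol = solve_subgame(sg, scores, params)
        oracle = oracle_equilibria(sg, tmap, params)
        if oracle:
            assert sol.is_equilibrium
            assert sol.state in oracle
            best = max(mean_abs_t(s, tmap) for s in oracle)
            assert mean_abs_t(sol.state, tmap) == pytest.approx(best)
        else:
            assert not sol.is_equilibrium

    def test_mean_abs_t_tiebreak(self):
        # two isolated free players with opposite-signed t: with α=β=γ=0
        # and δ=0 every state is an equilibrium; the highest mean |t|
        # joined set must be selected
        g = nx.Graph()
        g.add_nodes_from(["S", "A", "B"])
        g.add_edge("S", "A", weight=1.0)
        g.add_edge("S", "B", weight=1.0)
        sg = SubGame(seed="S", anchor="A", members=("A", "B", "S"), graph=g)
        scores = make_scores({"S": 1.0, "A": 9.0, "B": 0.5})
        params = PayoffParams(alpha=0, beta=0, gamma=0, delta=0)
        sol = solve_subgame(sg, scores, params)
        assert sol.state == {"S": 1, "A": 1, "B": 0}
        assert sol.n_equilibria == 4


class TestMergeSubgames:
    def test_all_seed_only_marker_is_seed(self):
        candidate = fig_shaped_candidate()
        scores = make_scores({v: 1.0 for v in candidate.members} | {"S": 4.0})
        solved = []
        for sg in decompose(candidate):
            state = {p: 0 for p in sg.free_players}
            state["S"] = 1
            solved.append(state)
        marker = merge_subgames(candidate, solved, scores)
        assert marker.joined == frozenset({"S"})
        assert marker.score == pytest.approx(4.0)

    def test_union_rule_join_wins(self):
        g = nx.Graph()
        for e in [("S", "A1"), ("S", "A2"), ("A1", "X"), ("A2", "X")]:
            g.add_edge(*e, weight=1.0)
        candidate = extract_candidate(g, "S")
        scores = make_scores({"S": 2.0, "A1": 2.0, "A2": 2.0, "X": 1.0})
        solved = [
            {"S": 1, "A1": 1, "X": 1},  # X joins here
            {"S": 1, "A2": 1, "X": 0},  # and leaves here
        ]
        marker = merge_subgames(candidate, solved, scores)
        assert "X" in marker.joined
        assert marker.joined == frozenset({"S", "A1", "A2", "X"})

    def test_roles_and_degrees_recorded(self):
        candidate = fig_shaped_candidate()
        scores = make_scores({v: 1.0 for v in candidate.members})
        solved = [sol.state for sol in
                  (solve_subgame(sg, scores, PayoffParams())
                   for sg in decompose(candidate))]
        marker = merge_subgames(candidate, solved, scores)
        assert marker.per_gene["S"].role == "seed"
        for gene in marker.joined:
            assert marker.per_gene[gene].degree == marker.graph.degree(gene)

    def test_merge_agrees_with_global_bruteforce_on_small_game(self):
        """On a small dense candidate the merged marker should match a
        global exhaustive equilibrium search (the decomposition is exact
        when every two-step node has a single anchor and sub-games do not
        interact through shared non-seed players)."""
        g = nx.Graph()
        for e in [("S", "A0"), ("S", "A1"), ("A0", "T0"), ("A1", "T1")]:
            g.add_edge(*e, weight=1.0)
        candidate = extract_candidate(g, "S")
        scores = make_scores(
            {"S": 3.0, "A0": 4.0, "A1": 2.5, "T0": 3.5, "T1": 0.1})
        params = PayoffParams()
        solved = [solve_subgame(sg, scores, params)
                  for sg in decompose(candidate)]
        marker = merge_subgames(candidate, solved, scores, params)

        whole = SubGame(seed="S", anchor="A0",
                        members=tuple(sorted(candidate.members)),
                        graph=candidate.graph)
        tmap = {p: scores.t(p) for p in whole.members}
        oracle = oracle_equilibria(whole, tmap, params)
        best = max(oracle, key=lambda s: mean_abs_t(s, tmap))
        assert marker.joined == frozenset(
            g for g, s in best.items() if s == 1)
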