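"""Sub-game decomposition, strategy enumeration and Nash-equilibrium search.

Solving a candidate subnetwork with |V_s| players exactly would require
evaluating 2^|V_s| strategy states. The game is therefore split into one
sub-game per retained one-step neighbour (the *anchor*): each sub-game
contains the seed, the anchor, and the two-step nodes assigned to that
anchor, so its state space is 2^(free players) with the seed pinned to
join. Every sub-game is solved exactly by enumeration; among its
pure-strategy equilibria the one with the highest mean |t-score| over
joined genes wins (ties: larger joined set, then lexicographic). The
per-sub-game solutions are merged by union into one subnetwork marker —
a good heuristic for, though not necessarily equal to, a global
equilibrium of the undecomposed game.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np

from gta.errors import GTAError
from gta.candidates import CandidateSubnetwork
from gta.scoring import GeneScoreTable, PayoffParams, payoff

logger = logging.getLogger(__name__)

DEFAULT_MAX_SUBGAME_PLAYERS = 21

StrategyState = dict  # gene -> 0 (leave) | 1 (join); seed always 1


@dataclass
class SubGame:
    """A reduced game: seed + one anchor + that anchor's two-step nodes."""

    seed: str
    anchor: str
    members: tuple[str, ...]
    graph: nx.Graph

    @property
    def free_players(self) -> tuple[str, ...]:
        return tuple(v for v in sorted(self.members) if v != self.seed)


class GeneInfo(NamedTuple):
    role: str
    tscore: float
    degree: int
    payoff: float


@dataclass
class SubnetworkMarker:
    """A merged equilibrium: the joined gene set with diagnostics.

    ``score`` is the mean |t-score| over joined genes — the quantity by
    which markers are ranked and equilibrium ties are broken.
    """

    seed: str
    joined: frozenset
    graph: nx.Graph
    score: float
    per_gene: dict[str, GeneInfo]


class SubgameSolution(NamedTuple):
    state: StrategyState
    is_equilibrium: bool
    n_equilibria: int


def decompose(candidate: CandidateSubnetwork,
              max_subgame_players: int = DEFAULT_MAX_SUBGAME_PLAYERS
              ) -> list[SubGame]:
    """One sub-game per retained one-step neighbour.

    A two-step node joins the sub-game of every anchor it is adjacent to
    (after capping, of every anchor that kept it), so it may appear in
    several sub-games. Raises when a sub-game would exceed
    ``max_subgame_players`` free players.
    """
    subgames = []
    for anchor in sorted(candidate.one_step):
        if candidate.anchor_map is not None:
            two = list(candidate.anchor_map.get(anchor, ()))
        else:
            two = [v for v in candidate.two_step
                   if candidate.graph.has_edge(anchor, v)]
        members = tuple(sorted({candidate.seed, anchor, *two}))
        n_free = len(members) - 1
        if n_free > max_subgame_players:
            raise GTAError(
                f"sub-game of anchor {anchor!r} has {n_free} free players "
                f"(cap {max_subgame_players}); lower the neighbour caps"
            )
        subgames.append(SubGame(
            seed=candidate.seed,
            anchor=anchor,
            members=members,
            graph=candidate.graph.subgraph(members).copy(),
        ))
    return subgames


def enumerate_states(subgame: SubGame,
                     max_subgame_players: int = DEFAULT_MAX_SUBGAME_PLAYERS
                     ) -> Iterator[StrategyState]:
    """All 2^(free players) states, seed fixed to join.

    Deterministic order: a binary counter over the lexicographically
    sorted free players, the last player toggling fastest.
    """
    free = subgame.free_players
    f = len(free)
    if f > max_subgame_players:
        raise GTAError(f"{f} free players exceed cap {max_subgame_players}")
    for code in range(1 << f):
        state: StrategyState = {subgame.seed: 1}
        for j, player in enumerate(free):
            state[player] = (code >> (f - 1 - j)) & 1
        yield state


def is_equilibrium(state: Mapping[str, int], subgame: SubGame,
                   scores: GeneScoreTable, params: PayoffParams) -> bool:
    """Pure-strategy Nash check: no free player can strictly raise its own
    payoff by unilaterally flipping join↔leave (the seed never deviates)."""
    for player in subgame.free_players:
        current = payoff(player, state, subgame.graph, scores, params)
        flipped = dict(state)
        flipped[player] = 1 - flipped[player]
        if payoff(player, flipped, subgame.graph, scores, params) > current:
            return False
    return True


def _payoff_table(subgame: SubGame, scores: GeneScoreTable,
                  params: PayoffParams
                  ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Vectorized payoffs for all states × players.

    Returns (PF, M, players): PF[s, i] is player i's payoff in state s,
    M[s, i] its strategy bit; players are sorted with the seed first.
    """
    free = list(subgame.free_players)
    players = [subgame.seed] + free
    f = len(free)
    n_states = 1 << f

    # strategy matrix: column 0 (seed) all ones; free columns count in
    # binary with the last free player toggling fastest
    M = np.ones((n_states, f + 1), dtype=np.int8)
    codes = np.arange(n_states, dtype=np.int64)
    for j in range(f):
        M[:, 1 + j] = (codes >> (f - 1 - j)) & 1

    t = np.array([scores.t(p) for p in players])
    idx = {p: i for i, p in enumerate(players)}
    edges = [(idx[a], idx[b], d.get("weight", 1.0))
             for a, b, d in subgame.graph.edges(data=True)]

    Mf = M.astype(np.float64)
    k = Mf.sum(axis=1)                                # |V_join| per state
    wsum = np.zeros(n_states)
    A = np.zeros((f + 1, f + 1))
    for u, v, w in edges:
        wsum += w * Mf[:, u] * Mf[:, v]
        A[u, v] = A[v, u] = 1.0
    pairs = k * (k - 1) / 2.0
    de = np.divide(wsum, pairs, out=np.zeros_like(wsum), where=pairs > 0)

    # LS[s, i] = s_i * Σ_j A_ij s_j t_j
    ls = Mf * (Mf @ (A * t[None, :]).T)
    pf = (params.alpha * t[None, :] + params.beta * ls
          + params.gamma * de[:, None] - params.delta * (k[:, None] - 1.0))
    return pf, M, players


def _joined_genes(state_code: int, players: Sequence[str], f: int
                  ) -> tuple[str, ...]:
    joined = [players[0]]
    for j in range(f):
        if (state_code >> (f - 1 - j)) & 1:
            joined.append(players[1 + j])
    return tuple(sorted(joined))


def solve_subgame(subgame: SubGame, scores: GeneScoreTable,
                  params: PayoffParams,
                  max_subgame_players: int = DEFAULT_MAX_SUBGAME_PLAYERS
                  ) -> SubgameSolution:
    """Exhaustively find the sub-game's pure-strategy Nash equilibria and
    select one.

    Selection among equilibria: highest mean |t-score| over joined genes;
    ties go to the larger joined set, then the lexicographically smallest
    joined tuple. If no pure equilibrium exists (possible in principle),
    the state with the largest total payoff is returned and flagged.
    """
    free = subgame.free_players
    f = len(free)
    if f > max_subgame_players:
        raise GTAError(f"{f} free players exceed cap {max_subgame_players}")

    pf, M, players = _payoff_table(subgame, scores, params)
    n_states = 1 << f
    codes = np.arange(n_states, dtype=np.int64)

    # state s with player j flipped is state s XOR bit(j)
    stable = np.ones(n_states, dtype=bool)
    for j in range(f):
        flipped = codes ^ (1 << (f - 1 - j))
        stable &= ~(pf[flipped, 1 + j] > pf[codes, 1 + j])
    eq_codes = codes[stable]

    abs_t = np.abs([scores.t(p) for p in players])
    Mf = M.astype(np.float64)
    mean_abs_t = (Mf @ abs_t) / Mf.sum(axis=1)

    if len(eq_codes) > 0:
        pool, flag = eq_codes, True
    else:
        total = pf.sum(axis=1)
        pool = codes[total == total.max()]
        flag = False
        logger.warning(
            "sub-game (seed %s, anchor %s) has no pure Nash equilibrium; "
            "falling back to the max-total-payoff state",
            subgame.seed, subgame.anchor,
        )

    best = min(
        pool,
        key=lambda c: (-mean_abs_t[c], -int(M[c].sum()),
                       _joined_genes(int(c), players, f)),
    )
    state: StrategyState = {subgame.seed: 1}
    for j, player in enumerate(free):
        state[player] = int((int(best) >> (f - 1 - j)) & 1)
    return SubgameSolution(state=state, is_equilibrium=flag,
                           n_equilibria=int(len(eq_codes)))


def merge_subgames(candidate: CandidateSubnetwork,
                   solved: Sequence[Mapping[str, int] | SubgameSolution],
                   scores: GeneScoreTable,
                   params: PayoffParams | None = None) -> SubnetworkMarker:
    """Union of the per-sub-game joined sets → one subnetwork marker.

    A two-step gene duplicated across sub-games joins iff it joins in at
    least one of them. Edges are induced on the joined set from the
    candidate; the marker score is the mean |t-score| of joined genes.
    """
    params = params or PayoffParams()
    joined: set[str] = {candidate.seed}
    for sol in solved:
        state = sol.state if isinstance(sol, SubgameSolution) else sol
        joined.update(g for g, s in state.items() if s == 1)

    graph = candidate.graph.subgraph(sorted(joined)).copy()
    score = float(np.mean([abs(scores.t(g)) for g in joined]))
    roles = {candidate.seed: "seed"}
    roles.update({g: "one-step" for g in candidate.one_step})
    roles.update({g: "two-step" for g in candidate.two_step})
    merged_state = {g: 1 for g in joined}
    per_gene = {
        g: GeneInfo(
            role=roles.get(g, "two-step"),
            tscore=scores.t(g),
            degree=graph.degree(g),
            payoff=payoff(g, merged_state, graph, scores, params),
        )
        for g in sorted(joined)
    }
    return SubnetworkMarker(
        seed=candidate.seed,
        joined=frozenset(joined),
        graph=graph,
        score=score,
        per_gene=per_gene,
    )
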