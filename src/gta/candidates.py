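"""Seed ranking, two-step candidate extraction, clustering-based pruning.

A candidate subnetwork (one *game*) is grown around a seed gene: the
seed's direct neighbours (one-step tier) plus every node at shortest-path
distance exactly two (two-step tier), with the edges induced on the
member set. Each tier is then pruned — nodes are visited in increasing
in-candidate degree and removed whenever the removal strictly raises the
relevant local clustering coefficient — and finally capped at the
user-configured tier sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from gta.errors import GTAError, InputError
from gta.scoring import GeneScoreTable

CAP_RANGE = (1, 19)


@dataclass
class CandidateSubnetwork:
    """A game: seed, retained tiers and the induced working-graph edges.

    ``anchor_map``, when set (after :func:`apply_caps`), records which
    two-step nodes each one-step anchor carries into its sub-game.
    """

    seed: str
    one_step: tuple[str, ...]
    two_step: tuple[str, ...]
    graph: nx.Graph
    anchor_map: dict[str, tuple[str, ...]] | None = None

    @property
    def members(self) -> tuple[str, ...]:
        return (self.seed, *self.one_step, *self.two_step)


def rank_seeds(graph: nx.Graph, scores: GeneScoreTable,
               signed: bool = False) -> list[str]:
    """Seed candidates: nodes with degree ≥ the graph's mean degree,
    sorted by decreasing |t-score| (or signed t with ``signed``), ties
    broken lexicographically."""
    n = graph.number_of_nodes()
    if n == 0:
        raise GTAError("empty working graph: no seeds can be ranked")
    mean_degree = 2.0 * graph.number_of_edges() / n
    eligible = [v for v in graph if graph.degree(v) >= mean_degree]
    if not eligible:
        raise GTAError(
            "no node reaches the mean degree; try a smaller network or "
            "different expression data"
        )
    key = (lambda v: scores.t(v)) if signed else (lambda v: abs(scores.t(v)))
    return sorted(eligible, key=lambda v: (-key(v), v))


def extract_candidate(graph: nx.Graph, seed: str) -> CandidateSubnetwork:
    """All nodes within distance two of the seed, with induced edges."""
    if seed not in graph:
        raise GTAError(f"seed {seed!r} not in the working graph")
    one_step = sorted(graph.neighbors(seed))
    two_step = sorted(
        {n for v in one_step for n in graph.neighbors(v)}
        - set(one_step) - {seed}
    )
    members = [seed, *one_step, *two_step]
    return CandidateSubnetwork(
        seed=seed,
        one_step=tuple(one_step),
        two_step=tuple(two_step),
        graph=graph.subgraph(members).copy(),
    )


def local_clustering_coefficient(graph: nx.Graph, node: str,
                                 neighbor_set: Iterable[str] | None = None
                                 ) -> float:
    """Fraction of realized edges among a node's neighbours.

    |edges among neighbours| / C(k, 2), with 0 for fewer than two
    neighbours; edge weights are ignored (a count, not a weight sum).
    """
    nbrs = sorted(neighbor_set) if neighbor_set is not None \
        else sorted(graph.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        1 for i, a in enumerate(nbrs) for b in nbrs[i + 1:]
        if graph.has_edge(a, b)
    )
    return links / (k * (k - 1) / 2)


def _rebuild(candidate: CandidateSubnetwork, work: nx.Graph,
             one_step: Iterable[str], two_step: Iterable[str]
             ) -> CandidateSubnetwork:
    one = tuple(sorted(one_step))
    two = tuple(sorted(two_step))
    members = [candidate.seed, *one, *two]
    return CandidateSubnetwork(
        seed=candidate.seed, one_step=one, two_step=two,
        graph=work.subgraph(members).copy(),
    )


def prune_neighbors(candidate: CandidateSubnetwork, tier: str,
                    scores: GeneScoreTable | None = None,
                    two_step_rule: str = "seed") -> CandidateSubnetwork:
    """Prune one tier to raise the seed's neighbourhood clustering.

    Tier nodes are visited once in increasing in-candidate degree (ties
    lexicographic); a node is removed iff its removal *strictly*
    increases the reference clustering coefficient, which is then
    recomputed. For the one-step tier the reference is the seed's own
    clustering coefficient. The criterion carried over to the two-step
    tier is configurable, since a non-neighbour cannot change the seed's
    own clustering: ``seed`` (default) applies the rule literally — the
    seed's clustering coefficient never strictly increases, so the pass
    removes only orphans; ``anchor`` applies the rule to the clustering
    coefficient of the node's one-step anchor (the retained neighbour
    linking it to the seed); ``seed2`` uses the edge density of the
    seed's full two-step neighbourhood. In every variant, two-step
    nodes left without a retained one-step neighbour are removed
    unconditionally first. The one-step tier is never emptied: if every
    removal is accepted, the neighbour with the largest |t-score| (or
    the largest degree when no scores are given) is restored.
    """
    if tier not in ("one_step", "two_step"):
        raise GTAError(f"unknown tier {tier!r}")
    if two_step_rule not in ("seed", "anchor", "seed2"):
        raise GTAError(f"unknown two-step pruning rule {two_step_rule!r}")

    work = candidate.graph.copy()
    seed = candidate.seed

    if tier == "one_step":
        order = sorted(candidate.one_step,
                       key=lambda v: (work.degree(v), v))
        removed: list[str] = []
        ref = local_clustering_coefficient(work, seed)
        for node in order:
            work.remove_node(node)
            new = local_clustering_coefficient(work, seed)
            if new > ref:
                ref = new
                removed.append(node)
            else:
                work.add_node(node)
                for nbr in candidate.graph.neighbors(node):
                    if nbr in work:
                        work.add_edge(node, nbr,
                                      **candidate.graph[node][nbr])
        kept = [v for v in candidate.one_step if v not in removed]
        if not kept:
            if scores is not None:
                best = max(candidate.one_step,
                           key=lambda v: (abs(scores.t(v)), v))
            else:
                best = max(candidate.one_step,
                           key=lambda v: (candidate.graph.degree(v), v))
            kept = [best]
            work.add_node(best)
            for nbr in candidate.graph.neighbors(best):
                if nbr in work:
                    work.add_edge(best, nbr, **candidate.graph[best][nbr])
        return _rebuild(candidate, work, kept, candidate.two_step)

    # two-step tier: drop orphans, then apply the accept/reject pass
    anchors = set(candidate.one_step)
    two = [v for v in candidate.two_step if v in work]
    orphaned = [v for v in two
                if not any(a in anchors for a in work.neighbors(v))]
    for v in orphaned:
        work.remove_node(v)
    two = [v for v in two if v not in orphaned]

    def reference(anchor: str | None) -> float:
        if two_step_rule == "anchor":
            return local_clustering_coefficient(work, anchor)
        if two_step_rule == "seed":
            return local_clustering_coefficient(work, seed)
        # second-order neighbourhood density around the seed
        return local_clustering_coefficient(
            work, seed, [v for v in work if v != seed])

    order = sorted(two, key=lambda v: (work.degree(v), v))
    for node in order:
        anchor = (min(a for a in work.neighbors(node) if a in anchors)
                  if two_step_rule == "anchor" else None)
        ref = reference(anchor)
        edges = [(nbr, dict(work[node][nbr])) for nbr in work.neighbors(node)]
        work.remove_node(node)
        if reference(anchor) > ref:
            two.remove(node)
        else:
            work.add_node(node)
            for nbr, data in edges:
                work.add_edge(node, nbr, **data)
    return _rebuild(candidate, work, candidate.one_step, two)


def _top_k(nodes: Iterable[str], k: int, filter_method: str,
           candidate: CandidateSubnetwork, scores: GeneScoreTable
           ) -> list[str]:
    if filter_method == "tscore":
        key = lambda v: (-abs(scores.t(v)), v)  # noqa: E731
    elif filter_method == "degree":
        key = lambda v: (-candidate.graph.degree(v), v)  # noqa: E731
    else:
        raise InputError(f"unknown filter method {filter_method!r}")
    return sorted(nodes, key=key)[:k]


def apply_caps(candidate: CandidateSubnetwork, max_one_step: int,
               max_two_step: int, filter_method: str,
               scores: GeneScoreTable) -> CandidateSubnetwork:
    """Enforce the user caps on tier sizes (each in 1..19).

    The one-step tier keeps its top ``max_one_step`` nodes by the filter
    method (largest |t-score| or largest in-candidate degree, ties
    lexicographic). The two-step cap applies per anchor: every retained
    one-step neighbour carries at most ``max_two_step`` of its adjacent
    two-step nodes into its sub-game; orphaned two-step nodes are dropped
    after one-step capping. The per-anchor assignment is recorded in
    ``anchor_map``.
    """
    for name, cap in (("max_one_step", max_one_step),
                      ("max_two_step", max_two_step)):
        if not (CAP_RANGE[0] <= cap <= CAP_RANGE[1]):
            raise InputError(
                f"{name}={cap} outside the allowed range "
                f"{CAP_RANGE[0]}..{CAP_RANGE[1]}"
            )

    one = candidate.one_step
    if len(one) > max_one_step:
        one = tuple(sorted(
            _top_k(one, max_one_step, filter_method, candidate, scores)))

    work = candidate.graph
    anchor_map: dict[str, tuple[str, ...]] = {}
    kept_two: set[str] = set()
    for anchor in one:
        adjacent = [v for v in candidate.two_step
                    if v in work and work.has_edge(anchor, v)]
        top = _top_k(adjacent, max_two_step, filter_method, candidate, scores)
        anchor_map[anchor] = tuple(sorted(top))
        kept_two.update(top)

    result = _rebuild(candidate, work, one, sorted(kept_two))
    result.anchor_map = anchor_map
    return result
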