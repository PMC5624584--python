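"""End-to-end orchestration: score → rank seeds → per-seed game → markers.

For every eligible seed (degree at least the working graph's mean,
visited in decreasing |t-score| order) a candidate subnetwork is
extracted, pruned, capped, decomposed into sub-games, solved and merged.
Markers with identical joined sets collapse to the higher-ranked seed's
marker; the surviving markers are ranked globally by score (mean |t| of
the joined genes) and truncated to ``n_results``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import networkx as nx

from gta.errors import GTAError, InputError
from gta.io import ExpressionProfile, read_expression, read_network, write_markers
from gta.scoring import GeneScoreTable, PayoffParams, score_genes
from gta.candidates import (
    apply_caps,
    extract_candidate,
    prune_neighbors,
    rank_seeds,
)
from gta.game import (
    DEFAULT_MAX_SUBGAME_PLAYERS,
    SubnetworkMarker,
    decompose,
    merge_subgames,
    solve_subgame,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a marker-finding run.

    Payoff weights default to α=1.24, β=1, γ=1, δ=2. The one-/two-step
    neighbour caps accept 1–19 (the two-step cap applies per anchor).
    ``filter_method`` picks how over-cap tiers are thinned: by largest
    |t-score| or by largest in-candidate degree.
    """

    alpha: float = 1.24
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 2.0
    max_one_step: int = 4
    max_two_step: int = 3
    n_results: int = 50
    filter_method: str = "tscore"
    rank_signed: bool = False
    show_tscores: bool = False
    show_degrees: bool = False
    two_step_rule: str = "seed"
    max_subgame_players: int = DEFAULT_MAX_SUBGAME_PLAYERS
    case_label: str | None = None
    control_label: str | None = None
    network_path: str | None = None
    expression_path: str | None = None
    labels_path: str | None = None
    out_dir: str | None = None

    @property
    def payoff_params(self) -> PayoffParams:
        return PayoffParams(alpha=self.alpha, beta=self.beta,
                            gamma=self.gamma, delta=self.delta)

    def __post_init__(self) -> None:
        if self.n_results < 1:
            raise InputError("n_results must be >= 1")
        if self.filter_method not in ("tscore", "degree"):
            raise InputError(f"unknown filter method {self.filter_method!r}")


def intersect_universe(network: nx.Graph, profile: ExpressionProfile
                       ) -> tuple[nx.Graph, int]:
    """Working graph restricted to genes present in the expression profile.

    Returns the restricted copy and the number of removed nodes. Every
    remaining player is scoreable.
    """
    keep = [n for n in network if n in set(profile.genes)]
    removed = network.number_of_nodes() - len(keep)
    if removed:
        logger.info(
            "removed %d network node(s) lacking expression data", removed)
    return network.subgraph(keep).copy(), removed


def run(network: nx.Graph, profile: ExpressionProfile,
        config: RunConfig | None = None
        ) -> tuple[list[SubnetworkMarker], dict]:
    """Full marker-finding run; returns (ranked markers, run summary)."""
    config = config or RunConfig()
    params = config.payoff_params

    working, n_removed = intersect_universe(network, profile)
    if working.number_of_nodes() == 0:
        raise InputError(
            "no shared gene identifiers between network and expression "
            "profile; the same nomenclature must be used in both"
        )
    scores = score_genes(profile, genes=working.nodes())

    seeds = rank_seeds(working, scores, signed=config.rank_signed)
    logger.info("processing %d eligible seed(s)", len(seeds))

    markers: list[SubnetworkMarker] = []
    seen_joined: dict[frozenset, int] = {}
    n_duplicates = 0
    n_fallback_subgames = 0
    for seed in seeds:
        candidate = extract_candidate(working, seed)
        candidate = prune_neighbors(candidate, "one_step", scores=scores,
                                    two_step_rule=config.two_step_rule)
        candidate = prune_neighbors(candidate, "two_step", scores=scores,
                                    two_step_rule=config.two_step_rule)
        candidate = apply_caps(candidate, config.max_one_step,
                               config.max_two_step, config.filter_method,
                               scores)
        subgames = decompose(candidate, config.max_subgame_players)
        solutions = [solve_subgame(sg, scores, params,
                                   config.max_subgame_players)
                     for sg in subgames]
        n_fallback_subgames += sum(1 for s in solutions if not s.is_equilibrium)
        marker = merge_subgames(candidate, solutions, scores, params)
        if marker.joined in seen_joined:
            n_duplicates += 1
            continue
        seen_joined[marker.joined] = len(markers)
        markers.append(marker)
        logger.debug(
            "seed %s: %d sub-game(s), %d joined gene(s), score %.4f",
            seed, len(subgames), len(marker.joined), marker.score)

    markers.sort(key=lambda m: (-m.score, m.seed))
    top = markers[:config.n_results]
    summary = {
        "parameters": {
            "alpha": config.alpha, "beta": config.beta,
            "gamma": config.gamma, "delta": config.delta,
            "max_one_step": config.max_one_step,
            "max_two_step": config.max_two_step,
            "n_results": config.n_results,
            "filter_method": config.filter_method,
            "rank_signed": config.rank_signed,
            "two_step_rule": config.two_step_rule,
        },
        "n_network_nodes": network.number_of_nodes(),
        "n_network_edges": network.number_of_edges(),
        "n_expression_genes": len(profile.genes),
        "n_samples": profile.m,
        "n_nodes_without_expression": n_removed,
        "n_working_nodes": working.number_of_nodes(),
        "n_eligible_seeds": len(seeds),
        "n_seeds_processed": len(seeds),
        "n_duplicate_markers_dropped": n_duplicates,
        "n_subgames_without_equilibrium": n_fallback_subgames,
        "n_markers_found": len(markers),
        "n_markers_returned": len(top),
    }
    if len(top) < config.n_results:
        summary["note"] = (
            f"only {len(top)} distinct marker(s) found; "
            f"{config.n_results} requested"
        )
    return top, summary


def run_from_paths(config: RunConfig) -> tuple[list[SubnetworkMarker], dict]:
    """Read the configured input files, run, and write results if out_dir set."""
    if not (config.network_path and config.expression_path
            and config.labels_path):
        raise InputError("network, expression and labels paths are required")
    network = read_network(config.network_path)
    profile = read_expression(config.expression_path, config.labels_path,
                              case_label=config.case_label,
                              control_label=config.control_label)
    markers, summary = run(network, profile, config)
    if config.out_dir:
        write_markers(markers, config.out_dir,
                      show_tscores=config.show_tscores,
                      show_degrees=config.show_degrees,
                      run_summary=summary)
    return markers, summary
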