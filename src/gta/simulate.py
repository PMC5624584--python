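"""Synthetic benchmarks: a random PPIN with a planted dense, differentially
expressed module.

The generator emulates the structure the marker search assumes: genes
linked to the phenotype are both differentially expressed and densely
interconnected. The background interactome is an Erdős–Rényi graph; a
small module is rewired to a higher edge probability (and forced
connected); expression is Gaussian, with the planted genes shifted by an
effect size Δ in the case class only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from gta.errors import GTAError, InputError
from gta.io import ExpressionProfile, write_expression, write_network


@dataclass
class FixtureSpec:
    """Parameters of one synthetic benchmark instance.

    Defaults describe the standard recovery setting: 200 genes, a
    10-gene module at edge probability 0.6 over a 0.02 background, a
    case-only mean shift of Δ=2 expression units against unit noise, and
    20 samples per class.
    """

    n_genes: int = 200
    p_background: float = 0.02
    module_size: int = 10
    p_module: float = 0.6
    n_case: int = 20
    n_control: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    rng_seed: int = 0
    distribution: str = "normal"  # or "lognormal"

    def __post_init__(self) -> None:
        if not (0 < self.p_background < 1):
            raise InputError("background edge probability must be in (0,1)")
        if self.module_size > self.n_genes:
            raise InputError("planted module larger than the gene universe")
        if self.p_module < self.p_background:
            raise InputError(
                "planted edge probability must be >= background probability")
        if min(self.n_case, self.n_control) < 3:
            raise InputError("each phenotype class needs >= 3 samples")
        if self.distribution not in ("normal", "lognormal"):
            raise InputError(f"unknown distribution {self.distribution!r}")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate(spec: FixtureSpec
             ) -> tuple[nx.Graph, ExpressionProfile, frozenset]:
    """Generate (network, profile, planted gene set) from a fixture spec.

    Deterministic given ``rng_seed``: all randomness flows from a single
    numpy Generator.
    """
    rng = np.random.default_rng(spec.rng_seed)
    names = _gene_names(spec.n_genes)

    graph = nx.gnp_random_graph(
        spec.n_genes, spec.p_background,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    planted_idx = sorted(
        rng.choice(spec.n_genes, size=spec.module_size, replace=False))

    # rewire the module: resample intra-module edges at the higher rate
    for a, b in [(a, b) for i, a in enumerate(planted_idx)
                 for b in planted_idx[i + 1:]]:
        if graph.has_edge(a, b):
            graph.remove_edge(a, b)
        if rng.random() < spec.p_module:
            graph.add_edge(a, b)
    # force connectivity with a random spanning tree over the module
    order = list(rng.permutation(planted_idx))
    for i, node in enumerate(order[1:], start=1):
        attach = order[rng.integers(0, i)]
        graph.add_edge(node, attach)
    if not nx.is_connected(graph.subgraph(planted_idx)):
        raise GTAError("internal error: planted module is disconnected")

    graph = nx.relabel_nodes(graph, dict(enumerate(names)))
    nx.set_edge_attributes(graph, 1.0, "weight")
    planted = frozenset(names[i] for i in planted_idx)

    m = spec.n_case + spec.n_control
    samples = ([f"case{i:03d}" for i in range(1, spec.n_case + 1)]
               + [f"ctrl{i:03d}" for i in range(1, spec.n_control + 1)])
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, m))
    for i in planted_idx:
        values[i, :spec.n_case] += spec.effect_size
    if spec.distribution == "lognormal":
        values = np.exp(values)

    profile = ExpressionProfile(
        values=pd.DataFrame(values, index=names, columns=samples),
        labels=pd.Series([1] * spec.n_case + [2] * spec.n_control,
                         index=samples, dtype=int),
    )
    return graph, profile, planted


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write network/expression/labels/truth files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    graph, profile, planted = generate(spec)
    paths = {
        "network": out_dir / "network.sif",
        "expression": out_dir / "expression.tsv",
        "labels": out_dir / "labels.tsv",
        "truth": out_dir / "planted_genes.txt",
    }
    write_network(graph, paths["network"], dialect="sif")
    write_expression(profile, paths["expression"], paths["labels"])
    with paths["truth"].open("w") as fh:
        for gene in sorted(planted):
            fh.write(gene + "\n")
    return paths
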