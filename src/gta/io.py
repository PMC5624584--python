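"""Readers and writers for networks, expression profiles and marker results.

The in-memory containers are deliberately thin: an interaction network is
a :class:`networkx.Graph` whose edges carry a positive ``weight``
attribute, and an expression profile is a pandas DataFrame (genes ×
samples) paired with a per-sample phenotype label (1 = case, 2 = control).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from gta.errors import InputError

logger = logging.getLogger(__name__)

#: header tokens that mark the first line of an edge list as a header row
_EDGE_HEADER_TOKENS = {
    "source", "target", "node1", "node2", "gene1", "gene2",
    "from", "to", "protein1", "protein2",
}


@dataclass
class ExpressionProfile:
    """A gene × sample expression matrix with a two-class phenotype labeling.

    Parameters
    ----------
    values:
        DataFrame indexed by gene identifier with one column per sample.
    labels:
        Series mapping sample identifier to phenotype class, 1 (case) or
        2 (control). Every column of ``values`` must be labeled.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise InputError(f"samples without labels: {missing[:5]}")
        self.labels = self.labels.loc[list(self.values.columns)]
        bad = sorted(set(self.labels.unique()) - {1, 2})
        if bad:
            raise InputError(
                f"phenotype labels must be 1 or 2, found {bad} (two classes only)"
            )
        for cls in (1, 2):
            n = int((self.labels == cls).sum())
            if n < 3:
                raise InputError(
                    f"phenotype class {cls} has {n} samples; at least 3 are "
                    "required for per-class variance and t-statistics"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def m(self) -> int:
        """Number of labeled samples."""
        return self.values.shape[1]

    def class_samples(self, cls: int) -> list[str]:
        return [s for s in self.samples if self.labels[s] == cls]


def read_network(path: str | Path, dialect: str | None = None) -> nx.Graph:
    """Read an undirected, optionally weighted network from SIF or TSV.

    SIF rows are ``A <relation> B`` (the relation is ignored; the standard
    multi-target form ``A rel B C`` is accepted, as is a single-token row
    declaring an isolated node). TSV rows are ``A B [weight]`` with an
    optional header. Duplicate edges keep the maximum weight; self-loops
    are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"network file not found: {path}")
    if dialect is None:
        dialect = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if dialect not in ("sif", "tsv"):
        raise InputError(f"unknown network dialect {dialect!r}")

    graph = nx.Graph()
    n_self_loops = 0

    def add_edge(a: str, b: str, w: float, lineno: int) -> None:
        nonlocal n_self_loops
        if w <= 0:
            raise InputError(f"{path}:{lineno}: non-positive edge weight {w}")
        if a == b:
            n_self_loops += 1
            graph.add_node(a)
            return
        if graph.has_edge(a, b):
            graph[a][b]["weight"] = max(graph[a][b]["weight"], w)
        else:
            graph.add_edge(a, b, weight=w)

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if dialect == "sif":
                if len(tokens) == 1:
                    graph.add_node(tokens[0])
                elif len(tokens) >= 3:
                    for target in tokens[2:]:
                        add_edge(tokens[0], target, 1.0, lineno)
                else:
                    raise InputError(
                        f"{path}:{lineno}: malformed SIF row (expected "
                        f"'A <relation> B'): {line!r}"
                    )
            else:
                if lineno == 1 and _looks_like_header(tokens):
                    continue
                if len(tokens) == 2:
                    add_edge(tokens[0], tokens[1], 1.0, lineno)
                elif len(tokens) == 3:
                    try:
                        w = float(tokens[2])
                    except ValueError as exc:
                        raise InputError(
                            f"{path}:{lineno}: non-numeric weight {tokens[2]!r}"
                        ) from exc
                    add_edge(tokens[0], tokens[1], w, lineno)
                else:
                    raise InputError(
                        f"{path}:{lineno}: malformed edge-list row (expected "
                        f"'A B [weight]'): {line!r}"
                    )

    graph.graph["n_dropped_self_loops"] = n_self_loops
    if n_self_loops:
        logger.info("dropped %d self-loop(s) while reading %s", n_self_loops, path)
    logger.info(
        "loaded network %s: %d nodes, %d edges",
        path, graph.number_of_nodes(), graph.number_of_edges(),
    )
    return graph


def _looks_like_header(tokens: Sequence[str]) -> bool:
    if len(tokens) == 3:
        try:
            float(tokens[2])
        except ValueError:
            return True
        return False
    return all(t.lower() in _EDGE_HEADER_TOKENS for t in tokens[:2])


def write_network(graph: nx.Graph, path: str | Path,
                  dialect: str | None = None) -> Path:
    """Write a network as a weighted TSV edge list or a SIF file.

    SIF preserves isolated nodes (single-token rows) but not weights; the
    TSV dialect preserves weights and writes isolated nodes as comment
    rows ignored on re-read only if absent — graphs with isolates should
    use SIF for exact node-set round-trips.
    """
    path = Path(path)
    if dialect is None:
        dialect = "sif" if path.suffix.lower() == ".sif" else "tsv"
    with path.open("w") as fh:
        if dialect == "sif":
            for a, b in sorted(graph.edges()):
                fh.write(f"{a}\tpp\t{b}\n")
            for node in sorted(nx.isolates(graph)):
                fh.write(f"{node}\n")
        else:
            fh.write("source\ttarget\tweight\n")
            for a, b in sorted(graph.edges()):
                fh.write(f"{a}\t{b}\t{graph[a][b].get('weight', 1.0):g}\n")
    return path


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    case_label: str | None = None,
    control_label: str | None = None,
) -> ExpressionProfile:
    """Read an expression matrix and a sample→phenotype label assignment.

    The matrix TSV has sample IDs in the header and gene IDs in the first
    column. The labels TSV has two columns, sample ID and label; labels are
    ``1``/``2`` unless ``case_label``/``control_label`` name the two classes
    explicitly. Samples present in the matrix but absent from the labels
    file are dropped with a logged count.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    for p in (matrix_path, labels_path):
        if not p.exists():
            raise InputError(f"file not found: {p}")

    values = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    values.index = values.index.astype(str)
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise InputError(
            f"{matrix_path}: non-numeric expression value "
            f"{values.loc[gene, sample]!r} at gene {gene!r}, sample {sample!r}"
        )
    values = numeric.astype(float)

    raw_labels: dict[str, str] = {}
    with labels_path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise InputError(
                    f"{labels_path}:{lineno}: malformed label row "
                    f"(expected 'sample label'): {line!r}"
                )
            if lineno == 1 and tokens[0].lower() in ("sample", "sample_id", "id"):
                continue
            raw_labels[tokens[0]] = tokens[1]

    if case_label is not None or control_label is not None:
        if case_label is None or control_label is None:
            raise InputError("case_label and control_label must be given together")
        mapping = {case_label: 1, control_label: 2}
        unknown = sorted({v for v in raw_labels.values()} - set(mapping))
        if unknown:
            raise InputError(
                f"{labels_path}: labels {unknown} match neither case "
                f"({case_label!r}) nor control ({control_label!r})"
            )
        labels = {s: mapping[v] for s, v in raw_labels.items()}
    else:
        labels = {}
        for s, v in raw_labels.items():
            if v not in ("1", "2"):
                raise InputError(
                    f"{labels_path}: label {v!r} for sample {s!r} is not 1 or 2 "
                    "(two classes only; use case/control label names to remap)"
                )
            labels[s] = int(v)

    unlabeled = [s for s in values.columns if s not in labels]
    if unlabeled:
        logger.warning(
            "dropping %d unlabeled sample(s): %s%s",
            len(unlabeled), unlabeled[:5], "..." if len(unlabeled) > 5 else "",
        )
        values = values.drop(columns=unlabeled)

    label_series = pd.Series({s: labels[s] for s in values.columns}, dtype=int)
    return ExpressionProfile(values=values, labels=label_series)


def write_expression(profile: ExpressionProfile, matrix_path: str | Path,
                     labels_path: str | Path) -> None:
    """Write a profile back to the matrix + labels TSV dialect."""
    profile.values.to_csv(matrix_path, sep="\t", index_label="gene")
    with Path(labels_path).open("w") as fh:
        fh.write("sample\tlabel\n")
        for s in profile.samples:
            fh.write(f"{s}\t{int(profile.labels[s])}\n")


def write_markers(
    markers: Sequence,
    out_dir: str | Path,
    show_tscores: bool = False,
    show_degrees: bool = False,
    run_summary: Mapping | None = None,
) -> list[Path]:
    """Write ranked markers: one SIF per marker, a summary TSV, a JSON summary.

    Each marker is named after its seed gene. The summary TSV has one row
    per (marker, gene) with the gene's role (seed / one-step / two-step)
    and, when the corresponding flag is on, its t-score and in-marker
    degree. Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    columns = ["rank", "marker", "score", "gene", "role"]
    if show_tscores:
        columns.append("t_score")
    if show_degrees:
        columns.append("degree")
    rows = []
    for rank, marker in enumerate(markers, start=1):
        sif_path = out_dir / f"marker_{rank:03d}_{marker.seed}.sif"
        with sif_path.open("w") as fh:
            if marker.graph.number_of_edges() == 0:
                fh.write(f"{marker.seed}\n")
            else:
                for a, b in sorted(marker.graph.edges()):
                    fh.write(f"{a}\tpp\t{b}\n")
        written.append(sif_path)
        for gene in sorted(marker.joined):
            info = marker.per_gene[gene]
            row = [rank, marker.seed, f"{marker.score:.6g}", gene, info.role]
            if show_tscores:
                row.append(f"{info.tscore:.6g}")
            if show_degrees:
                row.append(info.degree)
            rows.append(row)

    summary_path = out_dir / "markers_summary.tsv"
    with summary_path.open("w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    written.append(summary_path)

    json_path = out_dir / "run_summary.json"
    payload = dict(run_summary or {})
    payload["n_markers_written"] = len(markers)
    with json_path.open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(json_path)
    return written
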