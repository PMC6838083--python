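"""Equivalence graph construction, maximal cliques and reference-gene choice.

The selection rule: build an undirected graph with one node per candidate
gene and an edge wherever the pairwise equivalence test is significant
(``p_tost < cutoff``, strict).  The maximum cliques — largest sets of
mutually equivalent genes — define the reference set; when several cliques
share the maximum size, their intersection is selected.  Cliques of fewer
than ``min_reliable_clique`` genes (default 4) are flagged unreliable,
because small cliques arise too easily from chance edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .cq_data import CqMatrix
from .equivalence import all_pairs

__all__ = [
    "ReferenceSelection",
    "DeltaProfile",
    "clique_edge_count",
    "build_graph",
    "maximal_cliques",
    "select_reference_genes",
    "delta_profile",
    "export_graph",
    "write_selection",
]


def clique_edge_count(n: int) -> int:
    """Number of edges a clique of ``n`` nodes must contain: n*(n-1)/2."""
    return n * (n - 1) // 2


@dataclass
class ReferenceSelection:
    """Outcome of the maximal-clique selection.

    ``selected`` is the intersection of all maximum-cardinality cliques;
    ``ambiguous`` is set when that intersection is empty although cliques of
    size >= 2 exist; ``reliable`` is false when the maximum clique is smaller
    than ``min_reliable_clique``.
    """

    maximal_cliques: list[tuple[str, ...]]
    maximum_size: int
    selected: tuple[str, ...]
    isolated: tuple[str, ...]
    reliable: bool
    ambiguous: bool
    min_reliable_clique: int

    @property
    def maximum_cliques(self) -> list[tuple[str, ...]]:
        """All maximal cliques of maximum cardinality."""
        return [c for c in self.maximal_cliques if len(c) == self.maximum_size]


def build_graph(pairs: pd.DataFrame, cutoff: float,
                delta: float | None = None) -> nx.Graph:
    """Equivalence graph from a pairwise TOST table.

    An edge is added iff the pair is testable and ``p_tost < cutoff``
    (strict inequality); untestable pairs never produce edges.  All genes
    appearing in the table become nodes, so untestable or non-equivalent
    genes show up as isolated nodes.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    g = nx.Graph()
    g.graph["cutoff"] = float(cutoff)
    if delta is None:
        delta = pairs.attrs.get("delta")
    if delta is not None:
        g.graph["delta"] = float(delta)
    genes = list(dict.fromkeys(pd.concat([pairs["gene_a"], pairs["gene_b"]])))
    g.add_nodes_from(genes)
    ok = pairs["testable"].astype(bool) & (pairs["p_tost"] < cutoff)
    for _, row in pairs[ok].iterrows():
        g.add_edge(row["gene_a"], row["gene_b"], p_tost=float(row["p_tost"]))
    return g


def maximal_cliques(graph: nx.Graph) -> list[tuple[str, ...]]:
    """All inclusion-maximal cliques, deterministically ordered.

    Each clique is sorted; the list is ordered by decreasing size, then
    lexicographically.  Isolated nodes appear as singleton cliques.
    """
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def select_reference_genes(graph: nx.Graph,
                           min_reliable_clique: int = 4) -> ReferenceSelection:
    """Select the reference-gene set from the equivalence graph.

    The selected set is the intersection of all cliques of maximum size.
    An empty intersection (possible when several disjoint maximum cliques
    exist) yields an empty selection flagged ``ambiguous``.
    """
    cliques = maximal_cliques(graph)
    if not cliques:
        return ReferenceSelection([], 0, (), (), False, False,
                                  min_reliable_clique)
    maximum_size = len(cliques[0])
    biggest = [set(c) for c in cliques if len(c) == maximum_size]
    selected = set.intersection(*biggest)
    isolated = tuple(sorted(n for n in graph.nodes if graph.degree[n] == 0))
    ambiguous = (not selected) and maximum_size >= 2
    return ReferenceSelection(
        maximal_cliques=cliques,
        maximum_size=maximum_size,
        selected=tuple(sorted(selected)),
        isolated=isolated,
        reliable=maximum_size >= min_reliable_clique and not ambiguous,
        ambiguous=ambiguous,
        min_reliable_clique=min_reliable_clique,
    )


@dataclass
class DeltaProfile:
    """Selections across a grid of equivalence margins.

    ``entry_delta[gene]`` is the smallest margin at which the gene enters the
    selected set (NaN if never); sorting by it gives the partial stability
    ranking induced by varying the margin.
    """

    deltas: list[float]
    selections: dict[float, ReferenceSelection]
    entry_delta: pd.Series

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, ed in self.entry_delta.items():
            rows.append({"gene": gene, "entry_delta": ed})
        return pd.DataFrame(rows).sort_values(
            ["entry_delta", "gene"], na_position="last").reset_index(drop=True)


def delta_profile(matrix: CqMatrix, deltas: list[float],
                  cutoff: float | Mapping[float, float] | Callable[[float], float],
                  alpha: float = 0.05,
                  min_reliable_clique: int = 4) -> DeltaProfile:
    """Run the full pairwise-test + clique selection across a margin grid.

    ``cutoff`` may be a single p-value threshold, a mapping delta -> cutoff,
    or a callable delta -> cutoff (e.g. wrapping the simulation-based
    calibration).
    """
    deltas = sorted(float(d) for d in deltas)
    selections: dict[float, ReferenceSelection] = {}
    entry: dict[str, float] = {}
    for d in deltas:
        if callable(cutoff):
            c = float(cutoff(d))
        elif isinstance(cutoff, Mapping):
            c = float(cutoff[d])
        else:
            c = float(cutoff)
        pairs = all_pairs(matrix, d, alpha=alpha)
        graph = build_graph(pairs, c, delta=d)
        sel = select_reference_genes(graph, min_reliable_clique)
        selections[d] = sel
        for gene in sel.selected:
            entry.setdefault(gene, d)
    entry_delta = pd.Series(
        {g: entry.get(g, np.nan) for g in matrix.genes}, name="entry_delta")
    return DeltaProfile(deltas=deltas, selections=selections,
                        entry_delta=entry_delta)


def _membership_classes(graph: nx.Graph,
                        selection: ReferenceSelection) -> dict[str, str]:
    """Node class: core (all maximum cliques) / clique (some) / other."""
    in_any = set().union(*(set(c) for c in selection.maximum_cliques)) \
        if selection.maximum_cliques and selection.maximum_size >= 2 else set()
    classes = {}
    for node in graph.nodes:
        if node in selection.selected and selection.maximum_size >= 2:
            classes[node] = "core"
        elif node in in_any:
            classes[node] = "clique"
        else:
            classes[node] = "other"
    return classes


_CLASS_COLORS = {"core": "red", "clique": "pink", "other": "green"}


def export_graph(graph: nx.Graph, selection: ReferenceSelection,
                 path: str | Path, fmt: str = "graphml") -> None:
    """Write the annotated equivalence graph.

    Formats: ``graphml``, ``dot`` (Graphviz) or ``edge_tsv``.  Nodes carry a
    ``membership`` attribute (core = in all maximum cliques, clique = in at
    least one maximum clique, other) and a matching fill colour; edges carry
    their TOST p-value.
    """
    path = Path(path)
    classes = _membership_classes(graph, selection)
    if fmt == "graphml":
        g = graph.copy()
        for node, cls in classes.items():
            g.nodes[node]["membership"] = cls
            g.nodes[node]["color"] = _CLASS_COLORS[cls]
        nx.write_graphml(g, path)
    elif fmt == "dot":
        lines = ["graph equivalence {", "  node [style=filled];"]
        for node in sorted(graph.nodes):
            cls = classes[node]
            lines.append(
                f'  "{node}" [fillcolor={_CLASS_COLORS[cls]}, membership={cls}];'
            )
        for a, b, data in sorted(graph.edges(data=True)):
            lines.append(f'  "{a}" -- "{b}" [p_tost="{data["p_tost"]:.6g}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "edge_tsv":
        rows = [{"gene_a": a, "gene_b": b, "p_tost": d["p_tost"]}
                for a, b, d in sorted(graph.edges(data=True))]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "p_tost"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def write_selection(selection: ReferenceSelection, path: str | Path) -> None:
    """TSV selection report: one row per gene with its membership status."""
    genes = sorted(set().union(*map(set, selection.maximal_cliques))
                   ) if selection.maximal_cliques else []
    in_max = set().union(*(set(c) for c in selection.maximum_cliques)) \
        if selection.maximal_cliques else set()
    rows = []
    for gene in genes:
        rows.append({
            "gene": gene,
            "selected": gene in selection.selected,
            "in_maximum_clique": gene in in_max,
            "isolated": gene in selection.isolated,
        })
    df = pd.DataFrame(rows, columns=["gene", "selected",
                                     "in_maximum_clique", "isolated"])
    df.attrs["maximum_size"] = selection.maximum_size
    df.to_csv(path, sep="\t", index=False)
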