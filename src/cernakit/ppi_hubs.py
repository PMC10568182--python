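"""DEG-induced protein–protein interaction subnetwork and degree-ranked hubs.

Given an interaction edge list (e.g. a STRING export) and a region's DE
table, keep only edges whose two endpoints are both significant DEGs, then
rank nodes by plain (unweighted) degree and keep the top k (default 50).
Direction is carried from the DE table and rendered as the conventional
red (up) / blue (down) colour tag.
"""
from __future__ import annotations

import networkx as nx
import pandas as pd

from .diffexp import DETable


def induce_deg_subgraph(edges: pd.DataFrame, de: DETable, min_score: float | None = None) -> nx.Graph:
    """Subgraph induced by the region's significant DEGs.

    ``edges`` needs gene_a/gene_b columns and may carry an optional ``score``
    column (e.g. STRING combined score); ``min_score`` filters on it first.
    Self-loops are dropped; duplicate unordered pairs collapse.  Nodes carry
    ``direction`` and ``log2fc`` attributes from the DE table.
    """
    if min_score is not None:
        if "score" not in edges.columns:
            raise ValueError("min_score given but edge table has no 'score' column")
        edges = edges[edges["score"] >= min_score]
    sig = de.table[de.table["significant"]]
    info = {g: (d, l) for g, d, l in zip(sig["gene_id"], sig["direction"], sig["log2fc"])}
    g = nx.Graph()
    for a, b in zip(edges["gene_a"], edges["gene_b"]):
        if a == b or a not in info or b not in info:
            continue
        g.add_edge(a, b)
    for node in g.nodes:
        direction, lfc = info[node]
        g.nodes[node]["direction"] = direction
        g.nodes[node]["log2fc"] = float(lfc)
    return g


def select_hubs(graph: nx.Graph, k: int = 50) -> pd.DataFrame:
    """Top-k nodes by degree: gene_id, degree, direction, log2fc, color, rank.

    Ties broken by |log2fc| descending, then gene_id — invariant to edge
    input order and endpoint orientation.  Graphs with fewer than k nodes
    return everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = [
        {
            "gene_id": node,
            "degree": graph.degree(node),
            "direction": graph.nodes[node].get("direction", ""),
            "log2fc": graph.nodes[node].get("log2fc", float("nan")),
        }
        for node in graph.nodes
    ]
    out = pd.DataFrame(rows, columns=["gene_id", "degree", "direction", "log2fc"])
    if len(out):
        out["abs_lfc"] = out["log2fc"].abs()
        out = out.sort_values(
            ["degree", "abs_lfc", "gene_id"], ascending=[False, False, True], kind="mergesort"
        ).drop(columns="abs_lfc")
        out = out.head(k).reset_index(drop=True)
        out["color"] = out["direction"].map({"up": "red", "down": "blue"}).fillna("")
        out.insert(0, "rank", range(1, len(out) + 1))
    return out


def graph_tables(graph: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge table pair importable by graph viewers (e.g. Cytoscape)."""
    nodes = pd.DataFrame(
        [
            {
                "gene_id": n,
                "degree": graph.degree(n),
                "direction": graph.nodes[n].get("direction", ""),
                "log2fc": graph.nodes[n].get("log2fc", float("nan")),
            }
            for n in sorted(graph.nodes)
        ],
        columns=["gene_id", "degree", "direction", "log2fc"],
    )
    edges = pd.DataFrame(
        sorted(tuple(sorted(e)) for e in graph.edges), columns=["gene_a", "gene_b"]
    )
    return nodes, edges
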