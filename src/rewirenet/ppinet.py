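"""Protein–protein interaction networks: loading, centralities, hubs and
greedy-modularity communities.

Edge lists follow the STRING convention (protein1, protein2,
combined_score); scores on the 0–1000 integer scale are auto-detected and
rescaled to [0, 1].  Centralities and communities are computed on the
unweighted thresholded graph — scores are used only for filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .io import STRING_COLUMNS


def load_string_edges(
    path_or_frame: str | Path | pd.DataFrame,
    score_min: float = 0.9,
    node_whitelist: Iterable[str] | None = None,
) -> nx.Graph:
    """Build the high-confidence interaction graph from a STRING-style table.

    Scores greater than 1 anywhere in the file mark the 0–1000 scale and are
    divided by 1000.  Edges with score strictly greater than ``score_min``
    are kept; duplicate undirected pairs keep the maximum score; self-loops
    are dropped.  With a whitelist, the induced subgraph is returned.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        edges = path_or_frame.copy()
    else:
        edges = pd.read_csv(path_or_frame, sep="\t")
    missing = [c for c in STRING_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge table is missing columns: {missing}")
    edges["protein1"] = edges["protein1"].astype(str)
    edges["protein2"] = edges["protein2"].astype(str)
    score = edges["combined_score"].astype(float)
    if (score > 1.0).any():
        score = score / 1000.0
    graph = nx.Graph()
    for p1, p2, s in zip(edges["protein1"], edges["protein2"], score):
        if p1 == p2 or s <= score_min:
            continue
        if graph.has_edge(p1, p2):
            graph[p1][p2]["combined_score"] = max(graph[p1][p2]["combined_score"], s)
        else:
            graph.add_edge(p1, p2, combined_score=s)
    if node_whitelist is not None:
        graph = graph.subgraph([n for n in graph if n in set(node_whitelist)]).copy()
    if graph.number_of_edges() == 0:
        warnings.warn("no edge passes the score threshold", stacklevel=2)
    return graph


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree and normalised shortest-path betweenness per node."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    return pd.DataFrame(
        {
            "node": list(graph.nodes()),
            "degree": [degree[n] for n in graph.nodes()],
            "betweenness": [betweenness[n] for n in graph.nodes()],
        }
    )


def select_hubs(table: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Rank nodes by degree, then betweenness, then id; return the top k."""
    if table.empty:
        raise ValueError("centrality table is empty")
    if top_k > len(table):
        warnings.warn(f"top_k={top_k} exceeds {len(table)} nodes; returning all",
                      stacklevel=2)
        top_k = len(table)
    ranked = table.sort_values(
        by=["degree", "betweenness", "node"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return ranked.head(top_k)


@dataclass
class CommunityPartition:
    """Node → community labels plus the modularity of the partition."""

    labels: dict[str, int]
    modularity: float

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, set()).add(node)
        return [out[k] for k in sorted(out)]


def detect_communities(graph: nx.Graph) -> CommunityPartition:
    """Greedy modularity (Clauset–Newman–Moore) agglomeration.

    Communities are labelled 0..C−1 in decreasing size (ties by smallest
    member id).  An edgeless graph yields singleton communities with Q = 0
    by convention.
    """
    if graph.number_of_edges() == 0:
        labels = {n: i for i, n in enumerate(sorted(graph.nodes()))}
        return CommunityPartition(labels, 0.0)
    comms = list(nx.community.greedy_modularity_communities(graph))
    comms.sort(key=lambda c: (-len(c), min(c)))
    labels = {node: i for i, comm in enumerate(comms) for node in comm}
    q = nx.community.modularity(graph, comms)
    return CommunityPartition(labels, float(q))
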