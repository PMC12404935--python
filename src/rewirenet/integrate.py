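"""Multilayer network assembly, GraphML export and tissue Z-scores.

The multilayer network places one node per (gene, layer) membership across
five layers — shared DEGs, the co-expression module of interest, rewired
genes, and TF activity in each condition — and joins every pair of layers
that contain the same gene with an inter-layer edge.  Node scores carry the
layer's native statistic: log2 fold change (deg), module membership
correlation (module), rewiring score (rewired), and NES difference (the
two tf layers).

Tissue specificity is summarised per gene as a Z-score across tissues of
(optionally log2(TPM+1)-transformed) abundance, with hierarchical
clustering orders for heatmap-ready output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

LAYERS = ("deg", "module", "rewired", "tf_t2dm", "tf_htn")


def _as_scores(obj) -> dict[str, float]:
    """Coerce a layer argument to a gene → score mapping."""
    if obj is None:
        return {}
    if isinstance(obj, pd.Series):
        return {str(k): float(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        for col in ("log2fc", "kme", "rewiring_score", "delta_nes", "score"):
            if col in obj.columns:
                return {str(k): float(v) for k, v in obj[col].items()}
        raise ValueError(
            "cannot infer a score column from the DataFrame; pass a mapping"
        )
    if isinstance(obj, Mapping):
        return {str(k): float(v) for k, v in obj.items()}
    # iterable of genes without scores
    return {str(g): 0.0 for g in obj}


def build_multilayer(
    deg_genes=None,
    module_genes=None,
    rewired=None,
    tf_t2dm=None,
    tf_htn=None,
) -> nx.Graph:
    """Assemble the five-layer network with inter-layer gene edges.

    Each argument maps genes to that layer's score (Series, score-bearing
    DataFrame, mapping, or plain iterable for score 0).  At least one layer
    must be nonempty.
    """
    layer_scores = {
        "deg": _as_scores(deg_genes),
        "module": _as_scores(module_genes),
        "rewired": _as_scores(rewired),
        "tf_t2dm": _as_scores(tf_t2dm),
        "tf_htn": _as_scores(tf_htn),
    }
    if not any(layer_scores.values()):
        raise ValueError("all layers are empty")
    graph = nx.Graph()
    gene_layers: dict[str, list[str]] = {}
    for layer in LAYERS:
        for gene, score in sorted(layer_scores[layer].items()):
            graph.add_node((gene, layer), gene=gene, layer=layer,
                           score=float(score))
            gene_layers.setdefault(gene, []).append(layer)
    for gene, layers in gene_layers.items():
        for i in range(len(layers)):
            for j in range(i + 1, len(layers)):
                graph.add_edge((gene, layers[i]), (gene, layers[j]),
                               kind="inter_layer")
    return graph


def interlayer_edge_count(graph: nx.Graph) -> int:
    return sum(1 for _, _, d in graph.edges(data=True)
               if d.get("kind") == "inter_layer")


def export_graphml(network: nx.Graph, path: str | Path) -> None:
    """Write GraphML with deterministic node and edge order.

    Nodes are sorted by (layer, gene) and rewritten under string keys
    ``gene|layer``; two exports of the same network are byte-identical.
    """
    ordered = nx.Graph()
    nodes = sorted(network.nodes(data=True),
                   key=lambda nd: (nd[1].get("layer", ""), nd[1].get("gene", str(nd[0]))))
    for node, data in nodes:
        gene = data.get("gene", str(node))
        layer = data.get("layer", "")
        ordered.add_node(f"{gene}|{layer}", gene=gene, layer=layer,
                         score=float(data.get("score", 0.0)))

    def key_of(node, data):
        return f"{data.get('gene', str(node))}|{data.get('layer', '')}"

    edge_keys = sorted(
        (tuple(sorted((key_of(u, network.nodes[u]), key_of(v, network.nodes[v])))), d)
        for u, v, d in network.edges(data=True)
    )
    for (ku, kv), data in edge_keys:
        ordered.add_edge(ku, kv, kind=str(data.get("kind", "")))
    lines = nx.generate_graphml(ordered, named_key_ids=True)
    Path(path).write_text("\n".join(lines) + "\n")


def tissue_zscores(
    tpm: pd.DataFrame,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Per-gene Z-scores across tissues plus dendrogram leaf orders.

    Returns (Z matrix, gene order, tissue order).  Constant genes get an
    all-zero Z row; gene clustering uses correlation distance (undefined
    pairs set to the maximal distance), tissue clustering Euclidean
    distance on Z columns, both average linkage.
    """
    if tpm.shape[1] < 2:
        raise ValueError("tissue Z-scores need >= 2 tissues")
    if (tpm.to_numpy(dtype=float) < 0).any():
        raise ValueError("TPM values must be nonnegative")
    x = tpm.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=tpm.index, columns=tpm.columns)

    if zdf.shape[0] > 2:
        d = pdist(x, metric="correlation")
        d = np.where(np.isfinite(d), d, 2.0)
        gene_order = [tpm.index[i] for i in leaves_list(linkage(d, method="average"))]
    else:
        gene_order = list(tpm.index)
    if zdf.shape[1] > 2:
        d_t = pdist(z.T, metric="euclidean")
        tissue_order = [tpm.columns[i]
                        for i in leaves_list(linkage(d_t, method="average"))]
    else:
        tissue_order = list(tpm.columns)
    return zdf, gene_order, tissue_order
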