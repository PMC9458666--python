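"""Sample-graph construction, pruning and class fortification.

The raw graph has one node per training sample (named by its sample id,
"community" = its class) and one undirected edge per positive similarity,
weighted by that similarity (the *vectorial weight*). Two edge-space
transforms distill it into the frozen graph classifier model (GCM):

* **pruning** — keep an edge iff it ranks among the k strongest edges of at
  least one of its endpoints (union/either-endpoint kNN-graph semantics),
  with k chosen per training fold as ``min(k_max, least-class count)``;
* **fortification** — rescale each surviving weight by ``(1 + alpha)`` when
  its endpoints share a class and ``(1 - alpha)`` otherwise, injecting the
  supervision into the edge space. The graph may disconnect; no edge is ever
  deleted (alpha < 1 keeps weights positive).

Graphs are :class:`networkx.Graph` objects with a ``stage`` graph attribute
in {"raw", "pruned", "GCM"}; nodes carry ``community`` and
``weighted_degree`` (the sum of incident fortified weights, recomputed after
every stage), edges carry ``vectorial_weight`` and ``fortified_weight``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .similarity import AdjacencyMatrix

__all__ = [
    "PruningPolicy",
    "build_raw_graph",
    "weighted_degree",
    "choose_k",
    "prune_edges",
    "fortify_edges",
    "gcm_to_graphml",
    "gcm_to_edgelist",
]

RAW, PRUNED, GCM = "raw", "pruned", "GCM"


@dataclass(frozen=True)
class PruningPolicy:
    """Upper limit ``k_max`` and the per-fold effective neighbour count."""

    k_max: int
    k_effective: int

    def __post_init__(self) -> None:
        if not 1 <= self.k_effective <= self.k_max:
            raise ValueError("need 1 <= k_effective <= k_max")


def _recompute_degrees(g: nx.Graph) -> None:
    for node in g.nodes:
        g.nodes[node]["weighted_degree"] = float(
            sum(d["fortified_weight"] for _, _, d in g.edges(node, data=True))
        )


def build_raw_graph(
    A: AdjacencyMatrix, classes: Sequence, ids: Sequence[str] | None = None
) -> nx.Graph:
    """Undirected weighted graph from the adjacency matrix.

    Every training sample becomes a named node whose community is its class;
    every strictly positive similarity becomes an edge whose vectorial
    weight is that similarity (initially the fortified weight too).
    """
    ids = tuple(ids) if ids is not None else A.sample_ids
    if len(ids) != len(A.sample_ids) or len(set(ids)) != len(ids):
        raise ValueError("ids must be unique and aligned with the adjacency matrix")
    if len(classes) != len(ids):
        raise ValueError("one class token per sample required")
    g = nx.Graph(stage=RAW, max_train_distance=A.max_train_distance)
    for node, cls in zip(ids, classes):
        g.add_node(node, community=cls)
    relabel = dict(zip(A.sample_ids, ids))
    for u, v, s in A.edges():
        g.add_edge(relabel[u], relabel[v], vectorial_weight=s, fortified_weight=s)
    if g.number_of_edges() == 0:
        raise ValueError("degenerate similarity structure: empty edge set")
    _recompute_degrees(g)
    return g


def weighted_degree(g: nx.Graph, node: str) -> float:
    """Sum of incident edge weights at the graph's current stage."""
    if node not in g:
        raise KeyError(f"unknown node {node!r}")
    return g.nodes[node]["weighted_degree"]


def choose_k(class_counts: Mapping, k_max: int = 10) -> int:
    """Effective k = min(k_max, size of the least-represented class), >= 1."""
    if not class_counts:
        raise ValueError("empty class counts")
    if k_max < 1:
        raise ValueError("k_max must be positive")
    return max(1, min(k_max, min(class_counts.values())))


def _top_k_pairs(g: nx.Graph, node: str, k: int) -> set[frozenset]:
    # strongest first; weight ties broken by lexicographic neighbour id
    nbrs = sorted(
        g[node].items(), key=lambda kv: (-kv[1]["vectorial_weight"], str(kv[0]))
    )
    return {frozenset((node, v)) for v, _ in nbrs[:k]}


def prune_edges(g: nx.Graph, policy: PruningPolicy) -> nx.Graph:
    """Keep an edge iff it is within the top-k of at least one endpoint.

    A node may end up with more than k edges (edges kept on behalf of a
    neighbour) or with none of its own wishes denied — every node always
    retains at least min(k, degree) of its own strongest edges.
    """
    k = policy.k_effective
    survivors: set[frozenset] = set()
    for node in g.nodes:
        survivors |= _top_k_pairs(g, node, k)
    pruned = nx.Graph(stage=PRUNED, max_train_distance=g.graph.get("max_train_distance"))
    pruned.add_nodes_from((n, {"community": g.nodes[n]["community"]}) for n in g.nodes)
    for pair in survivors:
        u, v = tuple(pair)
        pruned.add_edge(u, v, **g.edges[u, v])
    _recompute_degrees(pruned)
    return pruned


def fortify_edges(g: nx.Graph, alpha: float = 0.5) -> nx.Graph:
    """Reward same-class edges and penalize cross-class edges by (1 +/- alpha).

    The edge set and node set are unchanged; the result is the GCM.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    gcm = g.copy()
    gcm.graph["stage"] = GCM
    gcm.graph["alpha"] = alpha
    for u, v, d in gcm.edges(data=True):
        same = gcm.nodes[u]["community"] == gcm.nodes[v]["community"]
        factor = (1.0 + alpha) if same else (1.0 - alpha)
        d["fortified_weight"] = d["vectorial_weight"] * factor
    _recompute_degrees(gcm)
    return gcm


def gcm_to_graphml(g: nx.Graph, path: str | Path) -> None:
    """Serialize the graph with all node/edge attributes to GraphML."""
    out = g.copy()
    for node in out.nodes:
        out.nodes[node]["name"] = str(node)
        out.nodes[node]["community"] = str(out.nodes[node]["community"])
    nx.write_graphml(out, str(path))


def gcm_to_edgelist(g: nx.Graph) -> pd.DataFrame:
    """Edge table (source, target, vectorial_weight, fortified_weight)."""
    rows = [
        {
            "source": str(u),
            "target": str(v),
            "vectorial_weight": d["vectorial_weight"],
            "fortified_weight": d["fortified_weight"],
        }
        for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "vectorial_weight", "fortified_weight"])
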