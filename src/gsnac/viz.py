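"""Explainability exports: decorated GCM, per-prediction views, comparison
matrix.

Serialized artifacts (GraphML, CSV, JSON) are the contract; raster rendering
via matplotlib is optional sugar. Every export is a pure function of its
inputs plus the layout seed, so re-export is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .evaluate import BenchmarkReport
from .predict import PredictionTrace, trace_to_dict

__all__ = [
    "GraphView",
    "layout_graph",
    "export_gcm",
    "export_prediction_view",
    "export_comparison_matrix",
]


@dataclass(frozen=True)
class GraphView:
    """Display geometry for a sample graph.

    Node sizes are affine in weighted degree (more connected, bigger);
    colors index the lexicographic class order; edge widths are affine in
    the current-stage edge weight.
    """

    coords: dict          # node -> (x, y)
    sizes: dict           # node -> display size
    color_index: dict     # node -> community color index
    edge_widths: dict     # frozenset pair -> display width
    seed: int


def _affine(values: dict, lo: float, hi: float) -> dict:
    vals = np.array(list(values.values()), dtype=float)
    vmin, vmax = (vals.min(), vals.max()) if vals.size else (0.0, 0.0)
    if vmax == vmin:
        mid = (lo + hi) / 2.0
        return {k: mid for k in values}
    scale = (hi - lo) / (vmax - vmin)
    return {k: lo + (v - vmin) * scale for k, v in values.items()}


def layout_graph(
    g: nx.Graph,
    seed: int = 0,
    size_range: tuple[float, float] = (100.0, 600.0),
    width_range: tuple[float, float] = (0.5, 4.0),
) -> GraphView:
    """Deterministic force-directed layout with degree-scaled node sizes."""
    if g.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty graph")
    pos = nx.spring_layout(g, seed=seed, weight="fortified_weight")
    coords = {n: (float(x), float(y)) for n, (x, y) in pos.items()}
    sizes = _affine({n: g.nodes[n]["weighted_degree"] for n in g.nodes}, *size_range)
    classes = sorted({g.nodes[n]["community"] for n in g.nodes}, key=str)
    cindex = {c: i for i, c in enumerate(classes)}
    color_index = {n: cindex[g.nodes[n]["community"]] for n in g.nodes}
    widths = _affine(
        {frozenset((u, v)): d["fortified_weight"] for u, v, d in g.edges(data=True)},
        *width_range,
    )
    return GraphView(coords=coords, sizes=sizes, color_index=color_index,
                     edge_widths=widths, seed=seed)


def export_gcm(g: nx.Graph, view: GraphView, path: str | Path, render: bool = False):
    """Write the decorated graph to GraphML (+ optional PNG next to it).

    Node attributes: name, community, weighted_degree (plus layout x/y and
    display size/color); edge attributes: vectorial_weight, fortified_weight.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot export an empty graph")
    path = Path(path)
    out = g.copy()
    for n in out.nodes:
        x, y = view.coords[n]
        out.nodes[n].update(
            name=str(n),
            community=str(out.nodes[n]["community"]),
            x=x,
            y=y,
            size=view.sizes[n],
            color=view.color_index[n],
        )
    nx.write_graphml(out, str(path))
    written = [path]
    if render:
        png = path.with_suffix(".png")
        _render_graph(g, view, png)
        written.append(png)
    return written


def _render_graph(g: nx.Graph, view: GraphView, path: Path, highlight=None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx(
        g,
        pos={n: view.coords[n] for n in g.nodes},
        node_size=[view.sizes[n] for n in g.nodes],
        node_color=[view.color_index[n] for n in g.nodes],
        width=[view.edge_widths[frozenset((u, v))] for u, v in g.edges],
        cmap="tab10",
        ax=ax,
        font_size=6,
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def export_prediction_view(
    trace: PredictionTrace, gcm: nx.Graph, view: GraphView, path: str | Path
):
    """Serialize one prediction: the test node, its contributing GCM nodes,
    annotated edges, and the predicted community."""
    if trace is None:
        raise ValueError("missing prediction trace")
    doc = trace_to_dict(trace)
    doc["contributing_edges"] = [
        {
            "source": doc["test_id"],
            "target": str(node),
            "similarity": val,
            "target_community": str(gcm.nodes[node]["community"]),
            "target_coords": list(view.coords[node]),
        }
        for cls in doc["classes"].values()
        for node, val in cls["contributors"]
    ]
    doc["layout_seed"] = view.seed
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return [path]


def export_comparison_matrix(report: BenchmarkReport, path: str | Path,
                             render: bool = False):
    """Samples x classifiers correctness grid as CSV (+ optional raster)."""
    path = Path(path)
    grid = report.correctness.astype(int)
    grid.to_csv(path, index_label="sample_id")
    written = [path]
    if render:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 8))
        ax.imshow(grid.to_numpy(), aspect="auto", cmap="bwr_r", vmin=0, vmax=1)
        ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90, fontsize=6)
        ax.set_yticks([])
        ax.set_xlabel("classifier")
        ax.set_ylabel("sample")
        png = path.with_suffix(".png")
        fig.savefig(png, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(png)
    return written
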