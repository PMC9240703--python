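"""Relational network graphs: construction, isolated-network detection, export.

A derivation table maps onto a directed multigraph — stimuli as vertices, one
edge per unique relational statement, coloured by derivation level (Blue =
trained, Purple = mutually entailed, Orange = combinatorially derived).
Mutual-entailment pairs already encode both directions, so connectivity and
default rendering treat the graph as undirected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import networkx as nx
import pandas as pd

from .closure import DerivationTable, dedup_relations

__all__ = [
    "build_graph",
    "connected_components",
    "export_graph",
    "render_plot",
    "EXPORT_FORMATS",
]

EXPORT_FORMATS = ("graphml", "dot", "edge-csv")

_MPL_COLORS = {"Blue": "tab:blue", "Purple": "purple", "Orange": "orange"}


def build_graph(table: DerivationTable) -> nx.MultiDiGraph:
    """Build the relational multigraph: one directed edge per unique relation.

    Duplicate Relation rows (possible in externally loaded tables) are dropped
    first; parallel edges between the same vertex pair — e.g. ``i < k`` next to
    ``i ku k`` — are preserved.
    """
    if not table.records:
        raise ValueError("cannot build a graph from an empty table")
    graph = nx.MultiDiGraph()
    for record in dedup_relations(table).records:
        s = record.statement
        graph.add_node(s.left)
        graph.add_node(s.right)
        graph.add_edge(
            s.left,
            s.right,
            relation=s.render(),
            operator=s.op.value,
            level=record.level.value,
            color=record.color,
        )
    return graph


def connected_components(graph: nx.MultiDiGraph) -> list[set[str]]:
    """Isolated networks: maximal vertex sets connected by edges of any
    direction or colour, ordered deterministically by smallest member."""
    components = [set(c) for c in nx.connected_components(graph.to_undirected())]
    return sorted(components, key=lambda c: min(c))


def _write_dot(graph: nx.MultiDiGraph, path: Path) -> None:
    # hand-rolled Graphviz emitter: the networkx DOT writers need pydot/pygraphviz
    lines = ["digraph relational_network {"]
    for node in sorted(graph.nodes):
        lines.append(f'    "{node}";')
    for u, v, data in graph.edges(data=True):
        lines.append(
            f'    "{u}" -> "{v}" [label="{data["relation"]}", '
            f'color={data["color"].lower()}];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def export_graph(
    graph: nx.MultiDiGraph, fmt: str, path: Union[str, Path]
) -> None:
    """Export as ``graphml`` (full attributes), ``dot`` (Graphviz, colour-mapped
    edges with relation labels) or ``edge-csv`` (write_table schema minus
    Derived_from)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "dot":
        _write_dot(graph, path)
    elif fmt == "edge-csv":
        rows = [
            {
                "From": u,
                "To": v,
                "Operator": data["operator"],
                "Derivation_Level": data["level"],
                "Relation": data["relation"],
                "Edge_color": data["color"],
            }
            for u, v, data in graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(
            f"unknown export format {fmt!r}; expected one of {EXPORT_FORMATS}"
        )


def layout_positions(graph: nx.MultiDiGraph, seed: int = 0) -> dict:
    """Seeded force-directed vertex positions (reproducible for a fixed seed)."""
    return nx.spring_layout(graph.to_undirected(as_view=False), seed=seed)


def render_plot(
    graph: nx.MultiDiGraph,
    path: Union[str, Path],
    seed: int = 0,
    combinatorial_labels: bool = True,
) -> None:
    """Render a static image: labelled vertices, edges coloured by derivation
    level, relation strings as edge labels.

    ``combinatorial_labels=False`` suppresses labels on combinatorially derived
    edges, which keeps dense networks readable.  The layout is force-directed
    and seeded, so the same seed gives identical coordinates.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = layout_positions(graph, seed=seed)
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx_nodes(graph, pos, ax=ax, node_size=600, node_color="white",
                           edgecolors="black")
    nx.draw_networkx_labels(graph, pos, ax=ax)
    # parallel edges get increasing arc radii so they stay distinguishable
    arc_index: dict[tuple[str, str], int] = {}
    for u, v, data in graph.edges(data=True):
        pair = tuple(sorted((u, v)))
        rad = 0.08 * arc_index.get(pair, 0)
        arc_index[pair] = arc_index.get(pair, 0) + 1
        nx.draw_networkx_edges(
            graph,
            pos,
            edgelist=[(u, v)],
            ax=ax,
            edge_color=_MPL_COLORS[data["color"]],
            connectionstyle=f"arc3,rad={rad}",
            arrows=True,
        )
        if combinatorial_labels or data["color"] != "Orange":
            mid_x = (pos[u][0] + pos[v][0]) / 2
            mid_y = (pos[u][1] + pos[v][1]) / 2 + rad
            ax.text(mid_x, mid_y, data["relation"], fontsize=7,
                    ha="center", va="center")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
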