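"""Serialize, export and plot rewired networks.

Formats
-------
* **edge list** — canonical TSV, one row per stored edge (self-loops
  included), header ``gene_a gene_b category weight n_contributing
  mediating_pairs``, sorted by gene pair, weights printed with 6 decimals.
* **pickled graph** — a :mod:`networkx` Graph with full edge attributes and
  run metadata in the graph attributes; lossless round trip.
* **Gephi edge table** — TSV with ``Source Target Type Weight category
  color``; ``Weight`` is the absolute value because negative weights break
  force-directed layouts — the direction of the change stays in the
  ``category`` column.
* **GML** — node blocks (id, label) and edge blocks (weight, category,
  color) for Cytoscape.

Self-loop exclusion is a *view* concern: the stored network always keeps
self-loops; Gephi/GML export and plotting drop them unless
``include_self_loops`` is set on the style.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402

from .exceptions import SplitpeaError  # noqa: E402
from .rewire import RewiredEdge, RewiredNetwork  # noqa: E402

logger = logging.getLogger("splitpea")

LARGE_NETWORK_NODES = 50

EDGE_LIST_HEADER = ["gene_a", "gene_b", "category", "weight",
                    "n_contributing", "mediating_pairs"]
GEPHI_HEADER = ["Source", "Target", "Type", "Weight", "category", "color"]

# Okabe–Ito colorblind-safe triple
DEFAULT_COLORS = {"gain": "#0072B2", "loss": "#D55E00", "chaos": "#999999"}


@dataclass
class ExportStyle:
    """Category colors, node sizing and self-loop policy for exports/plots."""

    colors: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLORS))
    node_size_per_degree: float = 120.0
    include_self_loops: bool = False

    def __post_init__(self) -> None:
        for cat in ("gain", "loss", "chaos"):
            color = self.colors.get(cat, "")
            if not (color.startswith("#") and len(color) == 7):
                raise ValueError(f"style: {cat} needs a #rrggbb color, got {color!r}")


def _view_edges(net: RewiredNetwork, style: ExportStyle) -> list[RewiredEdge]:
    edges = [net.edges[k] for k in sorted(net.edges)]
    if not style.include_self_loops:
        edges = [e for e in edges if not e.is_self_loop]
    return edges


# ---------------------------------------------------------------------------
# Canonical edge list TSV
# ---------------------------------------------------------------------------

def _format_pairs(pairs: tuple[tuple[str, str], ...]) -> str:
    return ",".join(f"{a}:{b}" for a, b in pairs)


def _parse_pairs(text: str) -> tuple[tuple[str, str], ...]:
    if not text:
        return ()
    out = []
    for token in text.split(","):
        a, b = token.split(":")
        out.append((a, b))
    return tuple(out)


def write_edge_list(net: RewiredNetwork, path: str | Path) -> None:
    """Write the canonical TSV edge list (all stored edges, self-loops kept)."""
    path = Path(path)
    if len(net) == 0:
        logger.warning("write_edge_list: empty network -> header-only file")
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(EDGE_LIST_HEADER) + "\n")
            for key in sorted(net.edges):
                e = net.edges[key]
                fh.write("\t".join([
                    e.gene_a, e.gene_b, e.category, f"{e.weight:.6f}",
                    str(e.n_contributing), _format_pairs(e.mediating_pairs),
                ]) + "\n")
    except OSError as exc:
        raise SplitpeaError(f"cannot write edge list to {path}: {exc}") from exc


def read_edge_list(path: str | Path) -> RewiredNetwork:
    """Read back a canonical edge-list TSV.

    Per-edge contributing ΔPSI details are not stored in the TSV; the
    reloaded edges carry category, weight, mediating pairs and the
    contribution count, which is all the analysis functions use.
    """
    path = Path(path)
    if not path.exists():
        raise SplitpeaError(f"edge list not found: {path}")
    net = RewiredNetwork(metadata={"loaded_from": str(path)})
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != EDGE_LIST_HEADER:
            raise SplitpeaError(f"{path}: unexpected edge-list header {header}")
        for line in fh:
            a, b, cat, w, n, pairs = line.rstrip("\n").split("\t")
            net.add(RewiredEdge(gene_a=a, gene_b=b, category=cat,  # type: ignore[arg-type]
                                weight=float(w), mediating_pairs=_parse_pairs(pairs),
                                n_contributing=int(n)))
    return net


# ---------------------------------------------------------------------------
# networkx bridge + pickle serialization
# ---------------------------------------------------------------------------

def to_networkx(net: RewiredNetwork) -> nx.Graph:
    """Full-fidelity networkx Graph (edge attributes + graph metadata)."""
    g = nx.Graph()
    g.graph["metadata"] = dict(net.metadata)
    g.graph["report"] = dict(net.report)
    g.add_nodes_from(sorted(net.nodes))
    for e in net.edges.values():
        g.add_edge(e.gene_a, e.gene_b, category=e.category, weight=e.weight,
                   mediating_pairs=list(e.mediating_pairs),
                   contributing_deltas=list(e.contributing_deltas),
                   n_contributing=e.n_contributing)
    return g


def from_networkx(g: nx.Graph) -> RewiredNetwork:
    net = RewiredNetwork(metadata=dict(g.graph.get("metadata", {})),
                         report=dict(g.graph.get("report", {})))
    for a, b, attrs in g.edges(data=True):
        net.add(RewiredEdge(
            gene_a=min(a, b), gene_b=max(a, b),
            category=attrs["category"], weight=attrs["weight"],
            mediating_pairs=tuple(tuple(p) for p in attrs.get("mediating_pairs", ())),
            contributing_deltas=tuple(tuple(c) for c in attrs.get("contributing_deltas", ())),
            n_contributing=attrs.get("n_contributing", 0)))
    return net


def serialize_graph(net: RewiredNetwork, path: str | Path) -> None:
    """Pickle the networkx representation (lossless)."""
    with open(path, "wb") as fh:
        pickle.dump(to_networkx(net), fh)


def load_graph(path: str | Path) -> RewiredNetwork:
    """Load a pickled rewired network; corrupt files raise a clean error."""
    path = Path(path)
    if not path.exists():
        raise SplitpeaError(f"graph file not found: {path}")
    try:
        with open(path, "rb") as fh:
            g = pickle.load(fh)
    except Exception as exc:
        raise SplitpeaError(f"{path} is not a readable pickled graph: {exc}") from exc
    if not isinstance(g, nx.Graph):
        raise SplitpeaError(f"{path} does not contain a networkx graph")
    return from_networkx(g)


# ---------------------------------------------------------------------------
# Gephi / GML
# ---------------------------------------------------------------------------

def export_gephi(net: RewiredNetwork, path: str | Path,
                 style: ExportStyle | None = None) -> None:
    """Write a Gephi-importable edge table (TSV)."""
    style = style or ExportStyle()
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(GEPHI_HEADER) + "\n")
            for e in _view_edges(net, style):
                fh.write("\t".join([
                    e.gene_a, e.gene_b, "Undirected", f"{abs(e.weight):.6f}",
                    e.category, style.colors[e.category],
                ]) + "\n")
    except OSError as exc:
        raise SplitpeaError(f"cannot write Gephi table to {path}: {exc}") from exc


def export_gml(net: RewiredNetwork, path: str | Path,
               style: ExportStyle | None = None) -> None:
    """Write GML (Cytoscape-compatible): node id/label, edge weight/category/color."""
    style = style or ExportStyle()
    edges = _view_edges(net, style)
    g = nx.Graph()
    nodes = sorted({n for e in edges for n in e.pair} | net.nodes)
    for n in nodes:
        g.add_node(n, label=str(n))
    for e in edges:
        g.add_edge(e.gene_a, e.gene_b, weight=float(e.weight), category=e.category,
                   color=style.colors[e.category])
    nx.write_gml(g, str(path))


def read_gml_edges(path: str | Path) -> set[tuple[str, str, str, float]]:
    """Re-parse a GML export into {(gene_a, gene_b, category, weight)}."""
    g = nx.read_gml(str(path))
    return {(min(a, b), max(a, b), d["category"], d["weight"])
            for a, b, d in g.edges(data=True)}


def read_gephi_edges(path: str | Path) -> set[tuple[str, str, str, float]]:
    """Re-parse a Gephi edge table into {(gene_a, gene_b, category, |weight|)}."""
    out = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GEPHI_HEADER:
            raise SplitpeaError(f"{path}: unexpected Gephi header {header}")
        for line in fh:
            a, b, _type, w, cat, _color = line.rstrip("\n").split("\t")
            out.add((min(a, b), max(a, b), cat, float(w)))
    return out


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_network(net: RewiredNetwork, path: str | Path,
                 style: ExportStyle | None = None, seed: int = 42,
                 figsize: tuple[float, float] = (8.0, 8.0)) -> dict[str, tuple[float, float]]:
    """Spring-layout plot with category-colored edges and node labels.

    Self-loops are dropped unless the style retains them.  Networks with
    more than 50 nodes trigger a warning recommending Gephi/Cytoscape
    export (the plot is still produced).  Returns the node positions of
    the layout, which are deterministic for a given seed.
    """
    style = style or ExportStyle()
    edges = _view_edges(net, style)
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    for e in edges:
        g.add_edge(e.gene_a, e.gene_b, category=e.category)
    if g.number_of_nodes() > LARGE_NETWORK_NODES:
        logger.warning(
            "plot_network: %d nodes (> %d); consider the Gephi or GML export "
            "for large networks", g.number_of_nodes(), LARGE_NETWORK_NODES)
    pos = nx.spring_layout(g, seed=seed)
    fig, ax = plt.subplots(figsize=figsize)
    degrees = dict(g.degree())
    nx.draw_networkx_nodes(
        g, pos, ax=ax, node_color="#e8e8e8", edgecolors="#555555",
        node_size=[200 + style.node_size_per_degree * degrees[n] for n in g.nodes()])
    for cat, color in style.colors.items():
        cat_edges = [(a, b) for a, b, d in g.edges(data=True) if d["category"] == cat]
        if cat_edges:
            nx.draw_networkx_edges(g, pos, edgelist=cat_edges, edge_color=color,
                                   ax=ax, width=1.8)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}
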