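"""GO-term co-occurrence network construction.

The co-occurrence score of a pair of GO terms is the number of genes
annotated with both terms. Each term selects its top-k (default 3)
co-occurrence targets as directed edges; the drawn graph is the undirected
union of those selections. Terms with exactly one distinct co-occurrence
partner are split off into a secondary "singleton" graph for readability,
and nodes are coloured on a red-white-blue scale by their expression score
(white at score 1, saturating red at >= 4, blue at <= 0.25, on a log2
scale).
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression import FoldChangeTable
from .go_scoring import GoAnnotation

log = logging.getLogger(__name__)

GREY = (190, 190, 190)


def count_cooccurrence(ann: GoAnnotation, universe: str = "all",
                       fc: FoldChangeTable | pd.Series | None = None,
                       ) -> dict[tuple[str, str], int]:
    """Count genes shared by every pair of GO terms.

    Keys are unordered pairs stored as sorted tuples; zero-count pairs are
    absent. ``universe`` selects which genes are counted: ``all`` annotated
    genes (default) or only the ``measured`` genes present in ``fc``.
    """
    if ann.n_terms == 0:
        raise ConfigError("empty annotation")
    if universe == "all":
        genes: Iterable[str] = ann.gene_ids
    elif universe == "measured":
        if fc is None:
            raise ConfigError("universe='measured' requires a fold-change "
                              "table")
        values = fc.fold_change if isinstance(fc, FoldChangeTable) else fc
        genes = [g for g in ann.gene_ids if g in values.index]
    else:
        raise ConfigError(f"unknown co-occurrence universe: {universe!r}")
    counts: Counter[tuple[str, str]] = Counter()
    for gene in genes:
        for pair in itertools.combinations(sorted(ann.terms(gene)), 2):
            counts[pair] += 1
    return dict(counts)


def select_top_targets(counts: Mapping[tuple[str, str], int],
                       k: int = 3) -> list[tuple[str, str, int]]:
    """Select each term's k highest-count co-occurrence targets.

    Ties are broken by descending count then ascending target identifier,
    making the edge list deterministic. Terms with no nonzero pair are
    absent. Returns directed (source, target, count) triples.
    """
    if k < 1:
        raise ConfigError(f"top-k must be >= 1, got {k}")
    partners: dict[str, list[tuple[str, int]]] = {}
    for (a, b), n in counts.items():
        if n <= 0:
            continue
        partners.setdefault(a, []).append((b, n))
        partners.setdefault(b, []).append((a, n))
    edges = []
    for term in sorted(partners):
        ranked = sorted(partners[term], key=lambda pn: (-pn[1], pn[0]))
        edges.extend((term, p, n) for p, n in ranked[:k])
    return edges


@dataclass
class NetworkGraph:
    """GO-term network: directed top-k selection edges plus node metadata.

    Node attributes: ``n_partners`` (distinct nonzero co-occurrence
    partners), ``aspect``, ``name``, ``partition`` (main/singleton),
    and after colouring ``score`` and ``color`` (hex). ``drawing`` is the
    undirected union of the selection edges (no self-loops, no
    duplicates), the graph that is actually laid out and drawn.
    """

    selection: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.selection.nodes)

    @property
    def drawing(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, **self.selection.nodes[node])
        for u, v, data in sorted(self.selection.edges(data=True)):
            if u != v and not g.has_edge(u, v):
                g.add_edge(u, v, weight=data["weight"])
        return g

    def edge_frame(self) -> pd.DataFrame:
        rows = sorted((u, v, d["weight"])
                      for u, v, d in self.selection.edges(data=True))
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


def build_network(ann: GoAnnotation,
                  counts: Mapping[tuple[str, str], int] | None = None,
                  scores: pd.DataFrame | None = None, k: int = 3,
                  aspect: str | None = None,
                  universe: str = "all",
                  fc: FoldChangeTable | pd.Series | None = None,
                  saturation: tuple[float, float] = (0.25, 4.0),
                  ) -> NetworkGraph:
    """Assemble the co-occurrence network for one aspect (or all).

    Counts are computed from the (optionally aspect-restricted) annotation
    unless given explicitly; nodes carry partner counts, aspect labels and
    score-based colours.
    """
    sub = ann.subset_aspect(aspect) if aspect else ann
    if counts is None:
        counts = count_cooccurrence(sub, universe=universe, fc=fc)
    edges = select_top_targets(counts, k=k)
    n_partners: Counter[str] = Counter()
    for (a, b), n in counts.items():
        if n > 0:
            n_partners[a] += 1
            n_partners[b] += 1
    g = nx.DiGraph()
    for term in sorted(n_partners):
        attrs = {"n_partners": int(n_partners[term]), "partition": "main"}
        if term in sub:
            attrs["aspect"] = sub.aspect(term)
            attrs["name"] = sub.name(term)
        g.add_node(term, **attrs)
    for src, tgt, n in edges:
        g.add_edge(src, tgt, weight=int(n))
    net = NetworkGraph(selection=g)
    if scores is not None:
        color_nodes(scores, net, lo=saturation[0], hi=saturation[1])
    return net


def split_singletons(net: NetworkGraph,
                     aspects: Sequence[str] | None = ("BP",),
                     ) -> tuple[NetworkGraph, NetworkGraph]:
    """Partition the network into a main graph and a singleton graph.

    A node is a singleton when its number of distinct co-occurrence
    partners is exactly 1. Singletons (restricted to ``aspects``; None
    applies the rule to every aspect) move with their incident edges to
    the secondary graph; their partners remain in the main graph and
    appear in the singleton graph only as anchor endpoints (tagged
    ``anchor=True``), so the main/singleton node partition is disjoint
    with union equal to the input node set.
    """
    sel = net.selection
    def eligible(node: str) -> bool:
        if aspects is None:
            return True
        return sel.nodes[node].get("aspect", "BP") in set(aspects)

    singles = {n for n in sel.nodes
               if sel.nodes[n].get("n_partners", 0) == 1 and eligible(n)}
    main_nodes = set(sel.nodes) - singles
    main = nx.DiGraph()
    for node in sorted(main_nodes):
        main.add_node(node, **{**sel.nodes[node], "partition": "main"})
    for u, v, d in sorted(sel.edges(data=True)):
        if u in main_nodes and v in main_nodes:
            main.add_edge(u, v, **d)
    single = nx.DiGraph()
    for node in sorted(singles):
        single.add_node(node, **{**sel.nodes[node], "partition": "singleton"})
    for u, v, d in sorted(sel.edges(data=True)):
        if u in singles or v in singles:
            for end in (u, v):
                if end not in single:
                    single.add_node(end, **{**sel.nodes[end],
                                            "partition": "main",
                                            "anchor": True})
            single.add_edge(u, v, **d)
    return NetworkGraph(selection=main), NetworkGraph(selection=single)


def singleton_members(net: NetworkGraph) -> list[str]:
    """Nodes of a split-off graph that are true singletons (not anchors)."""
    return [n for n in net.nodes
            if net.selection.nodes[n].get("partition") == "singleton"]


def score_to_rgb(score: float, lo: float = 0.25,
                 hi: float = 4.0) -> tuple[int, int, int]:
    """Map an expression score to a red-white-blue RGB triple.

    Linear interpolation in log2(score): white at 1, saturating pure red
    at >= ``hi`` and pure blue at <= ``lo``.
    """
    if not score > 0:
        raise ConfigError(f"expression score must be positive, got {score}")
    if not (0 < lo < 1 < hi):
        raise ConfigError("saturation points must satisfy lo < 1 < hi")
    x = np.log2(score)
    if x >= 0:
        t = min(x / np.log2(hi), 1.0)
        other = round(255 * (1 - t))
        return (255, int(other), int(other))
    t = min(x / np.log2(lo), 1.0)
    other = round(255 * (1 - t))
    return (int(other), int(other), 255)


def rgb_to_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def color_nodes(scores: pd.DataFrame, net: NetworkGraph, lo: float = 0.25,
                hi: float = 4.0) -> NetworkGraph:
    """Colour network nodes by expression score (in place; also returned).

    Terms absent from the score table are painted neutral grey.
    """
    lookup = scores["score"].to_dict()
    for node in net.selection.nodes:
        score = lookup.get(node)
        if score is None:
            rgb = GREY
        else:
            rgb = score_to_rgb(float(score), lo=lo, hi=hi)
            net.selection.nodes[node]["score"] = float(score)
        net.selection.nodes[node]["color"] = rgb_to_hex(rgb)
    return net


def layout_positions(net: NetworkGraph,
                     seed: int = 0) -> dict[str, tuple[float, float]]:
    """Deterministic Fruchterman-Reingold layout of the drawing graph."""
    pos = nx.spring_layout(net.drawing, seed=seed)
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}


def export_graph(net: NetworkGraph, outdir: str | Path, prefix: str = "network",
                 layout_seed: int = 0, image: bool = False) -> dict[str, Path]:
    """Write the network as GraphML + edge-list TSV (+ optional PNG).

    The GraphML carries node score/colour/aspect/partition attributes and
    the seeded layout coordinates; identical seeds give identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drawing = net.drawing
    pos = layout_positions(net, seed=layout_seed) if len(drawing) else {}
    for node, (x, y) in pos.items():
        drawing.nodes[node]["x"] = x
        drawing.nodes[node]["y"] = y
    graphml = outdir / f"{prefix}.graphml"
    nx.write_graphml(drawing, graphml)
    edges = outdir / f"{prefix}_edges.tsv"
    net.edge_frame().to_csv(edges, sep="\t", index=False)
    paths = {"graphml": graphml, "edges": edges}
    if image and len(drawing):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 8))
        colors = [drawing.nodes[n].get("color", rgb_to_hex(GREY))
                  for n in drawing.nodes]
        nx.draw_networkx(drawing, pos=pos, ax=ax, node_color=colors,
                         node_size=120, font_size=5, edge_color="0.7")
        ax.set_axis_off()
        png = outdir / f"{prefix}.png"
        fig.savefig(png, dpi=150)
        plt.close(fig)
        paths["image"] = png
    return paths
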