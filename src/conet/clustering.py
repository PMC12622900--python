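"""Sample clustering and plot-data preparation.

Samples (whole arrays) are compared by Euclidean distance in gene space
and clustered agglomeratively with Ward's minimum-variance criterion, in
its squared-distance (``ward.D2``) form: the Lance-Williams recurrence

    d(k, i u j)^2 = [(n_i+n_k) d(k,i)^2 + (n_j+n_k) d(k,j)^2
                     - n_k d(i,j)^2] / (n_i+n_j+n_k)

is applied to squared Euclidean distances, at each step merging the pair
at minimal current distance; recorded heights are on the original
(unsquared) scale. Merge ties are broken by the smallest pair of cluster
indices so the dendrogram is deterministic. Scatter- and volcano-plot
coordinate tables, with GO-term gene highlighting, are prepared here too.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError, FormatError
from .expression import ExpressionMatrix, FoldChangeTable, fold_change
from .go_scoring import GoAnnotation

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ConfigError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, rtol=0, atol=0):
            raise ConfigError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ConfigError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ConfigError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)


def sample_distances(matrix: ExpressionMatrix | pd.DataFrame,
                     log2: bool = False) -> DistanceMatrix:
    """Euclidean distances between sample columns over all genes.

    ``log2=True`` compares log2-transformed expression levels, damping the
    dominance of the brightest genes in the distance.
    """
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    if data.shape[1] < 2:
        raise ConfigError("need at least two samples for distances")
    values = data.to_numpy(dtype=float).T
    if not np.isfinite(values).all():
        raise ConfigError("non-finite expression values")
    if log2:
        if (values <= 0).any():
            raise ConfigError("log2 distances require positive values")
        values = np.log2(values)
    dist = squareform(pdist(values, metric="euclidean"))
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(labels=list(data.columns), values=dist)


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``merges`` has one row per merge: (left id, right id, height, size),
    with leaves numbered 0..n-1 in ``labels`` order and merge m creating
    cluster n+m (scipy linkage numbering).
    """

    labels: list[str]
    merges: np.ndarray

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if n >= 2 and self.merges.shape != (n - 1, 4):
            raise ConfigError(f"expected {n - 1} merges for {n} leaves")
        heights = self.merges[:, 2] if len(self.merges) else np.array([])
        if np.any(np.diff(heights) < -1e-9):
            raise ConfigError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def to_linkage(self) -> np.ndarray:
        """scipy.cluster.hierarchy linkage matrix."""
        return self.merges.copy()

    def merge_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.merges,
                          columns=["left", "right", "height", "size"])
        df[["left", "right", "size"]] = df[["left", "right", "size"]].astype(int)
        df.insert(0, "step", np.arange(len(df)))
        return df

    def cluster_members(self) -> dict[int, frozenset[str]]:
        """Map every cluster id (leaf or internal) to its leaf labels."""
        members = {i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        n = self.n_leaves
        for m, (left, right, _h, _s) in enumerate(self.merges):
            members[n + m] = members[int(left)] | members[int(right)]
        return members

    def root_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """The two leaf sets separated by the final (root) merge."""
        members = self.cluster_members()
        left, right = int(self.merges[-1, 0]), int(self.merges[-1, 1])
        return members[left], members[right]


def ward_dendrogram(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerate by Ward's criterion (D2 semantics) on a distance matrix.

    Works directly on squared distances through the Lance-Williams update;
    the recorded height of each merge is the (unsquared) merge distance.
    """
    n = dist.n
    if n < 2:
        raise ConfigError("need at least two samples to cluster")
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = dist.values[i, j] ** 2
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))  # kept sorted ascending
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        best_pair = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                pair = (active[ai], active[aj])
                v = d2[pair]
                if best is None or v < best:  # ties keep smallest index pair
                    best = v
                    best_pair = pair
        a, b = best_pair
        new = n + step
        size = sizes[a] + sizes[b]
        merges[step] = (a, b, np.sqrt(best), size)
        for k in active:
            if k in (a, b):
                continue
            dka = d2[tuple(sorted((k, a)))]
            dkb = d2[tuple(sorted((k, b)))]
            d2[(k, new)] = ((sizes[a] + sizes[k]) * dka
                            + (sizes[b] + sizes[k]) * dkb
                            - sizes[k] * best) / (size + sizes[k])
        active = [k for k in active if k not in (a, b)] + [new]
        sizes[new] = size
    return Dendrogram(labels=list(dist.labels), merges=merges)


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def dendrogram_to_newick(tree: Dendrogram) -> str:
    """Serialise a dendrogram to Newick under the half-height convention.

    Each cluster sits at height/2; a child branch length is the parent's
    position minus the child's, so a single merge of A and B at height 2
    renders as ``(A:1,B:1):0;``.
    """
    if tree.n_leaves == 0 or len(tree.merges) == 0:
        raise ConfigError("cannot serialise an empty dendrogram")
    n = tree.n_leaves
    pos = {i: 0.0 for i in range(n)}
    text = {i: lab for i, lab in enumerate(tree.labels)}
    for m, (left, right, h, _s) in enumerate(tree.merges):
        left, right = int(left), int(right)
        node = n + m
        pos[node] = h / 2.0
        text[node] = ("(" + text[left] + ":" + _fmt(pos[node] - pos[left])
                      + "," + text[right] + ":" + _fmt(pos[node] - pos[right])
                      + ")")
    return text[n + len(tree.merges) - 1] + ":0;"


def dendrogram_from_newick(newick: str) -> Dendrogram:
    """Parse an ultrametric binary Newick string back into a dendrogram.

    Heights are recovered as twice each node's distance to its leaves
    (inverting the half-height convention). Merge rows are ordered by
    height; leaf numbering follows sorted label order.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    root = tree.seed_node
    depth: dict = {}

    def leaf_depth(node) -> float:
        if node in depth:
            return depth[node]
        if node.is_leaf():
            depth[node] = 0.0
        else:
            kids = node.child_nodes()
            d = [leaf_depth(c) + (c.edge.length or 0.0) for c in kids]
            if max(d) - min(d) > 1e-6 * max(1.0, max(d)):
                raise FormatError("tree is not ultrametric")
            depth[node] = float(np.mean(d))
        return depth[node]

    leaf_depth(root)
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    if n < 2:
        raise FormatError("need at least two leaves")

    events: list[tuple[float, object]] = []

    def walk(node):
        if node.is_leaf():
            return
        kids = node.child_nodes()
        if len(kids) != 2:
            raise FormatError("dendrogram Newick must be strictly binary")
        for c in kids:
            walk(c)
        events.append((2.0 * depth[node], node))

    walk(root)
    events.sort(key=lambda e: e[0])
    cluster_of: dict = {leaf: index[leaf.taxon.label]
                        for leaf in tree.leaf_node_iter()}
    sizes = {i: 1 for i in range(n)}
    merges = np.zeros((n - 1, 4))
    for m, (h, node) in enumerate(events):
        left, right = node.child_nodes()
        a, b = cluster_of[left], cluster_of[right]
        a, b = min(a, b), max(a, b)
        size = sizes[a] + sizes[b]
        merges[m] = (a, b, h, size)
        cluster_of[node] = n + m
        sizes[n + m] = size
    return Dendrogram(labels=labels, merges=merges)


@dataclass
class PlotData:
    """Per-gene plot coordinates with optional highlighting and p-values.

    ``frame`` columns: gene_id (index), x, y, highlight and, for volcano
    data, p_value; ``guide_lines`` lists fold-change guide-line factors
    (drawn as y = c x); ``meta`` records how the coordinates were made.
    """

    frame: pd.DataFrame
    guide_lines: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("x", "y", "highlight"):
            if col not in self.frame.columns:
                raise ConfigError(f"plot data missing column {col!r}")
        if not np.isfinite(self.frame[["x", "y"]].to_numpy()).all():
            raise ConfigError("non-finite plot coordinates")

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id")


def scatter_data(matrix: ExpressionMatrix, group_x: Sequence[str],
                 group_y: Sequence[str],
                 fc_lines: Sequence[float] = (1.0, 2.0, 0.5)) -> PlotData:
    """Mean expression of one sample group against another, per gene."""
    gx, gy = list(group_x), list(group_y)
    if not gx or not gy:
        raise ConfigError("both sample groups must be non-empty")
    overlap = set(gx) & set(gy)
    if overlap:
        raise ConfigError(f"sample groups overlap: {sorted(overlap)}")
    missing = (set(gx) | set(gy)) - set(matrix.samples)
    if missing:
        raise ConfigError(f"unknown samples: {sorted(missing)}")
    df = pd.DataFrame({
        "x": matrix.data[gx].mean(axis=1),
        "y": matrix.data[gy].mean(axis=1),
    })
    df["highlight"] = False
    return PlotData(frame=df, guide_lines=tuple(fc_lines),
                    meta={"kind": "scatter", "group_x": gx, "group_y": gy})


def volcano_data(matrix: ExpressionMatrix,
                 treatment_lines: Sequence[str] | None = None) -> PlotData:
    """log2 fold change against -log10 p per gene.

    The p-value is a two-sided one-sample t-test of the per-treatment-
    sample log2 ratios against 0 (df = n_treatment - 1) — a pipeline
    default recorded in the output metadata, since a plain descriptive
    fold change carries no test of its own. Genes with zero variance
    across ratios get p = 1 when the mean log-ratio is 0 and the smallest
    positive float otherwise (flagged and counted in the log).
    """
    fc = fold_change(matrix, treatment_lines=treatment_lines)
    logr = np.log2(fc.ratios.to_numpy(dtype=float))
    nt = fc.n_treatment
    x = np.log2(fc.fold_change.to_numpy(dtype=float))
    mean = logr.mean(axis=1)
    df = pd.DataFrame(index=fc.fold_change.index)
    df["x"] = x
    if nt >= 2:
        sd = logr.std(axis=1, ddof=1)
        degenerate = sd == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(nt))
        p = 2 * stats.t.sf(np.abs(t), df=nt - 1)
        p[degenerate & (mean == 0)] = 1.0
        p[degenerate & (mean != 0)] = np.finfo(float).tiny
        n_flagged = int(np.sum(degenerate & (mean != 0)))
        if n_flagged:
            log.info("volcano_data: %d gene(s) with zero ratio variance and "
                     "nonzero mean assigned sentinel minimal p", n_flagged)
        df["y"] = -np.log10(p)
        df["highlight"] = False
        df["p_value"] = p
        df["degenerate"] = degenerate
    else:
        log.info("volcano_data: single treatment sample, no p-values")
        df["y"] = np.abs(x)
        df["highlight"] = False
    return PlotData(frame=df,
                    meta={"kind": "volcano",
                          "p_value_method": "two-sided one-sample t-test of "
                          "per-sample log2 ratios against 0 (pipeline "
                          "default; not part of the scoring method itself)",
                          "n_treatment": nt})


def highlight_genes(plot: PlotData, ann: GoAnnotation, term: str) -> PlotData:
    """Flag the plotted genes annotated with one GO term."""
    if term not in ann:
        near = difflib.get_close_matches(term, ann.term_ids, n=3)
        raise KeyError(f"unknown GO term {term!r}; near matches: {near}")
    members = ann.genes(term)
    frame = plot.frame.copy()
    frame["highlight"] = frame.index.isin(members)
    n = int(frame["highlight"].sum())
    if n == 0:
        log.warning("highlight_genes: no plotted gene carries %s", term)
    meta = dict(plot.meta, highlight_term=term, n_highlighted=n)
    return PlotData(frame=frame, guide_lines=plot.guide_lines, meta=meta)


# -- figures -----------------------------------------------------------


def _agg_pyplot():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_dendrogram(tree: Dendrogram, path: str | Path) -> Path:
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    scipy_dendrogram(tree.to_linkage(), labels=tree.labels, ax=ax)
    ax.set_ylabel("Ward merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_scatter(plot: PlotData, path: str | Path,
                 log_axes: bool = True) -> Path:
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(5, 5))
    base = plot.frame.loc[~plot.frame["highlight"]]
    ax.scatter(base["x"], base["y"], s=4, c="0.6", alpha=0.5, linewidths=0)
    hi = plot.frame.loc[plot.frame["highlight"]]
    if len(hi):
        ax.scatter(hi["x"], hi["y"], s=10, c="crimson", linewidths=0)
    lo = float(plot.frame["x"].min())
    hiv = float(plot.frame["x"].max())
    grid = np.linspace(lo, hiv, 50)
    for c in plot.guide_lines:
        ax.plot(grid, c * grid, color="green", lw=0.8)
    if log_axes:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("mean signal, group x")
    ax.set_ylabel("mean signal, group y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_volcano(plot: PlotData, path: str | Path) -> Path:
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(5, 5))
    base = plot.frame.loc[~plot.frame["highlight"]]
    ax.scatter(base["x"], base["y"], s=4, c="0.6", alpha=0.5, linewidths=0)
    hi = plot.frame.loc[plot.frame["highlight"]]
    if len(hi):
        ax.scatter(hi["x"], hi["y"], s=10, c="crimson", linewidths=0)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
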