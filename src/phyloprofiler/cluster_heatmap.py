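"""Hierarchical clustering of profile matrices and heatmap rendering.

Rows (genes) are clustered agglomeratively with the familiar gene-expression
metric/linkage menu — Euclidean, city-block, centered and uncentered Pearson
correlation, Spearman rank correlation; single, complete, average (UPGMA) or
centroid linkage.  Columns (species) are never clustered: they stay in the
user-supplied phylogenetic order.

The agglomeration is implemented here rather than delegated so that merge
and leaf-order tie-breaks are fully specified and reproducible:

* correlation distances are ``1 - r`` (maximal, 2.0, for constant rows where
  ``r`` is undefined);
* at each step the minimum-distance pair merges; exact ties resolve toward
  the pair whose clusters contain the smallest original row indices;
* centroid linkage measures the chosen metric between cluster mean vectors
  (so it remains defined for correlation metrics);
* leaf order places the smaller subtree first, ties broken by the smallest
  original index in the subtree.

Heatmaps are written as deterministic SVG: byte-identical output for
identical input, one ``<rect>`` tile per matrix cell, absence rendered
black.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "ClusterResult",
    "distance_matrix",
    "cluster_rows",
    "leaf_order",
    "to_newick",
    "tree_to_dict",
    "render_heatmap",
    "METRICS",
    "LINKAGES",
    "DEFAULT_BINARY_PALETTE",
    "DEFAULT_CATEGORICAL_PALETTE",
    "DEFAULT_DOMCONS_PALETTE",
]

METRICS = ("euclidean", "cityblock", "pearson_centered", "pearson_uncentered", "spearman")
LINKAGES = ("single", "complete", "average", "centroid")

_MAX_CORR_DISTANCE = 2.0  # 1 - r at r = -1; used for undefined correlations


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _correlation_distances(rows: np.ndarray, centered: bool) -> np.ndarray:
    x = rows - rows.mean(axis=1, keepdims=True) if centered else rows
    norms = np.sqrt((x * x).sum(axis=1))
    degenerate = norms == 0
    safe = np.where(degenerate, 1.0, norms)
    unit = x / safe[:, None]
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - r
    d[degenerate, :] = _MAX_CORR_DISTANCE
    d[:, degenerate] = _MAX_CORR_DISTANCE
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(rows: np.ndarray, metric: str) -> np.ndarray:
    """Square, symmetric, zero-diagonal distance matrix between rows."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("expected a 2-D row matrix")
    if np.isnan(rows).any():
        raise ValueError("matrix contains NaN; clean or impute before clustering")
    if metric in ("euclidean", "cityblock"):
        return squareform(pdist(rows, metric=metric))
    if metric == "pearson_centered":
        return _correlation_distances(rows, centered=True)
    if metric == "pearson_uncentered":
        return _correlation_distances(rows, centered=False)
    if metric == "spearman":
        ranks = np.apply_along_axis(rankdata, 1, rows)
        return _correlation_distances(ranks, centered=True)
    raise ValueError(f"unknown metric: {metric!r}")


# ---------------------------------------------------------------------------
# Agglomeration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class _Node:
    """Dendrogram node; leaves carry the original row index."""

    index: int | None = None  # leaf only
    left: "_Node | None" = None
    right: "_Node | None" = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.index is not None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.index]
        return self.left.leaves() + self.right.leaves()

    def min_index(self) -> int:
        if self.is_leaf:
            return self.index
        return min(self.left.min_index(), self.right.min_index())

    def size(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.size() + self.right.size()


@dataclasses.dataclass
class ClusterResult:
    row_order: list[int]
    tree: _Node
    merges: list[tuple[frozenset[int], frozenset[int], float]]
    metric: str
    linkage: str


def cluster_rows(
    matrix: np.ndarray | pd.DataFrame,
    metric: str = "pearson_uncentered",
    linkage: str = "average",
) -> ClusterResult:
    """Deterministic agglomerative clustering of matrix rows.

    Defaults (uncentered correlation, average linkage) follow the customary
    gene-expression clustering setup.  Raises on a single row (nothing to
    cluster) and on NaN.
    """
    rows = np.asarray(matrix, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("clustering needs at least two rows of equal length")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage: {linkage!r}")
    n = rows.shape[0]
    dist0 = distance_matrix(rows, metric)

    clusters: list[_Node] = [_Node(index=i) for i in range(n)]
    members: list[list[int]] = [[i] for i in range(n)]
    centroids = rows.copy()
    sizes = np.ones(n)
    d = dist0.copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))
    merges: list[tuple[frozenset[int], frozenset[int], float]] = []

    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        best = sub.min()
        # Tie resolution: among (near-)minimal pairs, the one whose clusters
        # contain the smallest original row indices.  The 1e-12 band keeps
        # the choice stable against floating-point noise in updates.
        candidates = []
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                if sub[ai, bi] <= best + 1e-12:
                    ra = clusters[active[ai]].min_index()
                    rb = clusters[active[bi]].min_index()
                    candidates.append((min(ra, rb), max(ra, rb), ai, bi))
        _, _, ai, bi = min(candidates)
        a, b = active[ai], active[bi]
        height = float(d[a, b])
        node = _Node(left=clusters[a], right=clusters[b], height=height)
        merges.append((frozenset(members[a]), frozenset(members[b]), height))

        new_members = members[a] + members[b]
        if linkage == "centroid":
            new_centroid = (centroids[a] * sizes[a] + centroids[b] * sizes[b]) / (
                sizes[a] + sizes[b]
            )
        # Merge into slot a; retire slot b.
        for c in active:
            if c in (a, b):
                continue
            if linkage == "single":
                d[a, c] = d[c, a] = min(d[a, c], d[b, c])
            elif linkage == "complete":
                d[a, c] = d[c, a] = max(d[a, c], d[b, c])
            elif linkage == "average":
                d[a, c] = d[c, a] = (
                    sizes[a] * d[a, c] + sizes[b] * d[b, c]
                ) / (sizes[a] + sizes[b])
            else:  # centroid: metric between mean vectors
                d[a, c] = d[c, a] = distance_matrix(
                    np.vstack([new_centroid, centroids[c]]), metric
                )[0, 1]
        clusters[a] = node
        members[a] = new_members
        if linkage == "centroid":
            centroids[a] = new_centroid
        sizes[a] = sizes[a] + sizes[b]
        d[b, :] = np.inf
        d[:, b] = np.inf
        active.remove(b)

    tree = clusters[active[0]]
    return ClusterResult(
        row_order=leaf_order(tree),
        tree=tree,
        merges=merges,
        metric=metric,
        linkage=linkage,
    )


def leaf_order(tree: _Node) -> list[int]:
    """Smaller-subtree-first leaf ordering (ties: smallest original index)."""
    if tree.is_leaf:
        return [tree.index]
    children = sorted(
        (tree.left, tree.right), key=lambda c: (c.size(), c.min_index())
    )
    return leaf_order(children[0]) + leaf_order(children[1])


# ---------------------------------------------------------------------------
# Dendrogram exports
# ---------------------------------------------------------------------------


def to_newick(tree: _Node, labels: Sequence[str]) -> str:
    """Newick serialization with branch lengths from merge-height deltas."""

    def render(node: _Node, parent_height: float) -> str:
        length = max(parent_height - node.height, 0.0)
        if node.is_leaf:
            return f"{labels[node.index]}:{length:.6g}"
        inner = ",".join(
            render(c, node.height)
            for c in sorted((node.left, node.right), key=lambda c: (c.size(), c.min_index()))
        )
        return f"({inner}):{length:.6g}"

    return render(tree, tree.height) + ";"


def tree_to_dict(tree: _Node, labels: Sequence[str]) -> dict:
    if tree.is_leaf:
        return {"label": labels[tree.index], "index": tree.index}
    children = sorted((tree.left, tree.right), key=lambda c: (c.size(), c.min_index()))
    return {
        "height": tree.height,
        "children": [tree_to_dict(c, labels) for c in children],
    }


# ---------------------------------------------------------------------------
# Heatmap rendering (deterministic SVG)
# ---------------------------------------------------------------------------

#: Presence/absence view: absence is black, presence colored.
DEFAULT_BINARY_PALETTE: dict[int, str] = {0: "#000000", 1: "#e8b420"}

#: Relationship-category view (0=absent, 1=1:1, 2=1:M, 3=M:1, 4=M:M).
DEFAULT_CATEGORICAL_PALETTE: dict[int, str] = {
    0: "#000000",
    1: "#e8b420",
    2: "#2c7fb8",
    3: "#7fbc41",
    4: "#d7301f",
}

#: Domain-conservation view keyed by ArchClass code (0=no ortholog ... 6=conserved).
DEFAULT_DOMCONS_PALETTE: dict[int, str] = {
    0: "#000000",
    1: "#bdbdbd",
    2: "#984ea3",
    3: "#ff7f00",
    4: "#e41a1c",
    5: "#4daf4a",
    6: "#e8b420",
}

_CELL = 14  # tile edge, px
_LABEL_W = 110
_LABEL_H = 90


def render_heatmap(
    matrix: pd.DataFrame,
    row_order: Sequence[int] | None = None,
    palette: Mapping[int, str] | None = None,
    out: str | None = None,
) -> str:
    """Render a categorical genes x species grid as SVG.

    One tile per cell, rows in clustered order, species columns in the given
    (phylogenetic) order.  The produced SVG is byte-deterministic for fixed
    input; it is also returned as a string.
    """
    palette = dict(palette or DEFAULT_CATEGORICAL_PALETTE)
    if row_order is None:
        row_order = list(range(matrix.shape[0]))
    genes = [str(matrix.index[i]) for i in row_order]
    species = [str(c) for c in matrix.columns]
    values = matrix.to_numpy()

    width = _LABEL_W + _CELL * len(species)
    height = _LABEL_H + _CELL * len(genes)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        '<style>text{font-family:monospace;font-size:9px;}</style>',
    ]
    for j, sp in enumerate(species):
        x = _LABEL_W + j * _CELL + _CELL // 2
        parts.append(
            f'<text x="{x}" y="{_LABEL_H - 6}" '
            f'transform="rotate(-60 {x} {_LABEL_H - 6})">{_esc(sp)}</text>'
        )
    for r, (orig, gene) in enumerate(zip(row_order, genes)):
        y = _LABEL_H + r * _CELL
        parts.append(f'<text x="2" y="{y + _CELL - 4}">{_esc(gene)}</text>')
        for j in range(len(species)):
            val = int(values[orig, j])
            if val not in palette:
                raise ValueError(
                    f"no palette entry for value {val} at cell "
                    f"({matrix.index[orig]!r}, {species[j]!r})"
                )
            parts.append(
                f'<rect x="{_LABEL_W + j * _CELL}" y="{y}" width="{_CELL}" '
                f'height="{_CELL}" fill="{palette[val]}"/>'
            )
    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"
    if out is not None:
        with open(out, "w") as fh:
            fh.write(svg)
    return svg


def _esc(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
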