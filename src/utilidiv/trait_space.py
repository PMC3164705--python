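"""Trait space construction: Gower dissimilarity and the functional dendrogram.

The pipeline summarizes species' utilitarian similarity as a single
ultrametric tree: mixed-type properties are combined into a Gower
dissimilarity matrix, several agglomerative linkage rules are tried, and
the tree whose cophenetic distances best correlate with the input
dissimilarities is retained (UPGMA wins ties). Branch lengths follow the
hclust convention: tips sit at height 0, an internal node sits at its merge
height, and an edge's length is the height difference between parent and
child. FD values depend on that convention, so it is stamped into result
metadata by the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import TraitTable
from .errors import (
    DegenerateDistanceError,
    NonMonotoneLinkageError,
    SchemaError,
    UndefinedCorrelationError,
)

logger = logging.getLogger(__name__)

#: Mapping from the names used throughout the package to scipy linkage codes.
LINKAGE_METHODS = {
    "UPGMA": "average",
    "single": "single",
    "complete": "complete",
    "WPGMA": "weighted",
}

#: Candidate linkage rules tried by :func:`select_linkage`, in tie-break
#: priority order (UPGMA first).
DEFAULT_LINKAGE_CANDIDATES = ("UPGMA", "single", "complete", "WPGMA")

EDGE_LENGTH_CONVENTION = "hclust: tips at 0, edge = parent height - child height"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric species dissimilarity matrix with values in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray  # square form

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.labels)
        if v.shape != (n, n):
            raise SchemaError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise SchemaError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise SchemaError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise SchemaError("distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def gower_distance(traits: TraitTable, weights: dict[str, float] | None = None) -> DistanceMatrix:
    """Gower dissimilarity over mixed ordinal/binary utilitarian properties.

    Per-property contributions are |x_i - x_j| / range for ordinal columns
    (0 when the pool range is 0) and a plain mismatch indicator for binary
    columns; the weighted mean over properties gives d(i, j) in [0, 1].
    Weights default to 1 per property; a zero-range property contributes 0
    but stays in the denominator through its weight.
    """
    cols = list(traits.properties)
    w = np.ones(len(cols))
    if weights is not None:
        unknown = set(weights) - set(cols)
        if unknown:
            raise SchemaError(f"weights name unknown properties: {sorted(unknown)}")
        w = np.array([float(weights.get(c, 1.0)) for c in cols])
        if np.any(w < 0) or w.sum() <= 0:
            raise SchemaError("weights must be nonnegative with positive sum")

    x = traits.values()
    n, p = x.shape
    ordinal = np.array([c in traits.ordinal for c in cols])
    ranges = x.max(axis=0) - x.min(axis=0)
    if np.all(ranges == 0):
        raise DegenerateDistanceError(
            "every property is constant across the pool; Gower distance degenerate"
        )

    diff = np.abs(x[:, None, :] - x[None, :, :])  # (n, n, p)
    delta = np.empty_like(diff)
    # ordinal / continuous: range-normalized absolute difference
    safe = np.where(ranges > 0, ranges, 1.0)
    delta[:, :, ordinal] = diff[:, :, ordinal] / safe[ordinal]
    delta[:, :, ordinal & (ranges == 0)] = 0.0
    # binary: symmetric simple mismatch
    delta[:, :, ~ordinal] = (diff[:, :, ~ordinal] != 0).astype(float)

    d = (delta * w).sum(axis=2) / w.sum()
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(tuple(traits.species), d)


@dataclass(frozen=True)
class FunctionalDendrogram:
    """Ultrametric merge tree over the species pool.

    Nodes are numbered scipy-style: leaves 0..n-1 in label order, internal
    node n+j is the j-th merge. ``heights`` holds the merge height of each
    internal node; ``parent`` maps every non-root node to its parent;
    ``edge_lengths[v]`` is the length of the edge above node v.
    """

    leaves: tuple[str, ...]
    merges: np.ndarray        # (n-1, 2) int children of each internal node
    heights: np.ndarray       # (n-1,) merge heights, non-decreasing
    linkage_method: str
    cophenetic_r: float | None = None
    _linkage: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.heights) < -1e-12):
            raise NonMonotoneLinkageError(
                f"{self.linkage_method}: merge heights decrease; "
                "nonnegative edge lengths impossible"
            )
        if np.any(self.heights < 0):
            raise NonMonotoneLinkageError("negative merge height")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def parent(self) -> np.ndarray:
        par = np.full(self.n_nodes, -1, dtype=int)
        n = self.n_leaves
        for j, (a, b) in enumerate(self.merges):
            par[a] = n + j
            par[b] = n + j
        return par

    @property
    def node_heights(self) -> np.ndarray:
        """Height of every node (tips at 0, internal at merge height)."""
        h = np.zeros(self.n_nodes)
        h[self.n_leaves :] = self.heights
        return h

    @property
    def edge_lengths(self) -> np.ndarray:
        """Length of the edge above every node (0 for the root)."""
        h = self.node_heights
        par = self.parent
        lengths = np.zeros(self.n_nodes)
        nonroot = par >= 0
        lengths[nonroot] = h[par[nonroot]] - h[nonroot]
        # clip tiny negatives from float noise in monotone linkages
        return np.maximum(lengths, 0.0)

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    def leaf_index(self, labels) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.leaves)}
        return np.array([lookup[s] for s in labels], dtype=int)

    def linkage_matrix(self) -> np.ndarray:
        if self._linkage is not None:
            return self._linkage
        n = self.n_leaves
        sizes = np.ones(self.n_nodes)
        z = np.zeros((n - 1, 4))
        for j, (a, b) in enumerate(self.merges):
            sizes[n + j] = sizes[a] + sizes[b]
            z[j] = (a, b, self.heights[j], sizes[n + j])
        return z

    def cophenetic_matrix(self) -> np.ndarray:
        """Condensed cophenetic distances (merge height of each pair's MRCA)."""
        return hierarchy.cophenet(self.linkage_matrix())


def cluster(dist: DistanceMatrix, method: str = "UPGMA") -> FunctionalDendrogram:
    """Agglomerative clustering of a distance matrix under a named linkage rule.

    Refuses non-monotone merge-height sequences (e.g. what centroid linkage
    can produce) because edge lengths would go negative.
    """
    if method not in LINKAGE_METHODS:
        raise SchemaError(
            f"unknown linkage {method!r}; choose from {sorted(LINKAGE_METHODS)}"
        )
    z = hierarchy.linkage(dist.condensed(), method=LINKAGE_METHODS[method])
    return FunctionalDendrogram(
        leaves=dist.labels,
        merges=z[:, :2].astype(int),
        heights=z[:, 2].copy(),
        linkage_method=method,
        _linkage=z,
    )


def cophenetic_correlation(tree: FunctionalDendrogram, dist: DistanceMatrix) -> float:
    """Pearson correlation between tree cophenetic distances and input distances."""
    if tuple(tree.leaves) != tuple(dist.labels):
        raise SchemaError("tree and distance matrix label sets differ")
    if dist.n < 3:
        raise UndefinedCorrelationError(
            "cophenetic correlation needs at least 3 species"
        )
    coph = tree.cophenetic_matrix()
    orig = dist.condensed()
    if np.std(coph) == 0 or np.std(orig) == 0:
        # a star-like tree or constant input: correlation is degenerate;
        # report 1 only when the tree reproduces the distances exactly
        return 1.0 if np.allclose(coph, orig) else 0.0
    return float(np.corrcoef(coph, orig)[0, 1])


def select_linkage(
    dist: DistanceMatrix,
    methods: tuple[str, ...] = DEFAULT_LINKAGE_CANDIDATES,
) -> tuple[FunctionalDendrogram, pd.DataFrame]:
    """Cluster under each candidate linkage and keep the best tree.

    "Best" is the highest cophenetic correlation with the input distances;
    exact ties go to the earliest method in ``methods`` (UPGMA first by
    default). Returns the winning tree (with ``cophenetic_r`` filled in)
    and a per-method report.
    """
    if len(methods) < 2:
        raise SchemaError("need at least 2 candidate linkage methods")
    rows = []
    best: FunctionalDendrogram | None = None
    best_r = -np.inf
    for method in methods:
        try:
            tree = cluster(dist, method)
            r = cophenetic_correlation(tree, dist)
        except (NonMonotoneLinkageError, UndefinedCorrelationError) as exc:
            logger.warning("linkage %s skipped: %s", method, exc)
            rows.append({"method": method, "cophenetic_r": np.nan})
            continue
        rows.append({"method": method, "cophenetic_r": r})
        if r > best_r:
            best, best_r = tree, r
    report = pd.DataFrame(rows, columns=["method", "cophenetic_r"])
    if best is None:
        raise NonMonotoneLinkageError("every candidate linkage failed")
    winner = FunctionalDendrogram(
        leaves=best.leaves,
        merges=best.merges,
        heights=best.heights,
        linkage_method=best.linkage_method,
        cophenetic_r=best_r,
        _linkage=best._linkage,
    )
    return winner, report


def to_newick(tree: FunctionalDendrogram) -> str:
    """Serialize the dendrogram as a Newick string with branch lengths.

    Branch lengths are printed with 12 significant digits (round-trip
    faithful well past the 1e-9 tolerance the format guarantees);
    at each node, children are ordered by the smallest leaf index in their
    subtree, so the output is canonical for a given tree.
    """
    heights = tree.node_heights
    n = tree.n_leaves

    def min_leaf(node: int) -> int:
        if node < n:
            return node
        a, b = tree.merges[node - n]
        return min(min_leaf(a), min_leaf(b))

    def children(node: int) -> list[int]:
        return sorted(tree.merges[node - n], key=min_leaf)

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            body = tree.leaves[node]
        else:
            parts = ",".join(render(c, heights[node]) for c in children(node))
            body = f"({parts})"
        return f"{body}:{float(length):.12g}"

    root = tree.root
    h = heights[root]
    parts = ",".join(render(c, h) for c in children(root))
    return f"({parts});"
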