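"""Dendrogram-based functional diversity (Petchey–Gaston FD).

FD of a plot is the total branch length of the smallest connected subtree
of the pool dendrogram that joins the plot's species. The stem from the
members' most recent common ancestor toward the root is *not* counted (the
"smallest subtree" reading); a singleton plot therefore has FD = 0. The
tree is built once from the full pool and all plot FDs are read off it, so
values are comparable across plots and valid inputs to the null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import MembershipError
from .trait_space import FunctionalDendrogram


@dataclass(frozen=True)
class FDValue:
    plot_id: str
    fd: float
    richness: int


def _membership_vector(tree: FunctionalDendrogram, members) -> np.ndarray:
    members = list(members)
    if not members:
        raise MembershipError("empty member set")
    unknown = sorted(set(members) - set(tree.leaves))
    if unknown:
        raise MembershipError(f"not leaves of the dendrogram: {unknown}")
    vec = np.zeros(tree.n_leaves, dtype=np.int64)
    vec[tree.leaf_index(members)] = 1
    return vec


def fd(tree: FunctionalDendrogram, members, plot_id: str = "") -> FDValue:
    """FD of one plot: branch length of the minimal subtree spanning its tips.

    An edge above node v lies on some tip-to-MRCA path exactly when v's
    subtree holds a nonempty proper subset of the members, so FD is the sum
    of edge lengths over such nodes.
    """
    vec = _membership_vector(tree, members)
    total = fd_batch(tree, vec[None, :])[0]
    return FDValue(plot_id=plot_id, fd=float(total), richness=int(vec.sum()))


def fd_batch(tree: FunctionalDendrogram, membership: np.ndarray) -> np.ndarray:
    """FD for many membership vectors at once.

    ``membership`` is (n_draws, n_leaves) 0/1; returns (n_draws,) FD values.
    The per-node member counts are accumulated bottom-up in merge order,
    which is valid because scipy numbers internal nodes in merge order.
    """
    n = tree.n_leaves
    n_draws = membership.shape[0]
    counts = np.empty((n_draws, tree.n_nodes), dtype=np.int64)
    counts[:, :n] = membership
    for j, (a, b) in enumerate(tree.merges):
        counts[:, n + j] = counts[:, a] + counts[:, b]
    total = counts[:, tree.root][:, None]
    on_path = (counts > 0) & (counts < total)
    return on_path @ tree.edge_lengths


def fd_bruteforce(tree: FunctionalDendrogram, members, plot_id: str = "") -> FDValue:
    """Independent FD computation by explicit edge-removal connectivity tests.

    For every edge of the dendrogram (viewed as an undirected graph), remove
    it and check whether two members end up in different components; the FD
    is the summed length of such separating edges. Quadratic in tree size —
    intended for cross-checks on small pools, not production use.
    """
    vec = _membership_vector(tree, members)
    member_nodes = set(np.flatnonzero(vec).tolist())
    if len(member_nodes) == 1:
        return FDValue(plot_id=plot_id, fd=0.0, richness=1)

    g = nx.Graph()
    g.add_nodes_from(range(tree.n_nodes))
    parent = tree.parent
    lengths = tree.edge_lengths
    edges = [(v, int(parent[v])) for v in range(tree.n_nodes) if parent[v] >= 0]
    g.add_edges_from(edges)

    total = 0.0
    for v, p in edges:
        g.remove_edge(v, p)
        side = nx.node_connected_component(g, v)
        inside = len(member_nodes & side)
        if 0 < inside < len(member_nodes):
            total += lengths[v]
        g.add_edge(v, p)
    return FDValue(plot_id=plot_id, fd=float(total), richness=len(member_nodes))
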