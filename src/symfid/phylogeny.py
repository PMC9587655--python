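"""Distance-based tree inference: neighbor joining with bootstrap support.

Implements classical neighbor joining (Saitou-Nei Q-criterion).  On
additive distance matrices NJ recovers the generating topology and branch
lengths exactly, which makes it fully testable against a path-length
oracle; for the low-divergence within-species matrices this pipeline
produces, it is interchangeable with balanced minimal-evolution methods.
Negative branch-length estimates are clamped to zero with the deficit
moved to the sibling edge so the joined pair's distance is preserved.

Ties in the Q-criterion are broken deterministically by the
lexicographically smallest pair of cluster labels (a cluster is labelled
by its smallest leaf).  Trees are unrooted; the NJ root is a trifurcation
kept only as an anchor for traversal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "Clade",
    "PhyloTree",
    "build_nj_tree",
    "bootstrap_support",
    "basal_split",
    "to_newick",
    "from_newick",
]


@dataclass
class Clade:
    """One node of an (un)rooted tree; ``length`` is the edge to its parent."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None  # percent, internal edges only
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    root: Clade

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def internal_edges(self) -> list[tuple[Clade, frozenset[str]]]:
        """(child node, leaf set below it) for every internal edge."""
        all_leaves = set(self.leaf_names())
        out = []

        def walk(node: Clade) -> None:
            for child in node.children:
                if not child.is_leaf:
                    below = frozenset(child.leaves())
                    # internal in the unrooted sense: >= 2 leaves on each side
                    if len(below) >= 2 and len(all_leaves) - len(below) >= 2:
                        out.append((child, below))
                    walk(child)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical internal bipartitions: each is represented by the side
        NOT containing the lexicographically smallest leaf."""
        ref = min(self.leaf_names())
        sides = set()
        for _, below in self.internal_edges():
            side = below if ref not in below else frozenset(self.leaf_names()) - below
            sides.add(side)
        return sides


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _clamp_pair(li: float, lj: float, dij: float) -> tuple[float, float]:
    """Clamp a negative pendant estimate to 0, moving the deficit to the
    sibling so li + lj == dij is preserved (dij >= 0)."""
    li = min(max(li, 0.0), dij)
    return li, dij - li


def build_nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Classical neighbor joining over a validated distance matrix."""
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 taxa")
    M = np.array(D.D, dtype=float)
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (M < 0).any():
        raise ValueError("distance matrix must be non-negative")

    nodes: list[Clade] = [Clade(name=l) for l in D.labels]
    labels: list[str] = list(D.labels)  # cluster label = smallest member leaf

    if n == 2:
        d = float(M[0, 1])
        nodes[0].length = d / 2.0
        nodes[1].length = d / 2.0
        return PhyloTree(root=Clade(children=nodes))

    active = list(range(n))
    dist = {(i, j): float(M[i, j]) for i in range(n) for j in range(n) if i < j}

    def d_of(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d_of(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d_of(i, j) - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if q < best_q or (q == best_q and best is not None and key < best[2]):
                    best_q = q
                    best = (i, j, key)
        i, j, _ = best  # type: ignore[misc]
        dij = d_of(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        li, lj = _clamp_pair(li, dij - li, dij)
        parent = Clade(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        for k in active:
            if k in (i, j):
                continue
            dist[(k, next_id) if k < next_id else (next_id, k)] = 0.5 * (
                d_of(i, k) + d_of(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    dij, dik, djk = d_of(i, j), d_of(i, k), d_of(j, k)
    vi = max(0.0, (dij + dik - djk) / 2.0)
    vj = max(0.0, (dij + djk - dik) / 2.0)
    vk = max(0.0, (dik + djk - dij) / 2.0)
    nodes[i].length, nodes[j].length, nodes[k].length = vi, vj, vk
    order = sorted(range(3), key=lambda t: labels[[i, j, k][t]])
    children = [[nodes[i], nodes[j], nodes[k]][t] for t in order]
    return PhyloTree(root=Clade(children=children))


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------


def bootstrap_support(main: PhyloTree, replicates: Sequence[PhyloTree]) -> PhyloTree:
    """Annotate each internal edge of ``main`` with the percentage of
    replicate trees containing the same bipartition."""
    main_leaves = set(main.leaf_names())
    for rep in replicates:
        if set(rep.leaf_names()) != main_leaves:
            raise ValueError("replicate leaf set differs from main tree")
    if not replicates:
        raise ValueError("need at least one replicate")
    ref = min(main_leaves)
    rep_parts = [rep.bipartitions() for rep in replicates]

    for child, below in main.internal_edges():
        side = below if ref not in below else frozenset(main_leaves) - below
        count = sum(side in parts for parts in rep_parts)
        child.support = 100.0 * count / len(replicates)
    return main


def basal_split(tree: PhyloTree) -> tuple[list[str], list[str]]:
    """Bipartition induced by the longest internal edge (the deepest
    divergence).  Ties break by higher support, then by lexicographically
    smallest side.  Requires >= 4 leaves."""
    leaves = tree.leaf_names()
    if len(leaves) < 4:
        raise ValueError("basal split needs >= 4 leaves")
    edges = tree.internal_edges()
    if not edges:
        raise ValueError("tree has no internal edge")

    def sort_key(item: tuple[Clade, frozenset[str]]):
        child, below = item
        side = tuple(sorted(below))
        support = child.support if child.support is not None else -1.0
        return (-child.length, -support, side)

    child, below = min(edges, key=sort_key)
    side = sorted(below)
    other = sorted(set(leaves) - below)
    return side, other


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def to_newick(tree: PhyloTree) -> str:
    """Newick with branch lengths and bootstrap supports as internal-node
    labels."""

    def fmt(node: Clade, top: bool = False) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else format(node.support, ".6g")
            body = f"({inner}){label}"
        if top:
            return body
        return f"{body}:{format(node.length, '.17g')}"

    return fmt(tree.root, top=True) + ";"


def from_newick(text: str) -> PhyloTree:
    """Parse newick (supports as internal labels) into a :class:`PhyloTree`."""
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)

    def convert(dnode) -> Clade:
        if dnode.is_leaf():
            return Clade(
                name=dnode.taxon.label if dnode.taxon else dnode.label,
                length=float(dnode.edge.length or 0.0),
            )
        support = None
        if dnode.label not in (None, ""):
            try:
                support = float(dnode.label)
            except ValueError:
                support = None
        return Clade(
            name=None,
            length=float(dnode.edge.length or 0.0),
            support=support,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    return PhyloTree(root=convert(dtree.seed_node))
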