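"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from symfid.distances import DistanceMatrix
from symfid.genotype_model import PosteriorGenotypeMatrix
from symfid.phylogeny import Clade, PhyloTree


def point_mass_matrix(genotypes: np.ndarray, sample_ids=None) -> PosteriorGenotypeMatrix:
    """Posterior matrix with all mass on the given integer genotypes
    (S x L array of allele indices)."""
    genotypes = np.asarray(genotypes)
    S, L = genotypes.shape
    P = np.zeros((S, L, 4))
    for i in range(S):
        P[i, np.arange(L), genotypes[i]] = 1.0
    ids = sample_ids or [f"s{i}" for i in range(S)]
    return PosteriorGenotypeMatrix(
        sample_ids=list(ids), positions=np.arange(1, L + 1), P=P
    )


def hamming_matrix_oracle(genotypes: np.ndarray) -> np.ndarray:
    """Brute-force normalized Hamming distances by string comparison."""
    S, L = genotypes.shape
    D = np.zeros((S, S))
    for i in range(S):
        for j in range(S):
            if i != j:
                D[i, j] = sum(
                    a != b for a, b in zip(genotypes[i], genotypes[j])
                ) / L
    return D


def random_additive_tree(n: int, rng) -> tuple[dict, np.ndarray, list[str]]:
    """Random binary unrooted tree with positive branch lengths and its
    path-length (additive) distance matrix, built by sequential leaf
    attachment; the oracle distances are summed path lengths in a graph."""
    labels = [f"t{i:02d}" for i in range(n)]
    # adjacency: node -> {node: length}; leaves are labels, internals ints
    adj: dict = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def remove_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    add_edge(labels[0], labels[1], float(rng.uniform(0.05, 1.0)))
    next_internal = 0
    for leaf in labels[2:]:
        edges = [(a, b) for a in adj for b in adj[a] if str(a) <= str(b)]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        split = float(rng.uniform(0.2, 0.8)) * w
        mid = ("x", next_internal)
        next_internal += 1
        remove_edge(a, b)
        add_edge(a, mid, split)
        add_edge(mid, b, w - split)
        add_edge(mid, leaf, float(rng.uniform(0.05, 1.0)))

    # all-pairs path lengths by BFS/DFS from each leaf
    D = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]
    return adj, D, labels


def two_cluster_tree(left: list[str], right: list[str], internal: float = 1.0,
                     pendant: float = 0.01) -> PhyloTree:
    """Hand-built tree: two rakes joined by one long internal edge."""

    def rake(names: list[str]) -> Clade:
        return Clade(
            children=[Clade(name=n, length=pendant) for n in names],
            length=internal / 2.0,
        )

    return PhyloTree(root=Clade(children=[rake(left), rake(right)]))


def brute_force_mst_weight(n: int, weights: dict[tuple[int, int], int]) -> int:
    """Exhaustive minimum spanning tree weight over all edge subsets."""
    edges = list(weights)
    best = None
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            w = sum(weights[e] for e in subset)
            if best is None or w < best:
                best = w
    return best


def grid_search_minor_freq(lmaj: np.ndarray, lmin: np.ndarray) -> float:
    """Independent fine-grid oracle for the ML minor-allele frequency:
    coarse 0.001 grid, then 1e-7 refinement around the coarse optimum."""

    def lnl(f):
        return np.sum(np.log(f * lmin + (1.0 - f) * lmaj))

    coarse = np.linspace(0.0, 1.0, 1001)
    vals = [lnl(f) for f in coarse]
    f0 = coarse[int(np.argmax(vals))]
    lo, hi = max(0.0, f0 - 0.002), min(1.0, f0 + 0.002)
    fine = np.arange(lo, hi + 1e-12, 1e-7)
    vals = [lnl(f) for f in fine]
    return float(fine[int(np.argmax(vals))])


@pytest.fixture
def oracles():
    """Bundle of independent oracle helpers."""
    return {
        "point_mass_matrix": point_mass_matrix,
        "hamming_matrix_oracle": hamming_matrix_oracle,
        "random_additive_tree": random_additive_tree,
        "two_cluster_tree": two_cluster_tree,
        "brute_force_mst_weight": brute_force_mst_weight,
        "grid_search_minor_freq": grid_search_minor_freq,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
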