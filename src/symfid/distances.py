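"""Expected pairwise genetic distances from posterior genotype matrices.

The distance between two samples is the expected fraction of SNP sites at
which their (haploid) genotypes differ, taking the genotype posteriors as
independent:

    d_ij = (1 / L) * sum_s [ 1 - sum_a P_i,s(a) * P_j,s(a) ]

On fully certain (point-mass) posteriors this reduces exactly to the
normalized Hamming distance.  No evolutionary-model correction is applied:
distances operate within species at low divergence, where multiple hits
are negligible, and are normalized per SNP site.  Log scaling for display
is a presentation choice left to reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_model import PosteriorGenotypeMatrix
from .io_formats import read_phylip_distances, write_phylip_distances

__all__ = [
    "DistanceMatrix",
    "expected_pairwise_distance",
    "distance_matrix",
    "bootstrap_distance_matrices",
]


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix over samples.

    ``normalization`` is ``"per-SNP-site"`` for the pipeline's expected
    distances (entries bounded by [0, 1]) or ``"raw"`` for unnormalized
    matrices (e.g. additive path-length matrices fed to tree inference).
    """

    labels: list[str]
    D: np.ndarray
    n_sites: int
    normalization: str = "per-SNP-site"

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if self.normalization == "per-SNP-site" and (
            (self.D < -1e-12).any() or (self.D > 1 + 1e-12).any()
        ):
            raise ValueError("per-SNP-site distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.D[self.labels.index(a), self.labels.index(b)])

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=list(labels),
            D=self.D[np.ix_(idx, idx)],
            n_sites=self.n_sites,
            normalization=self.normalization,
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.D[iu]

    def to_phylip(self) -> str:
        return write_phylip_distances(self.labels, self.D)

    @classmethod
    def from_phylip(cls, text: str, n_sites: int = 0) -> "DistanceMatrix":
        labels, D = read_phylip_distances(text)
        return cls(labels=labels, D=D, n_sites=n_sites)


def expected_pairwise_distance(P_i: np.ndarray, P_j: np.ndarray) -> float:
    """Expected per-site genotype mismatch between two posterior tracks.

    ``P_i``/``P_j``: (L, 4) posterior vectors over matched SNP sites.
    """
    P_i = np.asarray(P_i, dtype=float)
    P_j = np.asarray(P_j, dtype=float)
    if P_i.shape != P_j.shape or P_i.ndim != 2 or P_i.shape[1] != 4:
        raise ValueError("posterior tracks must both have shape (L, 4)")
    if P_i.shape[0] == 0:
        raise ValueError("distance undefined over zero sites")
    return float(np.mean(1.0 - np.sum(P_i * P_j, axis=1)))


def _pair_similarity_tensor(P: np.ndarray) -> np.ndarray:
    """Per-site probability that two samples' genotypes agree: (S, S, L)."""
    return np.einsum("ila,jla->ijl", P, P)


def distance_matrix(P: PosteriorGenotypeMatrix) -> DistanceMatrix:
    """All-pairs expected distances; symmetric with a zero diagonal."""
    if len(P.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    if P.n_sites == 0:
        raise ValueError("no SNP sites: distance matrix undefined")
    L = P.n_sites
    # (L - sum of per-site agreements) / L keeps the point-mass case exact
    # integer arithmetic, matching a brute-force Hamming count bit for bit
    agree = np.einsum("ila,jla->ij", P.P, P.P)
    D = (L - agree) / L
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(labels=list(P.sample_ids), D=D, n_sites=L)


def bootstrap_distance_matrices(
    P: PosteriorGenotypeMatrix, n_reps: int, seed: int = 0
) -> list[DistanceMatrix]:
    """Site-resampling bootstrap: each replicate redraws the L SNP sites
    with replacement (independent sites, block length 1) and recomputes the
    full matrix.  Deterministic under ``seed``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    L = P.n_sites
    S = len(P.sample_ids)
    out = []
    # per-site agreement tensor lets each replicate be a cheap mean over
    # resampled site slices; fall back to einsum when it would be too large
    use_tensor = S * S * L <= 40_000_000
    T = _pair_similarity_tensor(P.P) if use_tensor else None
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        if T is not None:
            agree = T[:, :, idx].sum(axis=2)
        else:
            Pb = P.P[:, idx, :]
            agree = np.einsum("ila,jla->ij", Pb, Pb)
        D = (L - agree) / L
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
        out.append(DistanceMatrix(labels=list(P.sample_ids), D=D, n_sites=L))
    return out
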