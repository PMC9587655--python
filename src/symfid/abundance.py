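"""Symbiont community composition from single-copy marker genes, and the
within-sample SNP-density estimator of strain diversity.

Relative abundances are computed from reads uniquely assigned to a
per-species reference of single-copy genes.  The reference is first purged
of (i) duplicated genes within a species and (ii) gene pairs shared at
> 90% nucleotide identity between species -- the purge is exactly what
makes unique-assignment counting adequate (cross-mapping genes are gone).
Per species, the abundance score is the mean over its retained genes of
``count / gene_length`` (a per-gene depth), normalized to percentages per
sample.

Within-sample SNP density (polymorphic sites per callable kbp at depth
>= 10, minor allele >= 10% and >= 2 reads) proxies within-host strain
diversity; low densities justify treating each symbiont in a host as a
single genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .genotype_model import SampleSiteData

__all__ = [
    "GeneRecord",
    "AbundanceTable",
    "SnpDensity",
    "build_single_copy_reference",
    "relative_abundance",
    "within_sample_snp_density",
]


@dataclass
class GeneRecord:
    """One single-copy gene sequence of one symbiont's reference set."""

    symbiont: str
    gene_id: str
    seq: str
    status: str = "retained"  # retained | dropped_duplicate | dropped_cross_identity

    @property
    def length(self) -> int:
        return len(self.seq)


def _identity(a: str, b: str) -> float:
    """Global (NW) alignment nucleotide identity between two sequences,
    computed as 1 - edit_distance / alignment_length."""
    res = edlib.align(a, b, mode="NW", task="distance")
    align_len = max(len(a), len(b))
    return 1.0 - res["editDistance"] / align_len


def build_single_copy_reference(
    gene_sets: Mapping[str, Sequence[GeneRecord]] | Iterable[GeneRecord],
    cross_identity_threshold: float = 0.90,
) -> list[GeneRecord]:
    """Filter the single-copy gene reference for unambiguous assignment.

    Duplicated gene ids within a species are dropped (all copies), and any
    cross-species gene pair aligning at > ``cross_identity_threshold``
    global nucleotide identity drops both members.  Raises when a species
    is left without any retained gene.
    """
    if isinstance(gene_sets, Mapping):
        genes = [g for recs in gene_sets.values() for g in recs]
    else:
        genes = list(gene_sets)
    if not genes:
        raise ValueError("empty gene set")

    # within-species duplicates
    seen: dict[tuple[str, str], int] = {}
    for g in genes:
        seen[(g.symbiont, g.gene_id)] = seen.get((g.symbiont, g.gene_id), 0) + 1
    for g in genes:
        if seen[(g.symbiont, g.gene_id)] > 1:
            g.status = "dropped_duplicate"

    # cross-species identity
    alive = [g for g in genes if g.status == "retained"]
    for i in range(len(alive)):
        for j in range(i + 1, len(alive)):
            gi, gj = alive[i], alive[j]
            if gi.symbiont == gj.symbiont:
                continue
            if _identity(gi.seq, gj.seq) > cross_identity_threshold:
                gi.status = "dropped_cross_identity"
                gj.status = "dropped_cross_identity"

    retained_per_species: dict[str, int] = {}
    for g in genes:
        retained_per_species.setdefault(g.symbiont, 0)
        if g.status == "retained":
            retained_per_species[g.symbiont] += 1
    empty = sorted(s for s, k in retained_per_species.items() if k == 0)
    if empty:
        raise ValueError(f"no retained single-copy genes for: {empty}")
    return genes


@dataclass
class AbundanceTable:
    """Per-sample relative abundances (%) with detection flags."""

    abundances: pd.DataFrame  # samples x symbionts, percentages
    detected: pd.DataFrame  # samples x symbionts, bool
    gene_scores: pd.DataFrame  # per-gene normalized counts, kept for QC

    def of(self, sample: str, symbiont: str) -> float:
        return float(self.abundances.loc[sample, symbiont])


def relative_abundance(
    read_counts: pd.DataFrame | Mapping[str, Mapping[str, int]],
    genes: Sequence[GeneRecord],
    breadth_fraction: float = 0.5,
) -> AbundanceTable:
    """Relative abundances from per-sample unique read counts per gene.

    ``read_counts``: samples x gene_id counts (missing genes count 0).
    Per symbiont, score = mean over its retained genes of count/length;
    per-sample abundance = 100 * score / sum(scores).  A symbiont is
    flagged detected in a sample when at least ``breadth_fraction`` of its
    retained genes receive >= 1 read.  Samples with zero total counts get
    all-NA rows.
    """
    retained = [g for g in genes if g.status == "retained"]
    if not retained:
        raise ValueError("no retained genes")
    counts = pd.DataFrame(read_counts).T if isinstance(read_counts, Mapping) else read_counts.copy()
    gene_ids = [g.gene_id for g in retained]
    for gid in gene_ids:
        if gid not in counts.columns:
            counts[gid] = 0
    counts = counts[gene_ids].astype(float)

    lengths = pd.Series({g.gene_id: g.length for g in retained})
    species_of = pd.Series({g.gene_id: g.symbiont for g in retained})
    per_gene_depth = counts / lengths

    species = sorted(set(species_of))
    scores = pd.DataFrame(
        {s: per_gene_depth.loc[:, species_of[species_of == s].index].mean(axis=1)
         for s in species}
    )
    detected = pd.DataFrame(
        {s: (counts.loc[:, species_of[species_of == s].index] >= 1).mean(axis=1)
         >= breadth_fraction
         for s in species}
    )
    totals = scores.sum(axis=1)
    abundances = 100.0 * scores.div(totals, axis=0)
    abundances[totals <= 0] = np.nan
    detected[totals <= 0] = False
    return AbundanceTable(
        abundances=abundances, detected=detected, gene_scores=per_gene_depth
    )


@dataclass
class SnpDensity:
    """Within-sample polymorphism density for one symbiont in one host."""

    sample_id: str
    symbiont: str
    n_within_sample_snps: int
    callable_kbp: float
    min_depth: int
    min_minor_fraction: float
    min_minor_reads: int

    @property
    def density(self) -> float:
        """SNPs per callable kbp; NaN when nothing is callable."""
        if self.callable_kbp <= 0:
            return float("nan")
        return self.n_within_sample_snps / self.callable_kbp


def within_sample_snp_density(
    sample: SampleSiteData,
    symbiont: str,
    min_depth: int = 10,
    min_minor_fraction: float = 0.1,
    min_minor_reads: int = 2,
) -> SnpDensity:
    """Count within-sample polymorphic sites per callable kbp.

    Callable sites reach ``min_depth``; a within-sample SNP is a callable
    site whose minor (second most observed) allele reaches both
    ``min_minor_fraction`` of the depth and ``min_minor_reads`` reads.
    The denominator is callable kbp, not total reference kbp, so sparse
    coverage does not deflate the estimate.
    """
    if sample.counts is None:
        raise ValueError("within-sample SNP density needs raw allele counts")
    counts = np.sort(sample.counts, axis=1)  # ascending per site
    depth = sample.counts.sum(axis=1)
    callable_mask = depth >= min_depth
    minor = counts[:, 2]  # second-largest count
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, minor / np.maximum(depth, 1), 0.0)
    snp = callable_mask & (minor >= min_minor_reads) & (frac >= min_minor_fraction)
    return SnpDensity(
        sample_id=sample.sample_id,
        symbiont=symbiont,
        n_within_sample_snps=int(snp.sum()),
        callable_kbp=float(callable_mask.sum()) / 1000.0,
        min_depth=min_depth,
        min_minor_fraction=min_minor_fraction,
        min_minor_reads=min_minor_reads,
    )
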