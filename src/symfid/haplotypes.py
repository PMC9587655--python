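"""COI-style haplotype collapsing and a minimum-spanning haplotype network.

Aligned marker-gene sequences (e.g. a mitochondrial COI core alignment)
are collapsed into haplotypes; identical sequences merge, with ambiguous
columns (N or gap) compared only on unambiguous positions.  The network is
a minimum spanning tree over the complete Hamming graph of haplotypes -- a
deliberately simple stand-in for statistical-parsimony networks that
preserves the analysis-relevant content: haplotype frequencies and
mutational step counts between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "Haplotype",
    "HaplotypeTable",
    "collapse_haplotypes",
    "min_spanning_network",
    "hamming",
]

AMBIGUOUS = set("N-")


def hamming(a: str, b: str) -> int:
    """Pairwise Hamming distance excluding ambiguous (N/gap) columns."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x not in AMBIGUOUS and y not in AMBIGUOUS
    )


def _compatible(a: str, b: str) -> bool:
    """Equal on every column where both sequences are unambiguous."""
    return hamming(a, b) == 0


@dataclass
class Haplotype:
    haplotype_id: str
    representative: str
    members: list[str]  # sample ids

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]
    locations: dict[str, str] = field(default_factory=dict)  # sample -> location

    @property
    def n_samples(self) -> int:
        return sum(h.frequency for h in self.haplotypes)

    def frequency_by_location(self, haplotype_id: str) -> dict[str, int]:
        hap = next(h for h in self.haplotypes if h.haplotype_id == haplotype_id)
        out: dict[str, int] = {}
        for sid in hap.members:
            loc = self.locations.get(sid, "unknown")
            out[loc] = out.get(loc, 0) + 1
        return out


def collapse_haplotypes(
    sequences: Sequence[str],
    sample_ids: Sequence[str],
    locations: dict[str, str] | None = None,
) -> HaplotypeTable:
    """Collapse equal-length aligned sequences into haplotypes.

    Sequences are merged greedily in input order into the first existing
    haplotype they are compatible with (identical on all mutually
    unambiguous columns); a cluster's representative is upgraded to the
    member with the fewest ambiguous positions.  Ids are assigned by
    descending frequency, ties by representative sequence.
    """
    if len(sequences) != len(sample_ids):
        raise ValueError("sequences and sample_ids must align")
    if not sequences:
        raise ValueError("no sequences")
    length = len(sequences[0])
    allowed = set("ACGTN-")
    for seq in sequences:
        if len(seq) != length:
            raise ValueError("unequal sequence lengths")
        if not set(seq) <= allowed:
            raise ValueError("alphabet restricted to A,C,G,T,N,-")

    clusters: list[tuple[str, list[str]]] = []  # (representative, members)
    for seq, sid in zip(sequences, sample_ids):
        for k, (rep, members) in enumerate(clusters):
            if _compatible(seq, rep):
                members.append(sid)
                if sum(c in AMBIGUOUS for c in seq) < sum(
                    c in AMBIGUOUS for c in rep
                ):
                    clusters[k] = (seq, members)
                break
        else:
            clusters.append((seq, [sid]))

    ordered = sorted(clusters, key=lambda c: (-len(c[1]), c[0]))
    haplotypes = [
        Haplotype(haplotype_id=f"H{k + 1}", representative=rep, members=members)
        for k, (rep, members) in enumerate(ordered)
    ]
    return HaplotypeTable(haplotypes=haplotypes, locations=dict(locations or {}))


def min_spanning_network(
    table: HaplotypeTable,
) -> list[tuple[str, str, int]]:
    """Minimum spanning tree on the complete Hamming graph of haplotypes.

    Kruskal's algorithm with deterministic tie-breaking: equal-weight
    edges prefer the pair with the higher combined frequency, then the
    lexicographically smallest id pair.  Returns edges
    ``(haplotype_i, haplotype_j, hamming_weight)``.
    """
    haps = table.haplotypes
    if len(haps) < 2:
        raise ValueError("need at least 2 haplotypes")
    edges = []
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            w = hamming(haps[i].representative, haps[j].representative)
            combined = haps[i].frequency + haps[j].frequency
            edges.append(
                (w, -combined, (haps[i].haplotype_id, haps[j].haplotype_id))
            )
    edges.sort()

    parent = {h.haplotype_id: h.haplotype_id for h in haps}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst: list[tuple[str, str, int]] = []
    for w, _, (a, b) in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            mst.append((a, b, w))
        if len(mst) == len(haps) - 1:
            break
    return mst


def to_dot(table: HaplotypeTable, edges: list[tuple[str, str, int]]) -> str:
    """Graphviz DOT text of the haplotype network (node size = frequency)."""
    lines = ["graph haplotype_network {"]
    for h in table.haplotypes:
        lines.append(f'  {h.haplotype_id} [label="{h.haplotype_id} (n={h.frequency})"];')
    for a, b, w in edges:
        lines.append(f'  {a} -- {b} [label="{w}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
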