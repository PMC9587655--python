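"""Forward-time simulation of a host population and its symbiont consortium.

The generator produces the ground truth against which every downstream
stage of the pipeline is verifiable: a host population structured into two
maternal (mitochondrial) lineages sampled at two locations, and a set of
haploid symbiont species transmitted down host generations either
vertically (probability ``fidelity`` per host generation, copying the
mother's genotype plus new mutations) or horizontally (drawing a genotype
from an evolving environmental pool, structured globally or per location).

Model assumptions
-----------------
* Transmission is strictly maternal and clonal per species: each host
  carries exactly one genotype of each symbiont it hosts (no
  recombination, no within-host strain mixtures).
* Maternal lines never cross between the two mitochondrial lineages; the
  lineages are founded with a fixed number of diagnostic differences.
* Host reproduction is Wright-Fisher within each lineage-by-location
  group, with a small per-generation migration probability between the
  two locations of the same lineage.
* The environmental pool of each species is a set of K free-living
  lineages evolving neutrally from the species founder after a burn-in,
  exchanging migrants between locations when structured per location.

Sequencing is emulated at the pileup level: per-site read depth is
Poisson, each read reports the true allele with probability ``1 - e`` and
each of the three wrong alleles with probability ``e/3``, and the emitted
Phred score is ``round(-10 log10 e)``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ALPHABET, PileupColumn, ReferenceGenome, SampleTable

__all__ = [
    "SymbiontSpec",
    "GroupSpec",
    "SimConfig",
    "SimTruth",
    "TransmissionEvent",
    "SitePileups",
    "simulate_population",
    "simulate_pileups",
    "inject_switch",
    "simulate_gene_read_counts",
    "simulate_two_strain_pileups",
    "default_config",
]

# wrong-allele index table: row t lists the three alleles != t
_OTHERS = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.int64)

MITO = "mito"  # reserved genome name for the host mitochondrion


@dataclass
class SymbiontSpec:
    """Parameters of one symbiont species in the simulation."""

    name: str
    genome_length: int
    fidelity: float  # probability of vertical transmission per host generation
    mutation_rate: float = 0.02  # substitutions per genome per generation
    relative_abundance: float = 1.0  # fraction of community (coverage share)
    mean_coverage: float = 5.0  # expected read depth per site
    presence_prob: float = 1.0  # probability a sampled host carries the species
    env_pool_structure: str = "global"  # "global" or "per-location"
    founder_divergence: int = 8  # fixed diffs between A- and B-associated founders

    def __post_init__(self) -> None:
        if not 0.0 <= self.fidelity <= 1.0:
            raise ValueError(f"{self.name}: fidelity must be in [0, 1]")
        if self.genome_length <= 0:
            raise ValueError(f"{self.name}: zero genome length")
        if self.mutation_rate < 0 or self.mean_coverage < 0:
            raise ValueError(f"{self.name}: rates must be >= 0")
        if self.env_pool_structure not in ("global", "per-location"):
            raise ValueError(f"{self.name}: bad env_pool_structure")


@dataclass
class GroupSpec:
    lineage: str  # "A" or "B"
    location: str
    n: int


@dataclass
class SimConfig:
    """Full configuration of one simulated study population."""

    groups: list[GroupSpec]
    symbiont_species: list[SymbiontSpec]
    n_generations: int = 200
    seed: int = 0
    mito_genome_length: int = 15000
    mito_mutation_rate: float = 0.02
    mito_founder_divergence: int = 25
    mito_mean_coverage: float = 20.0
    founder_diversity: float = 2.0  # expected private mutations per founding host
    host_migration_rate: float = 0.02
    env_pool_size: int = 8
    env_pool_burnin: int = 100
    env_pool_migration: float = 0.05

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not self.symbiont_species:
            raise ValueError("empty symbiont list")
        if not self.groups:
            raise ValueError("no host groups configured")
        for g in self.groups:
            if g.lineage not in ("A", "B"):
                raise ValueError(f"lineage must be A or B, got {g.lineage!r}")
        if self.mito_mutation_rate < 0 or self.founder_diversity < 0:
            raise ValueError("rates must be >= 0")

    @property
    def n_hosts(self) -> int:
        return sum(g.n for g in self.groups)

    @property
    def locations(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g.location not in seen:
                seen.append(g.location)
        return seen

    def species(self, name: str) -> SymbiontSpec:
        for s in self.symbiont_species:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class TransmissionEvent:
    generation: int
    host: str
    symbiont: str
    kind: str  # "vertical" | "horizontal"
    n_mutations: int


@dataclass
class SimTruth:
    """Ground truth of one simulated population.

    Genotypes are stored as full sequences (integer-coded A=0..T=3) for
    every sampled host; the event log covers every non-founder inheritance
    of every symbiont at every generation.
    """

    config: SimConfig
    sample_table: SampleTable
    mito_genotypes: dict[str, np.ndarray]
    symbiont_genotypes: dict[str, dict[str, np.ndarray]]  # species -> host -> seq
    carriers: dict[str, list[str]]  # species -> sampled hosts carrying it
    references: dict[str, ReferenceGenome]  # founder reference per genome
    events: list[TransmissionEvent] = field(default_factory=list)

    def host_lineage(self, host_id: str) -> str:
        return self.sample_table.lineage_of(host_id)

    def genotype(self, genome: str, host_id: str) -> np.ndarray:
        if genome == MITO:
            return self.mito_genotypes[host_id]
        return self.symbiont_genotypes[genome][host_id]

    def horizontal_events(self, symbiont: str | None = None) -> list[TransmissionEvent]:
        return [
            e
            for e in self.events
            if e.kind == "horizontal" and (symbiont is None or e.symbiont == symbiont)
        ]

    def to_json(self) -> str:
        """Serialize lineage labels, carriage and the event log (not the
        per-host sequences) for provenance."""
        payload = {
            "sample_table": self.sample_table.frame.to_dict(orient="list"),
            "carriers": self.carriers,
            "events": [asdict(e) for e in self.events],
            "seed": self.config.seed,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


def _mutate(diffs: dict[int, int], n: int, length: int, root: np.ndarray, rng) -> None:
    """Apply ``n`` random substitutions to a sparse genotype in place."""
    for _ in range(n):
        pos = int(rng.integers(length))
        cur = diffs.get(pos, int(root[pos]))
        new = int(rng.integers(3))
        if new >= cur:
            new += 1
        diffs[pos] = new


def _materialize(root: np.ndarray, diffs: dict[int, int]) -> np.ndarray:
    seq = root.copy()
    if diffs:
        idx = np.fromiter(diffs.keys(), dtype=np.int64, count=len(diffs))
        val = np.fromiter(diffs.values(), dtype=np.uint8, count=len(diffs))
        seq[idx] = val
    return seq


def _founder_lineage_diffs(length: int, n_diffs: int, root: np.ndarray, rng) -> dict:
    """Fixed differences distinguishing the B founder from the A founder,
    at distinct positions."""
    positions = rng.choice(length, size=min(n_diffs, length), replace=False)
    diffs: dict[int, int] = {}
    for pos in positions:
        cur = int(root[int(pos)])
        new = int(rng.integers(3))
        if new >= cur:
            new += 1
        diffs[int(pos)] = new
    return diffs


def simulate_population(config: SimConfig) -> SimTruth:
    """Run the forward transmission simulation and return its ground truth.

    Fully reproducible from ``config.seed``: the same configuration run
    twice yields identical genotypes, carriage and event logs.
    """
    rng = np.random.default_rng(config.seed)
    locations = config.locations
    genomes: dict[str, dict] = {}

    # roots and lineage founders
    mito_root = rng.integers(0, 4, size=config.mito_genome_length).astype(np.uint8)
    mito_b = _founder_lineage_diffs(
        config.mito_genome_length, config.mito_founder_divergence, mito_root, rng
    )
    genomes[MITO] = {"root": mito_root, "B": mito_b, "length": config.mito_genome_length,
                     "rate": config.mito_mutation_rate}
    for spec in config.symbiont_species:
        root = rng.integers(0, 4, size=spec.genome_length).astype(np.uint8)
        b = _founder_lineage_diffs(
            spec.genome_length, max(spec.founder_divergence, 5), root, rng
        )
        genomes[spec.name] = {"root": root, "B": b, "length": spec.genome_length,
                              "rate": spec.mutation_rate}

    # environmental pools: per species, per location key ("global" collapses)
    pools: dict[str, dict[str, list[dict[int, int]]]] = {}
    for spec in config.symbiont_species:
        g = genomes[spec.name]
        keys = ["global"] if spec.env_pool_structure == "global" else locations
        pools[spec.name] = {}
        for key in keys:
            lineages = []
            for _ in range(config.env_pool_size):
                # pool lineages are founded from a lineage-A/B mixture and
                # diverge over the burn-in
                diffs = dict(g["B"]) if rng.random() < 0.5 else {}
                n = int(rng.poisson(spec.mutation_rate * config.env_pool_burnin))
                _mutate(diffs, n, g["length"], g["root"], rng)
                lineages.append(diffs)
            pools[spec.name][key] = lineages

    def pool_key(spec: SymbiontSpec, location: str) -> str:
        return "global" if spec.env_pool_structure == "global" else location

    # founding host generation: per group, hosts carry their lineage founder
    # genotypes plus private founder diversity
    species_names = [s.name for s in config.symbiont_species]
    population: dict[int, list[dict]] = {}
    for gi, grp in enumerate(config.groups):
        hosts = []
        for _ in range(grp.n):
            host = {"mito": dict(genomes[MITO]["B"]) if grp.lineage == "B" else {}}
            _mutate(
                host["mito"],
                int(rng.poisson(config.founder_diversity)),
                config.mito_genome_length,
                mito_root,
                rng,
            )
            for spec in config.symbiont_species:
                g = genomes[spec.name]
                diffs = dict(g["B"]) if grp.lineage == "B" else {}
                _mutate(
                    diffs,
                    int(rng.poisson(config.founder_diversity)),
                    g["length"],
                    g["root"],
                    rng,
                )
                host[spec.name] = diffs
            hosts.append(host)
        population[gi] = hosts

    # partner groups for migration: same lineage, other location
    partners: dict[int, list[int]] = {}
    for gi, grp in enumerate(config.groups):
        partners[gi] = [
            gj
            for gj, other in enumerate(config.groups)
            if gj != gi and other.lineage == grp.lineage
        ]

    events: list[TransmissionEvent] = []
    for gen in range(1, config.n_generations + 1):
        # pools evolve one generation
        for spec in config.symbiont_species:
            g = genomes[spec.name]
            for key, lineages in pools[spec.name].items():
                for diffs in lineages:
                    _mutate(diffs, int(rng.poisson(spec.mutation_rate)),
                            g["length"], g["root"], rng)
            if spec.env_pool_structure == "per-location" and len(locations) > 1:
                for li, loc in enumerate(locations):
                    if rng.random() < config.env_pool_migration:
                        other = locations[(li + 1) % len(locations)]
                        src = int(rng.integers(config.env_pool_size))
                        dst = int(rng.integers(config.env_pool_size))
                        pools[spec.name][loc][dst] = dict(pools[spec.name][other][src])

        new_population: dict[int, list[dict]] = {}
        for gi, grp in enumerate(config.groups):
            hosts = []
            for idx in range(grp.n):
                src_group = gi
                if partners[gi] and rng.random() < config.host_migration_rate:
                    src_group = partners[gi][int(rng.integers(len(partners[gi])))]
                mother = population[src_group][
                    int(rng.integers(len(population[src_group])))
                ]
                host_label = f"g{gen}:{grp.lineage}|{grp.location}:{idx}"
                child = {}
                n_mut = int(rng.poisson(config.mito_mutation_rate))
                child["mito"] = dict(mother["mito"])
                _mutate(child["mito"], n_mut, config.mito_genome_length, mito_root, rng)
                for spec in config.symbiont_species:
                    g = genomes[spec.name]
                    if rng.random() < spec.fidelity:
                        n = int(rng.poisson(spec.mutation_rate))
                        diffs = dict(mother[spec.name])
                        _mutate(diffs, n, g["length"], g["root"], rng)
                        events.append(
                            TransmissionEvent(gen, host_label, spec.name, "vertical", n)
                        )
                    else:
                        lineages = pools[spec.name][pool_key(spec, grp.location)]
                        diffs = dict(lineages[int(rng.integers(len(lineages)))])
                        events.append(
                            TransmissionEvent(gen, host_label, spec.name, "horizontal", 0)
                        )
                    child[spec.name] = diffs
                hosts.append(child)
            new_population[gi] = hosts
        population = new_population

    # sample the final generation
    rows = []
    mito_genotypes: dict[str, np.ndarray] = {}
    symbiont_genotypes: dict[str, dict[str, np.ndarray]] = {
        s: {} for s in species_names
    }
    final_ids: dict[tuple[int, int], str] = {}
    for gi, grp in enumerate(config.groups):
        for idx, host in enumerate(population[gi]):
            sid = f"{grp.lineage}-{grp.location}-{idx + 1:02d}"
            final_ids[(gi, idx)] = sid
            rows.append({"sample_id": sid, "lineage": grp.lineage,
                         "location": grp.location})
            mito_genotypes[sid] = _materialize(mito_root, host["mito"])
            for spec in config.symbiont_species:
                symbiont_genotypes[spec.name][sid] = _materialize(
                    genomes[spec.name]["root"], host[spec.name]
                )
    sample_table = SampleTable(pd.DataFrame(rows))

    # rewrite final-generation event labels to sample ids
    relabel = {
        f"g{config.n_generations}:{grp.lineage}|{grp.location}:{idx}": final_ids[(gi, idx)]
        for gi, grp in enumerate(config.groups)
        for idx in range(grp.n)
    }
    events = [
        TransmissionEvent(e.generation, relabel.get(e.host, e.host), e.symbiont,
                          e.kind, e.n_mutations)
        for e in events
    ]

    # carriage of each species by each sampled host
    carriers: dict[str, list[str]] = {}
    for spec in config.symbiont_species:
        carried = []
        for sid in sample_table.sample_ids:
            if rng.random() < spec.presence_prob:
                carried.append(sid)
        carriers[spec.name] = carried

    references = {MITO: ReferenceGenome(MITO, _decode(mito_root))}
    for spec in config.symbiont_species:
        references[spec.name] = ReferenceGenome(
            spec.name, _decode(genomes[spec.name]["root"])
        )

    return SimTruth(
        config=config,
        sample_table=sample_table,
        mito_genotypes=mito_genotypes,
        symbiont_genotypes=symbiont_genotypes,
        carriers=carriers,
        references=references,
        events=events,
    )


def _decode(seq: np.ndarray) -> str:
    return "".join(ALPHABET[b] for b in seq)


def inject_switch(
    truth: SimTruth, symbiont: str, donor_lineage: str, recipient_host: str
) -> SimTruth:
    """Replace one host's symbiont genotype by a contemporary genotype from a
    donor-lineage host, logging the replacement as a horizontal event.

    Reproduces the single observed host-switch pattern: a symbiont of one
    mitochondrial lineage's host falling inside the clade of the other
    lineage.  Modifies ``truth`` in place and returns it.
    """
    if symbiont not in truth.symbiont_genotypes:
        raise KeyError(f"unknown symbiont {symbiont!r}")
    if recipient_host not in truth.sample_table.sample_ids:
        raise KeyError(f"unknown host {recipient_host!r}")
    if recipient_host not in truth.carriers[symbiont]:
        raise ValueError(f"{recipient_host} does not carry {symbiont}")
    donors = [
        sid
        for sid in truth.carriers[symbiont]
        if truth.host_lineage(sid) == donor_lineage and sid != recipient_host
    ]
    if not donors:
        raise ValueError(f"no donor of lineage {donor_lineage} carries {symbiont}")
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [truth.config.seed, zlib.crc32(recipient_host.encode()) % (2**31)]
        )
    )
    donor = donors[int(rng.integers(len(donors)))]
    truth.symbiont_genotypes[symbiont][recipient_host] = truth.symbiont_genotypes[
        symbiont
    ][donor].copy()
    truth.events.append(
        TransmissionEvent(
            truth.config.n_generations, recipient_host, symbiont, "horizontal", 0
        )
    )
    return truth


# ---------------------------------------------------------------------------
# pileup simulation
# ---------------------------------------------------------------------------


@dataclass
class SitePileups:
    """Simulated pileup observations of one genome in one sample.

    Stores per-site allele counts; :meth:`columns` expands to decoded
    :class:`~symfid.io_formats.PileupColumn` objects (positions with zero
    depth are omitted, matching the pileup reader's contract).
    """

    sample_id: str
    ref_name: str
    counts: np.ndarray  # (L, 4) int32
    qual: int
    error_rate: float

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def columns(self) -> list[PileupColumn]:
        cols = []
        depth = self.depth
        for i in np.nonzero(depth)[0]:
            bases: list[str] = []
            for a in range(4):
                bases.extend(ALPHABET[a] * int(self.counts[i, a]))
            cols.append(
                PileupColumn(
                    sample_id=self.sample_id,
                    ref_name=self.ref_name,
                    pos=int(i) + 1,
                    bases=tuple(bases),
                    quals=tuple([self.qual] * len(bases)),
                )
            )
        return cols


def _phred(error_rate: float, cap: int = 60) -> int:
    if error_rate <= 0:
        return cap
    return min(cap, int(round(-10.0 * np.log10(error_rate))))


def _observe(seq: np.ndarray, mean_coverage: float, error_rate: float, rng) -> np.ndarray:
    """Vectorized sequencing of one genome: Poisson depth, symmetric errors."""
    L = seq.shape[0]
    depth = rng.poisson(mean_coverage, size=L)
    counts = np.zeros((L, 4), dtype=np.int32)
    if error_rate > 0:
        n_err = rng.binomial(depth, error_rate)
    else:
        n_err = np.zeros(L, dtype=np.int64)
    correct = depth - n_err
    idx = np.arange(L)
    counts[idx, seq] = correct
    if error_rate > 0 and n_err.sum() > 0:
        split = rng.multinomial(n_err, [1 / 3.0] * 3)
        np.add.at(counts, (idx[:, None], _OTHERS[seq]), split)
    return counts


def simulate_pileups(
    truth: SimTruth,
    symbiont: str,
    error_rate: float = 0.01,
    seed: int = 0,
    mean_coverage: float | None = None,
) -> dict[str, SitePileups]:
    """Emit per-host pileup observations for one genome.

    ``symbiont`` may be a species name or ``"mito"``.  Coverage defaults to
    the species' configured ``mean_coverage`` (``mito_mean_coverage`` for
    the mitochondrion).  Deterministic under ``seed``.
    """
    if not 0.0 <= error_rate < 0.75:
        raise ValueError("error_rate must be in [0, 0.75)")
    rng = np.random.default_rng(np.random.SeedSequence([truth.config.seed, seed]))
    qual = _phred(error_rate)
    out: dict[str, SitePileups] = {}
    if symbiont == MITO:
        cov = (
            truth.config.mito_mean_coverage if mean_coverage is None else mean_coverage
        )
        hosts = truth.sample_table.sample_ids
        genotypes = truth.mito_genotypes
    else:
        spec = truth.config.species(symbiont)
        cov = spec.mean_coverage if mean_coverage is None else mean_coverage
        hosts = truth.carriers[symbiont]
        genotypes = truth.symbiont_genotypes[symbiont]
    for sid in hosts:
        counts = _observe(genotypes[sid], cov, error_rate, rng)
        out[sid] = SitePileups(
            sample_id=sid,
            ref_name=symbiont,
            counts=counts,
            qual=qual,
            error_rate=error_rate,
        )
    return out


def simulate_two_strain_pileups(
    seq_major: np.ndarray,
    seq_minor: np.ndarray,
    minor_fraction: float,
    mean_coverage: float,
    error_rate: float,
    seed: int = 0,
    sample_id: str = "sample",
    ref_name: str = "ref",
) -> SitePileups:
    """Within-host strain mixture: reads drawn from two genotypes.

    Used to exercise the within-sample SNP-density estimator; the main
    simulation keeps each host single-strain.
    """
    if seq_major.shape != seq_minor.shape:
        raise ValueError("strain genomes must have equal length")
    rng = np.random.default_rng(seed)
    L = seq_major.shape[0]
    depth = rng.poisson(mean_coverage, size=L)
    from_minor = rng.binomial(depth, minor_fraction)
    counts = np.zeros((L, 4), dtype=np.int32)
    for seq, n_reads in ((seq_major, depth - from_minor), (seq_minor, from_minor)):
        if error_rate > 0:
            n_err = rng.binomial(n_reads, error_rate)
        else:
            n_err = np.zeros(L, dtype=np.int64)
        idx = np.arange(L)
        counts[idx, seq] += (n_reads - n_err).astype(np.int32)
        if error_rate > 0 and n_err.sum() > 0:
            split = rng.multinomial(n_err, [1 / 3.0] * 3)
            np.add.at(counts, (idx[:, None], _OTHERS[seq]), split)
    return SitePileups(
        sample_id=sample_id,
        ref_name=ref_name,
        counts=counts,
        qual=_phred(error_rate),
        error_rate=error_rate,
    )


def simulate_gene_read_counts(
    gene_lengths: dict[str, dict[str, int]],
    abundances: dict[str, float],
    n_reads: int,
    seed: int = 0,
) -> dict[str, int]:
    """Assign ``n_reads`` to single-copy genes of a symbiont community.

    ``abundances`` are coverage shares (per-gene read depth shares): a read
    lands on gene *g* of species *s* with probability proportional to
    ``abundance_s * length_g``, so that mean per-gene depth recovers the
    configured composition.
    """
    rng = np.random.default_rng(seed)
    gene_ids: list[str] = []
    weights: list[float] = []
    for species in sorted(gene_lengths):
        a = abundances.get(species, 0.0)
        for gid in sorted(gene_lengths[species]):
            gene_ids.append(gid)
            weights.append(a * gene_lengths[species][gid])
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("all assignment weights are zero")
    counts = rng.multinomial(n_reads, w / w.sum())
    return dict(zip(gene_ids, (int(c) for c in counts)))


# ---------------------------------------------------------------------------
# default study-scale configuration
# ---------------------------------------------------------------------------

#: (name, relative abundance, per-generation fidelity, presence probability)
#: The abundance spread follows the observed consortium composition: two
#: dominant sulphur oxidizers, four lower-abundance sulphate reducers (one
#: nearly absent) and a rare spirochete; fidelity decreases with abundance.
DEFAULT_SPECIES = [
    ("Thiosymbion", 0.42, 1.00, 1.00, "global"),
    ("Gamma3", 0.28, 0.95, 1.00, "per-location"),
    ("Delta4", 0.15, 0.30, 0.84, "per-location"),
    ("Delta1b", 0.06, 0.60, 0.57, "per-location"),
    ("Delta1a", 0.05, 0.60, 0.46, "global"),
    ("Spirochete", 0.03, 0.00, 1.00, "global"),
    ("Delta3", 0.003, 0.50, 0.075, "global"),
]


def default_config(
    seed: int = 0,
    n_per_group: int = 20,
    genome_length: int = 20000,
    total_coverage: float = 50.0,
    n_generations: int = 200,
    locations: Sequence[str] = ("SantAndrea", "Cavoli"),
) -> SimConfig:
    """Study-scale default: 80 hosts in 4 lineage-by-location groups of 20,
    7 symbiont species whose coverage tracks relative abundance."""
    groups = [
        GroupSpec(lineage, loc, n_per_group)
        for lineage in ("A", "B")
        for loc in locations
    ]
    species = [
        SymbiontSpec(
            name=name,
            genome_length=genome_length,
            fidelity=fidelity,
            relative_abundance=abundance,
            mean_coverage=total_coverage * abundance,
            presence_prob=presence,
            env_pool_structure=pool,
        )
        for name, abundance, fidelity, presence, pool in DEFAULT_SPECIES
    ]
    return SimConfig(groups=groups, symbiont_species=species,
                     n_generations=n_generations, seed=seed)
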