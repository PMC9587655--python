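"""End-to-end orchestration: pileups -> SNPs -> distances -> trees ->
fidelity report.

The chain runs once per genome (the host mitochondrion plus each symbiont
species): posterior genotype matrix at SNP sites, expected distance matrix
with site-resampling bootstrap, neighbor-joining tree with bipartition
support, then the fidelity statistics of each symbiont against the
mitochondrial reference: pair-category distance tests, Mantel
co-divergence, and tree congruence.  Symbionts carried by too few hosts,
or with too few usable samples after the lateral-coverage cutoff, are
skipped and reported as insufficient rather than failing the run.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .distances import DistanceMatrix, bootstrap_distance_matrices, distance_matrix
from .fidelity_stats import (
    FidelityReport,
    FidelityRow,
    build_report,
    classify_pairs,
    congruence_score,
    kruskal_dunn,
    mantel_test,
)
from .genotype_model import (
    InsufficientDataError,
    PosteriorGenotypeMatrix,
    SampleSiteData,
    select_snp_sites,
)
from .io_formats import SampleTable, write_sample_table
from .phylogeny import PhyloTree, bootstrap_support, build_nj_tree, to_newick
from .synthetic_data import MITO, SimConfig, SimTruth, simulate_pileups, simulate_population

__all__ = [
    "Thresholds",
    "GenomeAnalysis",
    "PipelineResult",
    "analyze_genome",
    "run_simulated_pipeline",
    "load_run_config",
]


@dataclass
class Thresholds:
    """All tunable cutoffs of the chain, with the defaults used throughout:
    SNP p < 0.01 at sites covered >= 1x in all samples, lateral-coverage
    sample cutoff 0.10, >= 8 hosts per analysed symbiont, 100 bootstrap
    replicates and 999 Mantel permutations."""

    snp_p: float = 0.01
    min_all_sample_coverage: int = 1
    lateral_coverage_cutoff: float = 0.10
    min_hosts: int = 8
    det_min_depth: int = 5
    boot_reps: int = 100
    n_perm: int = 999
    null: str = "chi2"

    def validate(self) -> None:
        if not 0 < self.snp_p <= 1:
            raise ValueError("snp_p must be in (0, 1]")
        if not 0 <= self.lateral_coverage_cutoff <= 1:
            raise ValueError("lateral_coverage_cutoff must be in [0, 1]")
        if self.min_hosts < 3 or self.boot_reps < 0 or self.n_perm < 1:
            raise ValueError("invalid threshold configuration")


@dataclass
class GenomeAnalysis:
    """Per-genome chain output (mitochondrion or one symbiont species)."""

    name: str
    posterior: PosteriorGenotypeMatrix
    dist: DistanceMatrix
    tree: PhyloTree
    bootstrap_trees: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.posterior.sample_ids)

    @property
    def n_snps(self) -> int:
        return self.posterior.n_sites


@dataclass
class PipelineResult:
    report: FidelityReport
    genomes: dict[str, GenomeAnalysis]
    skipped: dict[str, str]
    truth: SimTruth | None = None


def analyze_genome(
    name: str,
    samples: Sequence[SampleSiteData],
    thresholds: Thresholds,
    seed: int = 0,
) -> GenomeAnalysis:
    """SNP selection -> distance matrix -> bootstrapped NJ tree for one
    genome.  Raises :class:`InsufficientDataError` when too few samples
    survive or no SNP site is found."""
    if len(samples) < thresholds.min_hosts:
        raise InsufficientDataError(
            f"{name}: carried by {len(samples)} hosts "
            f"(minimum {thresholds.min_hosts})"
        )
    pgm = select_snp_sites(
        samples,
        lateral_coverage_cutoff=thresholds.lateral_coverage_cutoff,
        min_samples=thresholds.min_hosts,
        p_threshold=thresholds.snp_p,
        min_all_sample_coverage=thresholds.min_all_sample_coverage,
        null=thresholds.null,
    )
    if pgm.n_sites == 0:
        raise InsufficientDataError(f"{name}: no SNP site detected")
    dist = distance_matrix(pgm)
    tree = build_nj_tree(dist)
    if dist.n >= 4 and thresholds.boot_reps >= 1:
        reps = bootstrap_distance_matrices(pgm, thresholds.boot_reps, seed=seed)
        rep_trees = [build_nj_tree(r) for r in reps]
        tree = bootstrap_support(tree, rep_trees)
    return GenomeAnalysis(
        name=name,
        posterior=pgm,
        dist=dist,
        tree=tree,
        bootstrap_trees=thresholds.boot_reps,
    )


def _fidelity_row(
    name: str,
    analysis: GenomeAnalysis,
    mito: GenomeAnalysis,
    table: SampleTable,
    abundance: float,
    thresholds: Thresholds,
    seed: int,
) -> FidelityRow:
    row = FidelityRow(
        symbiont=name,
        n_hosts_analyzed=len(analysis.sample_ids),
        n_snp_sites=analysis.n_snps,
        relative_abundance=abundance,
    )
    sub_table = table.subset(analysis.sample_ids)

    cats = classify_pairs(sub_table, analysis.dist, seed=seed)
    if len(cats) >= 2:
        kd = kruskal_dunn({c: s.distances for c, s in cats.items()})
        row.kruskal_H = kd.H
        row.kruskal_p = kd.p_value
        for _, r in kd.dunn.iterrows():
            pair = {r["group1"], r["group2"]}
            if pair == {"within", "mito"}:
                row.mito_effect_p = float(r["p_adj"])
            elif pair == {"within", "location"}:
                row.location_effect_p = float(r["p_adj"])

    common = [s for s in analysis.sample_ids if s in mito.dist.labels]
    if len(common) >= 4:
        m = mantel_test(
            mito.dist.subset(common),
            analysis.dist.subset(common),
            n_perm=thresholds.n_perm,
            seed=seed,
        )
        row.mantel_r = m.r
        row.mantel_p = m.p_value

    if len(analysis.sample_ids) >= 4:
        row.congruence_fraction, row.discordant_hosts = congruence_score(
            analysis.tree, sub_table
        )
    return row


def run_simulated_pipeline(
    config: SimConfig,
    error_rate: float = 0.01,
    thresholds: Thresholds | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    species: Sequence[str] | None = None,
) -> PipelineResult:
    """Simulate a population and run the full chain on every genome.

    ``species`` restricts the analysis to a subset of the configured
    symbionts (the mitochondrion always runs).  With ``out_dir`` set, the
    report, per-genome trees and distance matrices, the sample table and a
    provenance record are written out.
    """
    thresholds = thresholds or Thresholds()
    thresholds.validate()
    truth = simulate_population(config)
    table = truth.sample_table

    genomes: dict[str, GenomeAnalysis] = {}
    skipped: dict[str, str] = {}

    def data_for(genome: str) -> list[SampleSiteData]:
        pileups = simulate_pileups(truth, genome, error_rate=error_rate, seed=seed)
        return [
            SampleSiteData.from_counts(p.counts, error_rate, sample_id=sid)
            for sid, p in pileups.items()
        ]

    mito = analyze_genome(MITO, data_for(MITO), thresholds, seed=seed)
    genomes[MITO] = mito

    rows: list[FidelityRow] = []
    wanted = [s.name for s in config.symbiont_species]
    if species is not None:
        wanted = [n for n in wanted if n in set(species)]
    for si, name in enumerate(wanted):
        spec = config.species(name)
        try:
            analysis = analyze_genome(
                name, data_for(name), thresholds, seed=seed + si + 1
            )
        except InsufficientDataError as exc:
            skipped[name] = str(exc)
            rows.append(
                FidelityRow(
                    symbiont=name,
                    status="insufficient",
                    reason=str(exc),
                    relative_abundance=spec.relative_abundance,
                )
            )
            continue
        genomes[name] = analysis
        rows.append(
            _fidelity_row(
                name, analysis, mito, table, spec.relative_abundance,
                thresholds, seed=seed + si + 1,
            )
        )

    report = build_report(rows)
    result = PipelineResult(report=report, genomes=genomes, skipped=skipped,
                            truth=truth)
    if out_dir is not None:
        _write_artifacts(Path(out_dir), result, table, thresholds, seed)
    return result


def _write_artifacts(
    out: Path,
    result: PipelineResult,
    table: SampleTable,
    thresholds: Thresholds,
    seed: int,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "report.json").write_text(result.report.to_json())
    write_sample_table(table, out / "samples.tsv")
    for name, g in result.genomes.items():
        (out / f"{name}.nwk").write_text(to_newick(g.tree))
        (out / f"{name}.phylip.dist").write_text(g.dist.to_phylip())
    provenance = {
        "symfid_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "thresholds": asdict(thresholds),
        "skipped": result.skipped,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1,
                                                    sort_keys=True))


# ---------------------------------------------------------------------------
# YAML run configuration (CLI entry)
# ---------------------------------------------------------------------------


def load_run_config(path: str | Path) -> tuple[SimConfig, Thresholds, dict]:
    """Parse a YAML run configuration for the simulated pipeline.

    Recognized keys: ``simulate`` (either ``defaults: {...}`` forwarded to
    :func:`symfid.synthetic_data.default_config`, or explicit ``groups`` /
    ``species`` lists), ``thresholds`` (fields of :class:`Thresholds`),
    ``error_rate``, ``seed``, ``out``.
    """
    from .synthetic_data import GroupSpec, SymbiontSpec, default_config

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "simulate" not in raw:
        raise ValueError("run config must contain a 'simulate' section")
    sim = raw["simulate"]
    seed = int(raw.get("seed", 0))
    if "defaults" in sim:
        config = default_config(seed=seed, **(sim["defaults"] or {}))
    else:
        groups = [GroupSpec(**g) for g in sim["groups"]]
        species = [SymbiontSpec(**s) for s in sim["species"]]
        extra = {
            k: v
            for k, v in sim.items()
            if k not in ("groups", "species")
        }
        config = SimConfig(groups=groups, symbiont_species=species, seed=seed,
                           **extra)
    thresholds = Thresholds(**(raw.get("thresholds") or {}))
    meta = {
        "error_rate": float(raw.get("error_rate", 0.01)),
        "out": raw.get("out"),
        "seed": seed,
    }
    return config, thresholds, meta
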