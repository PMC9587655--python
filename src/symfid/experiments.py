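"""Packaged simulation experiments: the study designs used to validate the
pipeline end to end.

Each experiment fixes its own design constants (population layout,
genome lengths, coverages, generation depth) and exposes a seed so runs
are reproducible.  Design notes:

* The strict-fidelity experiment mirrors the study scale -- 80 hosts in
  four lineage-by-location groups of 20, a dominant strictly vertically
  transmitted symbiont at 20x coverage -- and measures host-symbiont tree
  congruence through the full chain.
* The fidelity-gradient and abundance-correlation experiments use a
  SHALLOW genealogy (two host generations from the founding population).
  Per-generation horizontal-transmission probabilities compound
  geometrically down a genealogy, so after many generations every
  fidelity below ~1 produces an almost fully scrambled symbiont
  population and intermediate fidelities become indistinguishable; a
  shallow genealogy maps the per-generation fidelity f onto a measurable
  fraction ~f^2 of intact vertical chains per host pair.
* Those two experiments also enlarge the environmental pool (32 lineages
  instead of the default 8): horizontal acquisition should act as an
  unstructured null, and a small pool lets chance alignment of pool
  clusters with host lineages inflate the Mantel correlation of a
  zero-fidelity species.
* Calibration experiments check empirical type-I error of the SNP
  likelihood-ratio test (in its target regime: many samples at ~1x
  coverage with noisy base calls), the Kruskal-Wallis test and the Mantel
  permutation test on null data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .abundance import GeneRecord, build_single_copy_reference, relative_abundance
from .distances import DistanceMatrix
from .fidelity_stats import kruskal_dunn, mantel_test
from .genotype_model import (
    InsufficientDataError,
    SampleSiteData,
    deterministic_genotypes,
    select_snp_sites,
    snp_scan,
)
from .pipeline import Thresholds, run_simulated_pipeline
from .synthetic_data import (
    GroupSpec,
    SimConfig,
    SymbiontSpec,
    _observe,
    default_config,
    simulate_gene_read_counts,
    simulate_population,
    simulate_pileups,
)

__all__ = [
    "strict_fidelity_experiment",
    "fidelity_gradient_experiment",
    "abundance_fidelity_experiment",
    "abundance_recovery_experiment",
    "method_comparison_experiment",
    "lrt_calibration",
    "kruskal_calibration",
    "mantel_calibration",
]

DOMINANT = "Thiosymbion"


def strict_fidelity_experiment(
    seed: int = 1,
    genome_length: int = 20000,
    coverage: float = 20.0,
    error_rate: float = 0.01,
) -> dict:
    """Full-chain congruence for a strictly vertically transmitted dominant
    symbiont in an 80-host population (4 groups of 20).

    The dominant species has fidelity 1.0 and lineage founders separated
    by well over 5 fixed differences; under strict maternal co-inheritance
    every host's symbiont must fall in the clade of its own mitochondrial
    lineage, i.e. congruence 100%.
    """
    config = default_config(seed=seed, n_per_group=20, genome_length=genome_length)
    config.species(DOMINANT).mean_coverage = coverage
    result = run_simulated_pipeline(
        config,
        error_rate=error_rate,
        thresholds=Thresholds(),
        seed=seed,
        species=[DOMINANT],
    )
    row = result.report.row(DOMINANT)
    return {
        "congruence_percent": 100.0 * row.congruence_fraction,
        "n_hosts": row.n_hosts_analyzed,
        "n_snp_sites": row.n_snp_sites,
        "mantel_r": row.mantel_r,
        "mantel_p": row.mantel_p,
        "mito_effect_p": row.mito_effect_p,
        "discordant_hosts": row.discordant_hosts,
    }


def _gradient_base(
    seed: int,
    abundance_fidelity: list[tuple[float, float]],
    genome_length: int,
    total_coverage: float,
) -> SimConfig:
    groups = [
        GroupSpec(lin, loc, 20) for lin in "AB" for loc in ("SantAndrea", "Cavoli")
    ]
    species = [
        SymbiontSpec(
            name=f"S{k}",
            genome_length=genome_length,
            fidelity=f,
            relative_abundance=a,
            mean_coverage=total_coverage * a,
            founder_divergence=10,
        )
        for k, (a, f) in enumerate(abundance_fidelity)
    ]
    return SimConfig(
        groups=groups,
        symbiont_species=species,
        n_generations=2,
        seed=seed,
        mito_genome_length=15000,
        env_pool_size=32,
    )


def fidelity_gradient_experiment(
    seed: int = 1,
    n_replicates: int = 20,
    genome_length: int = 50000,
    coverage: float = 12.0,
    n_perm: int = 199,
) -> dict:
    """Recovery of a transmission-fidelity gradient from Mantel R.

    Four equally covered species with per-generation fidelity
    {1.0, 0.95, 0.6, 0.0}; per replicate the ranking of Mantel R across
    species is compared with the fidelity ranking, and the zero-fidelity
    species' Mantel p is recorded (it should not reject the null).
    """
    fidelities = (1.0, 0.95, 0.6, 0.0)
    thresholds = Thresholds(boot_reps=0, n_perm=n_perm)
    replicates = []
    for rep in range(n_replicates):
        config = _gradient_base(
            seed * 10_000 + rep,
            [(0.25, f) for f in fidelities],
            genome_length,
            coverage * 4.0,
        )
        result = run_simulated_pipeline(
            config, error_rate=0.01, thresholds=thresholds, seed=seed + rep
        )
        rs = [result.report.row(f"S{k}").mantel_r for k in range(4)]
        ps = [result.report.row(f"S{k}").mantel_p for k in range(4)]
        replicates.append(
            {
                "mantel_r": rs,
                "mantel_p": ps,
                "rank_correct": bool(rs[0] > rs[1] > rs[2] > rs[3]),
                "null_nonsignificant": bool(ps[3] > 0.05),
            }
        )
    return {
        "fidelities": list(fidelities),
        "replicates": replicates,
        "n_rank_correct": sum(r["rank_correct"] for r in replicates),
        "n_null_nonsignificant": sum(r["null_nonsignificant"] for r in replicates),
        "n_replicates": n_replicates,
    }


def abundance_fidelity_experiment(
    seed: int = 1,
    n_replicates: int = 20,
    genome_length: int = 30000,
) -> dict:
    """Positive abundance/co-divergence correlation under coverage that
    tracks abundance and fidelity that increases with abundance."""
    abundance_fidelity = [(0.45, 1.0), (0.27, 0.95), (0.20, 0.6), (0.08, 0.0)]
    thresholds = Thresholds(boot_reps=0, n_perm=199)
    taus = []
    for rep in range(n_replicates):
        config = _gradient_base(
            seed * 20_000 + rep, abundance_fidelity, genome_length, 50.0
        )
        result = run_simulated_pipeline(
            config, error_rate=0.01, thresholds=thresholds, seed=seed + rep
        )
        taus.append(result.report.kendall_tau)
    return {
        "taus": taus,
        "n_positive": int(sum(t > 0 for t in taus)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# abundance recovery
# ---------------------------------------------------------------------------

RECOVERY_COMPOSITION = {
    "Thiosymbion": 42.0,
    "Gamma3": 28.0,
    "Delta4": 15.0,
    "Delta1b": 6.0,
    "Delta1a": 5.0,
    "Spirochete": 3.0,
    "Delta3": 0.3,
}


def abundance_recovery_experiment(
    seed: int = 1,
    n_reads: int = 200_000,
    genes_per_species: int = 10,
) -> dict:
    """Recovery of a 7-species composition from single-copy gene counts.

    Random gene sets (lengths 600-1200 bp) are filtered through the
    duplicate/cross-identity purge, reads are assigned with per-gene depth
    proportional to the configured composition, and the unique-assignment
    estimator is compared against the truth.
    """
    rng = np.random.default_rng(seed)
    records = []
    for species in sorted(RECOVERY_COMPOSITION):
        for k in range(genes_per_species):
            length = int(rng.integers(600, 1201))
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
            records.append(
                GeneRecord(symbiont=species, gene_id=f"{species}|g{k:02d}", seq=seq)
            )
    genes = build_single_copy_reference(records)
    gene_lengths = {}
    for g in genes:
        if g.status == "retained":
            gene_lengths.setdefault(g.symbiont, {})[g.gene_id] = g.length
    abundances = {s: v / 100.0 for s, v in RECOVERY_COMPOSITION.items()}
    counts = simulate_gene_read_counts(gene_lengths, abundances, n_reads, seed=seed)
    table = relative_abundance({"sample1": counts}, genes)
    recovered = {s: table.of("sample1", s) for s in RECOVERY_COMPOSITION}
    errors = {s: recovered[s] - RECOVERY_COMPOSITION[s] for s in RECOVERY_COMPOSITION}
    max_err = max(
        abs(e) for s, e in errors.items() if RECOVERY_COMPOSITION[s] >= 1.0
    )
    return {
        "true_percent": dict(RECOVERY_COMPOSITION),
        "recovered_percent": recovered,
        "errors": errors,
        "max_abs_error_major": max_err,
        "n_reads": n_reads,
    }


# ---------------------------------------------------------------------------
# probabilistic vs deterministic method comparison
# ---------------------------------------------------------------------------


def method_comparison_experiment(
    seed: int = 1,
    mean_coverage: float = 2.0,
    error_rate: float = 0.01,
    genome_length: int = 30000,
    n_per_group: int = 3,
) -> dict:
    """Sample and SNP-site yield of the probabilistic vs the deterministic
    branch on one simulated symbiont at a given coverage.

    Returns retained-sample and SNP counts for both branches plus the two
    SNP position sets (for the high-coverage identity check).
    """
    groups = [
        GroupSpec(lin, loc, n_per_group)
        for lin in "AB"
        for loc in ("SantAndrea", "Cavoli")
    ]
    species = [
        SymbiontSpec(
            name="S",
            genome_length=genome_length,
            fidelity=1.0,
            mean_coverage=mean_coverage,
            founder_divergence=10,
        )
    ]
    config = SimConfig(
        groups=groups, symbiont_species=species, n_generations=100, seed=seed,
        mito_genome_length=10000,
    )
    truth = simulate_population(config)
    pileups = simulate_pileups(truth, "S", error_rate=error_rate, seed=seed)
    samples = [
        SampleSiteData.from_counts(p.counts, error_rate, sample_id=sid)
        for sid, p in pileups.items()
    ]
    try:
        pgm = select_snp_sites(samples, min_samples=3)
        prob_samples = len(pgm.sample_ids)
        prob_snps = set(int(p) for p in pgm.positions)
    except InsufficientDataError:
        prob_samples, prob_snps = 0, set()
    try:
        det = deterministic_genotypes(samples, min_depth=5, min_samples=3)
        det_samples = len(det.sample_ids)
        det_snps = set(int(p) for p in det.snp_positions)
    except InsufficientDataError:
        det_samples, det_snps = 0, set()
    return {
        "mean_coverage": mean_coverage,
        "prob_samples": prob_samples,
        "prob_snps": len(prob_snps),
        "det_samples": det_samples,
        "det_snps": len(det_snps),
        "prob_snp_positions": prob_snps,
        "det_snp_positions": det_snps,
    }


# ---------------------------------------------------------------------------
# statistical calibration
# ---------------------------------------------------------------------------


def lrt_calibration(
    seed: int = 1,
    n_samples: int = 80,
    mean_coverage: float = 1.0,
    error_rate: float = 0.05,
    n_sites: int = 20000,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the SNP LRT on monomorphic truth.

    Evaluated in the method's target regime -- many samples at ~1x
    coverage with noisy base calls -- where duplicate sequencing errors
    can mimic low-frequency alleles, using the boundary-corrected null
    (the plain chi-square null is strictly more conservative).  Sites with
    at least two covered samples count as replicates.
    """
    rng = np.random.default_rng(seed)
    seq = rng.integers(0, 4, size=n_sites).astype(np.uint8)
    samples = [
        SampleSiteData.from_counts(
            _observe(seq, mean_coverage, error_rate, rng), error_rate, f"s{i}"
        )
        for i in range(n_samples)
    ]
    scan = snp_scan(samples, min_all_sample_coverage=0, null="mixture")
    scan_default = snp_scan(samples, min_all_sample_coverage=0, null="chi2")
    n_covered = np.stack([s.depth > 0 for s in samples]).sum(axis=0)
    mask = n_covered >= 2
    return {
        "n_sites_tested": int(mask.sum()),
        "rejection_rate": float((scan.p_value[mask] < alpha).mean()),
        "rejection_rate_default_null": float(
            (scan_default.p_value[mask] < alpha).mean()
        ),
        "snp_rate_default": float((scan_default.p_value[mask] < 0.01).mean()),
        "alpha": alpha,
    }


def kruskal_calibration(
    seed: int = 1, n_reps: int = 5000, group_size: int = 10, alpha: float = 0.05
) -> dict:
    """Type-I error of the Kruskal-Wallis test on two iid normal groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        a = rng.normal(size=group_size)
        b = rng.normal(size=group_size)
        res = kruskal_dunn({"g1": a, "g2": b})
        rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}


def mantel_calibration(
    seed: int = 1, n_reps: int = 2000, n: int = 20, n_perm: int = 999,
    alpha: float = 0.05
) -> dict:
    """Type-I error of the one-sided Mantel permutation test on pairs of
    independent random distance matrices."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n)]

    def random_matrix() -> DistanceMatrix:
        M = rng.random((n, n))
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 0.0)
        return DistanceMatrix(labels=labels, D=M, n_sites=1)

    rejections = 0
    for rep in range(n_reps):
        D1 = random_matrix()
        D2 = random_matrix()
        res = mantel_test(D1, D2, n_perm=n_perm, seed=seed * 100_000 + rep)
        rejections += res.p_value <= alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}
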