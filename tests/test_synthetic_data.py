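"""Simulator ground-truth contracts: determinism, transmission modes,
sequencing model and mutation statistics."""

import numpy as np
import pytest
from scipy import stats

from symfid.synthetic_data import (
    GroupSpec,
    SimConfig,
    SymbiontSpec,
    default_config,
    inject_switch,
    simulate_pileups,
    simulate_population,
)


def small_config(seed=0, fidelity=1.0, n_generations=30, n_per_group=5,
                 genome_length=2000, **kwargs):
    groups = [GroupSpec(lin, loc, n_per_group) for lin in "AB" for loc in ("X", "Y")]
    species = [
        SymbiontSpec(
            name="sym",
            genome_length=genome_length,
            fidelity=fidelity,
            mean_coverage=5.0,
            mutation_rate=0.05,
        )
    ]
    return SimConfig(
        groups=groups,
        symbiont_species=species,
        n_generations=n_generations,
        seed=seed,
        mito_genome_length=2000,
        **kwargs,
    )


class TestSimulatePopulation:
    def test_strict_fidelity_has_no_horizontal_events(self):
        truth = simulate_population(small_config(fidelity=1.0))
        assert truth.horizontal_events() == []
        # genotype partition mirrors the host lineage partition: mean
        # cross-lineage divergence exceeds mean within-lineage divergence
        ids = truth.sample_table.sample_ids
        lin = {s: truth.host_lineage(s) for s in ids}
        within, cross = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                d = np.mean(
                    truth.symbiont_genotypes["sym"][a]
                    != truth.symbiont_genotypes["sym"][b]
                )
                (within if lin[a] == lin[b] else cross).append(d)
        assert np.mean(cross) > np.mean(within)
        assert min(cross) > 0

    def test_zero_fidelity_makes_all_inheritance_horizontal(self):
        truth = simulate_population(small_config(fidelity=0.0))
        sym_events = [e for e in truth.events if e.symbiont == "sym"]
        assert sym_events and all(e.kind == "horizontal" for e in sym_events)

    def test_same_seed_reproduces_everything(self):
        t1 = simulate_population(small_config(seed=7))
        t2 = simulate_population(small_config(seed=7))
        assert t1.to_json() == t2.to_json()
        for sid in t1.sample_table.sample_ids:
            np.testing.assert_array_equal(
                t1.mito_genotypes[sid], t2.mito_genotypes[sid]
            )
            np.testing.assert_array_equal(
                t1.symbiont_genotypes["sym"][sid], t2.symbiont_genotypes["sym"][sid]
            )

    def test_founder_lineages_differ_by_at_least_five_sites(self):
        truth = simulate_population(small_config(fidelity=1.0, n_generations=1,
                                                 founder_diversity=0.0))
        a = [s for s in truth.sample_table.sample_ids if truth.host_lineage(s) == "A"]
        b = [s for s in truth.sample_table.sample_ids if truth.host_lineage(s) == "B"]
        diffs = np.sum(truth.mito_genotypes[a[0]] != truth.mito_genotypes[b[0]])
        assert diffs >= 5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="genome length"):
            SymbiontSpec(name="x", genome_length=0, fidelity=0.5)
        with pytest.raises(ValueError, match="empty symbiont"):
            SimConfig(groups=[GroupSpec("A", "X", 2)], symbiont_species=[])
        with pytest.raises(ValueError, match="fidelity"):
            SymbiontSpec(name="x", genome_length=10, fidelity=1.5)

    def test_vertical_mutation_counts_are_poisson(self):
        """Chi-square goodness of fit of per-branch mutation counts against
        the configured Poisson rate, over ~10,000 transmission events."""
        cfg = small_config(fidelity=1.0, n_generations=125, n_per_group=10,
                           genome_length=5000)
        cfg.symbiont_species[0].mutation_rate = 0.5
        truth = simulate_population(cfg)
        counts = np.array(
            [e.n_mutations for e in truth.events
             if e.symbiont == "sym" and e.kind == "vertical"]
        )
        assert counts.size >= 4500
        edges = [0, 1, 2, 3]
        observed = [np.sum(counts == k) for k in edges] + [np.sum(counts > 3)]
        pmf = stats.poisson.pmf(edges, 0.5)
        expected = list(counts.size * pmf) + [counts.size * (1 - pmf.sum())]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        p = stats.chi2.sf(chi2, df=len(observed) - 1)
        assert p > 0.01


class TestInjectSwitch:
    def test_switch_appends_single_horizontal_event(self):
        truth = simulate_population(small_config(fidelity=1.0))
        before = len(truth.horizontal_events())
        host = [s for s in truth.sample_table.sample_ids
                if truth.host_lineage(s) == "B"][0]
        donor_genos = {
            s: truth.symbiont_genotypes["sym"][s].copy()
            for s in truth.sample_table.sample_ids
            if truth.host_lineage(s) == "A"
        }
        inject_switch(truth, "sym", donor_lineage="A", recipient_host=host)
        assert len(truth.horizontal_events()) == before + 1
        new = truth.symbiont_genotypes["sym"][host]
        assert any(np.array_equal(new, g) for g in donor_genos.values())

    def test_same_lineage_donor_still_logged_horizontal(self):
        truth = simulate_population(small_config(fidelity=1.0))
        host = truth.sample_table.sample_ids[0]
        lineage = truth.host_lineage(host)
        inject_switch(truth, "sym", donor_lineage=lineage, recipient_host=host)
        last = truth.events[-1]
        assert last.kind == "horizontal" and last.host == host

    def test_unknown_host_rejected(self):
        truth = simulate_population(small_config())
        with pytest.raises(KeyError):
            inject_switch(truth, "sym", "A", "nobody")


class TestSimulatePileups:
    def test_zero_coverage_produces_no_columns(self):
        truth = simulate_population(small_config())
        piles = simulate_pileups(truth, "sym", 0.01, seed=1, mean_coverage=0.0)
        assert all(len(p.columns()) == 0 for p in piles.values())

    def test_error_free_reads_match_truth(self):
        truth = simulate_population(small_config(genome_length=500))
        piles = simulate_pileups(truth, "sym", 0.0, seed=1, mean_coverage=50.0)
        for sid, p in piles.items():
            geno = truth.symbiont_genotypes["sym"][sid]
            observed_alleles = p.counts > 0
            expected = np.zeros_like(observed_alleles)
            expected[np.arange(geno.size), geno] = True
            # only the true allele is ever observed (where covered)
            assert not np.any(observed_alleles & ~expected)

    def test_poisson_depth_mean_within_three_standard_errors(self):
        cfg = small_config(genome_length=10000, n_per_group=1)
        truth = simulate_population(cfg)
        piles = simulate_pileups(truth, "sym", 0.01, seed=2, mean_coverage=10.0)
        depth = next(iter(piles.values())).depth
        se = np.sqrt(10.0 / depth.size)
        assert abs(depth.mean() - 10.0) <= 3 * se

    def test_deterministic_under_seed(self):
        truth = simulate_population(small_config())
        p1 = simulate_pileups(truth, "sym", 0.01, seed=9)
        p2 = simulate_pileups(truth, "sym", 0.01, seed=9)
        for sid in p1:
            np.testing.assert_array_equal(p1[sid].counts, p2[sid].counts)

    def test_error_rate_bounds_enforced(self):
        truth = simulate_population(small_config())
        with pytest.raises(ValueError, match="error_rate"):
            simulate_pileups(truth, "sym", 0.8, seed=0)

    def test_phred_encodes_error_rate(self):
        truth = simulate_population(small_config(genome_length=100))
        piles = simulate_pileups(truth, "sym", 0.01, seed=0)
        assert next(iter(piles.values())).qual == 20
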