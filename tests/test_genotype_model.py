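"""Likelihood model, posterior normalization, EM frequency estimation and
both SNP-detection branches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from symfid.genotype_model import (
    AlleleLikelihoods,
    InsufficientDataError,
    SampleSiteData,
    deterministic_genotypes,
    ml_minor_allele_frequency,
    posterior_probabilities,
    select_snp_sites,
    site_likelihoods,
    snp_scan,
    snp_test,
)
from symfid.io_formats import PileupColumn


def column(bases, quals, pos=1):
    return PileupColumn("s", "r", pos, tuple(bases), tuple(quals))


def certain(allele: str, depth: int = 20, q: int = 30) -> AlleleLikelihoods:
    return site_likelihoods(column(allele * depth, [q] * depth))


class TestSiteLikelihoods:
    def test_empty_column_is_uninformative(self):
        lik = site_likelihoods(None)
        np.testing.assert_array_equal(lik.loglik, np.zeros(4))
        assert lik.depth == 0

    def test_single_read_q20(self):
        lik = site_likelihoods(column("A", [20]))
        np.testing.assert_allclose(
            np.exp(lik.loglik), [0.99, 0.01 / 3, 0.01 / 3, 0.01 / 3], rtol=1e-12
        )

    def test_two_discordant_reads_q10(self):
        lik = site_likelihoods(column("AC", [10, 10]))
        expected = [0.9 * (0.1 / 3), 0.9 * (0.1 / 3), (0.1 / 3) ** 2, (0.1 / 3) ** 2]
        np.testing.assert_allclose(np.exp(lik.loglik), expected, rtol=1e-12)


class TestPosterior:
    def test_uninformative_site_is_uniform(self):
        np.testing.assert_allclose(
            posterior_probabilities(site_likelihoods(None)), [0.25] * 4
        )

    def test_single_strong_read(self):
        post = posterior_probabilities(site_likelihoods(column("A", [20])))
        assert post[0] == pytest.approx(0.99, abs=1e-12)

    @given(st.lists(st.floats(-500, 10), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_always_sums_to_one(self, loglik):
        post = posterior_probabilities(np.array(loglik))
        assert post.sum() == pytest.approx(1.0, abs=1e-9)
        assert (post >= 0).all()


class TestMinorFrequencyEM:
    def test_all_major_gives_zero_frequency(self):
        liks = [certain("A") for _ in range(8)]
        f, _ = ml_minor_allele_frequency(liks, "A", "C")
        assert f == pytest.approx(0.0, abs=1e-6)

    def test_balanced_split_gives_half(self, oracles):
        liks = [certain("A") for _ in range(5)] + [certain("C") for _ in range(5)]
        f, _ = ml_minor_allele_frequency(liks, "A", "C")
        assert f == pytest.approx(0.5, abs=1e-6)
        lin = np.exp(np.stack([l.loglik for l in liks]))
        lin /= lin.max(axis=1, keepdims=True)
        f_grid = oracles["grid_search_minor_freq"](lin[:, 0], lin[:, 1])
        assert f == pytest.approx(f_grid, abs=1e-6)

    def test_em_matches_fine_grid_on_noisy_data(self, oracles, rng):
        """EM against an independent fine-grid oracle on random mixed
        pileups."""
        for _ in range(5):
            liks = []
            for _ in range(12):
                depth = int(rng.integers(1, 6))
                bases = "".join(rng.choice(["A", "C"], size=depth,
                                           p=[0.7, 0.3]))
                quals = list(rng.integers(8, 35, size=depth))
                liks.append(site_likelihoods(column(bases, quals)))
            f, gain = ml_minor_allele_frequency(liks, "A", "C")
            lin = np.exp(
                np.stack([l.loglik for l in liks])
                - np.stack([l.loglik for l in liks]).max(axis=1, keepdims=True)
            )
            f_grid = oracles["grid_search_minor_freq"](lin[:, 0], lin[:, 1])
            assert f == pytest.approx(f_grid, abs=1e-6)
            assert gain >= -1e-9  # lnL(f_hat) can never fall below lnL(0)

    def test_requires_two_covered_samples(self):
        with pytest.raises(InsufficientDataError):
            ml_minor_allele_frequency([certain("A")], "A", "C")


class TestSnpTest:
    def test_monomorphic_deep_site_is_not_a_snp(self):
        call = snp_test([certain("A") for _ in range(10)])
        assert call.minor_freq == pytest.approx(0.0, abs=1e-6)
        assert call.lrt == pytest.approx(0.0, abs=1e-9)
        assert call.p_value == 1.0
        assert not call.is_snp

    def test_balanced_split_is_overwhelming(self):
        liks = [certain("A", depth=10) for _ in range(5)] + [
            certain("C", depth=10) for _ in range(5)
        ]
        call = snp_test(liks)
        assert call.p_value < 1e-10
        assert call.is_snp
        assert {call.major, call.minor} == {"A", "C"}

    def test_uncovered_sample_excludes_site(self):
        liks = (
            [certain("A", depth=10) for _ in range(5)]
            + [certain("C", depth=10) for _ in range(4)]
            + [site_likelihoods(None)]
        )
        call = snp_test(liks)
        assert not call.covered_by_all
        assert not call.is_snp

    def test_major_minor_tie_breaks_alphabetically(self):
        liks = [certain("G", depth=10) for _ in range(5)] + [
            certain("T", depth=10) for _ in range(5)
        ]
        call = snp_test(liks)
        assert (call.major, call.minor) == ("G", "T")


class TestSelectSnpSites:
    def build_samples(self, genotypes, error_rate=0.001, depth=20):
        """Deterministic high-coverage samples from integer genotypes."""
        S, L = genotypes.shape
        samples = []
        for i in range(S):
            counts = np.zeros((L, 4), dtype=np.int32)
            counts[np.arange(L), genotypes[i]] = depth
            samples.append(
                SampleSiteData.from_counts(counts, error_rate, f"s{i}")
            )
        return samples

    def test_matrix_shape_over_detected_sites(self):
        genotypes = np.zeros((6, 50), dtype=int)
        genotypes[:3, 10] = 1
        genotypes[:3, 30] = 2
        pgm = select_snp_sites(self.build_samples(genotypes))
        assert list(pgm.positions) == [11, 31]
        assert pgm.P.shape == (6, 2, 4)
        np.testing.assert_allclose(pgm.P.sum(axis=2), 1.0, atol=1e-9)

    def test_low_lateral_coverage_sample_dropped_then_recomputed(self):
        genotypes = np.zeros((6, 200), dtype=int)
        genotypes[:3, 50] = 1
        samples = self.build_samples(genotypes)
        starved = np.zeros((200, 4), dtype=np.int32)
        starved[0, 0] = 1  # 0.5% lateral coverage
        samples.append(SampleSiteData.from_counts(starved, 0.001, "starved"))
        pgm = select_snp_sites(samples, lateral_coverage_cutoff=0.10)
        assert "starved" in pgm.dropped_samples
        assert list(pgm.positions) == [51]
        assert "starved" not in pgm.sample_ids

    def test_monomorphic_genome_has_empty_site_set(self):
        genotypes = np.zeros((5, 100), dtype=int)
        pgm = select_snp_sites(self.build_samples(genotypes))
        assert pgm.n_sites == 0

    def test_too_few_samples_flags_insufficient(self):
        genotypes = np.zeros((2, 100), dtype=int)
        with pytest.raises(InsufficientDataError):
            select_snp_sites(self.build_samples(genotypes))


class TestDeterministicGenotypes:
    def test_fivefold_unanimous_site_is_callable_monomorphic(self):
        counts = np.zeros((10, 4), dtype=np.int32)
        counts[:, 0] = 5
        samples = [SampleSiteData.from_counts(counts, 0.01, f"s{i}")
                   for i in range(4)]
        det = deterministic_genotypes(samples, min_depth=5)
        assert det.positions.size == 10
        assert det.n_snps == 0

    def test_fourfold_site_is_not_callable(self):
        counts = np.full((1, 4), 0, dtype=np.int32)
        counts[0, 0] = 5
        low = counts.copy()
        low[0, 0] = 4
        samples = [
            SampleSiteData.from_counts(counts, 0.01, "deep1"),
            SampleSiteData.from_counts(counts, 0.01, "deep2"),
            SampleSiteData.from_counts(low, 0.01, "shallow"),
        ]
        det = deterministic_genotypes(
            samples, min_depth=5, lateral_coverage_cutoff=0.0
        )
        assert det.positions.size == 0

    def test_ambiguous_majority_masks_site(self):
        clean = np.zeros((2, 4), dtype=np.int32)
        clean[:, 0] = 10
        mixed = clean.copy()
        mixed[1] = [6, 4, 0, 0]  # 60% majority < 90%
        samples = [
            SampleSiteData.from_counts(clean, 0.01, "a"),
            SampleSiteData.from_counts(clean, 0.01, "b"),
            SampleSiteData.from_counts(mixed, 0.01, "c"),
        ]
        det = deterministic_genotypes(samples, min_depth=5)
        assert list(det.positions) == [1]

    def test_detects_fixed_difference(self):
        counts_a = np.zeros((5, 4), dtype=np.int32)
        counts_a[:, 0] = 8
        counts_b = counts_a.copy()
        counts_b[2] = [0, 8, 0, 0]
        samples = [
            SampleSiteData.from_counts(counts_a, 0.01, "a"),
            SampleSiteData.from_counts(counts_a, 0.01, "b"),
            SampleSiteData.from_counts(counts_b, 0.01, "c"),
        ]
        det = deterministic_genotypes(samples, min_depth=5)
        assert list(det.snp_positions) == [3]
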