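"""Haploid genotype likelihoods, posteriors and SNP detection.

The organisms genotyped here are haploid (bacterial symbionts, host
mitochondria), so the model works directly with single-allele genotypes:
per read *r* with base ``b_r`` and error probability ``e_r = 10^(-q_r/10)``,

    L(a) = prod_r [ 1 - e_r  if b_r == a  else  e_r / 3 ]

Posterior genotype probabilities use a uniform prior (which cancels in the
normalization).  A site is polymorphic (a SNP) when the maximum-likelihood
population minor-allele frequency ``f`` is significantly greater than zero
under a likelihood-ratio test:

    L(f) = prod_i [ f * L_i(minor) + (1 - f) * L_i(major) ]

``f`` is estimated by EM; the LRT statistic ``2 [ln L(f_hat) - ln L(0)]``
is referred to a chi-square distribution with one degree of freedom
(optionally the boundary-corrected 1/2 chi2_0 + 1/2 chi2_1 mixture, since
``f = 0`` lies on the boundary of the parameter space).

Alongside the probabilistic branch, :func:`deterministic_genotypes`
implements the conventional depth-thresholded majority-call genotyper used
for method comparison: it only calls sites deeply sequenced (default at
least fivefold) in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import ALPHABET, PileupColumn

__all__ = [
    "AlleleLikelihoods",
    "SampleSiteData",
    "SnpCall",
    "SnpScan",
    "PosteriorGenotypeMatrix",
    "InsufficientDataError",
    "site_likelihoods",
    "posterior_probabilities",
    "ml_minor_allele_frequency",
    "snp_test",
    "snp_scan",
    "select_snp_sites",
    "deterministic_genotypes",
    "DeterministicResult",
]

EM_START = 0.1
EM_TOL = 1e-8
EM_MAX_ITER = 200


class InsufficientDataError(RuntimeError):
    """Too few samples survive the coverage cutoffs to analyse a genome."""


@dataclass(frozen=True)
class AlleleLikelihoods:
    """Log-likelihood vector over (A, C, G, T) at one site of one sample."""

    loglik: np.ndarray  # (4,)
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not np.all(np.isfinite(self.loglik)):
            raise ValueError("log-likelihoods must be finite")


def site_likelihoods(column: PileupColumn | None) -> AlleleLikelihoods:
    """Per-allele log-likelihoods for one decoded pileup column.

    A zero-depth site (``None``) carries no information: all four
    log-likelihoods are zero.
    """
    if column is None or column.depth == 0:
        return AlleleLikelihoods(loglik=np.zeros(4), depth=0)
    ll = np.zeros(4)
    for base, q in zip(column.bases, column.quals):
        eps = 10.0 ** (-q / 10.0)
        eps = min(eps, 0.75)  # a read can never be informative beyond random
        row = np.full(4, np.log(eps / 3.0))
        row[ALPHABET.index(base)] = np.log1p(-eps)
        ll += row
    return AlleleLikelihoods(loglik=ll, depth=column.depth)


def posterior_probabilities(lik: AlleleLikelihoods | np.ndarray) -> np.ndarray:
    """Posterior over the four alleles under a uniform prior.

    Numerically stable via max-subtraction; an all-equal likelihood vector
    (zero-depth site) yields the uninformative (0.25, 0.25, 0.25, 0.25).
    """
    ll = lik.loglik if isinstance(lik, AlleleLikelihoods) else np.asarray(lik, float)
    shifted = ll - ll.max(axis=-1, keepdims=True)
    w = np.exp(shifted)
    return w / w.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# per-sample site data
# ---------------------------------------------------------------------------


@dataclass
class SampleSiteData:
    """All sites of one genome in one sample: depth, log-likelihoods and
    (when available) raw allele counts.

    The array layout is 0-based over the full reference length; positions
    reported to the outside are 1-based.
    """

    sample_id: str
    depth: np.ndarray  # (L,) int32
    loglik: np.ndarray  # (L, 4) float32; rows of zeros where depth == 0
    counts: np.ndarray | None = None  # (L, 4) int32

    def __post_init__(self) -> None:
        if self.loglik.shape != (self.depth.shape[0], 4):
            raise ValueError("loglik must have shape (L, 4)")

    @property
    def n_sites(self) -> int:
        return int(self.depth.shape[0])

    @property
    def lateral_coverage(self) -> float:
        """Fraction of reference sites covered by at least one read."""
        return float(np.mean(self.depth > 0))

    @classmethod
    def from_columns(
        cls, columns: Iterable[PileupColumn], ref_length: int, sample_id: str
    ) -> "SampleSiteData":
        depth = np.zeros(ref_length, dtype=np.int32)
        loglik = np.zeros((ref_length, 4), dtype=np.float32)
        counts = np.zeros((ref_length, 4), dtype=np.int32)
        for col in columns:
            if col.pos > ref_length:
                raise ValueError(
                    f"position {col.pos} beyond reference length {ref_length}"
                )
            i = col.pos - 1
            lik = site_likelihoods(col)
            depth[i] = lik.depth
            loglik[i] = lik.loglik
            counts[i] = col.base_counts()
        return cls(sample_id=sample_id, depth=depth, loglik=loglik, counts=counts)

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, error_rate: float, sample_id: str
    ) -> "SampleSiteData":
        """Vectorized construction when every read shares one error rate
        (the simulator's single-quality regime)."""
        counts = np.asarray(counts)
        eps = min(max(error_rate, 1e-6), 0.75)
        depth = counts.sum(axis=1).astype(np.int32)
        hit = np.log1p(-eps)
        miss = np.log(eps / 3.0)
        loglik = (counts * hit + (depth[:, None] - counts) * miss).astype(np.float32)
        loglik[depth == 0] = 0.0
        return cls(
            sample_id=sample_id,
            depth=depth,
            loglik=loglik,
            counts=counts.astype(np.int32),
        )


# ---------------------------------------------------------------------------
# allele-frequency EM and the SNP likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpCall:
    """Result of the polymorphism test at one site (1-based position)."""

    position: int
    major: str
    minor: str
    minor_freq: float
    lrt: float
    p_value: float
    covered_by_all: bool

    @property
    def is_snp(self) -> bool:
        return self.covered_by_all and self.p_value < 0.01

    def __post_init__(self) -> None:
        if self.major == self.minor:
            raise ValueError("major and minor allele must differ")


def _em_minor_frequency(
    lmaj: np.ndarray, lmin: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM for the minor-allele frequency at many sites at once.

    ``lmaj``/``lmin`` are linear-scale per-sample likelihoods of the major
    and minor allele, shape (S, L), each row pair scaled by a common
    per-sample-site constant (scaling cancels everywhere).  Returns
    ``(f_hat, lnL(f_hat), lnL(0))`` with the shared scaling constants
    removed, so only differences of the log-likelihoods are meaningful.
    """
    S, L = lmaj.shape
    f = np.full(L, EM_START)
    active = np.ones(L, dtype=bool)
    for _ in range(EM_MAX_ITER):
        if not active.any():
            break
        fa = f[active]
        num = fa * lmin[:, active]
        # the floor only matters when both scaled likelihoods underflowed
        den = np.maximum(num + (1.0 - fa) * lmaj[:, active], 1e-320)
        f_new = (num / den).mean(axis=0)
        moved = np.abs(f_new - fa) >= EM_TOL
        f[active] = f_new
        idx = np.nonzero(active)[0]
        active[idx[~moved]] = False
    ll_hat = np.log(np.maximum(f * lmin + (1.0 - f) * lmaj, 1e-320)).sum(axis=0)
    ll_zero = np.log(np.maximum(lmaj, 1e-320)).sum(axis=0)
    return f, ll_hat, ll_zero


def _scaled_top_likelihoods(
    loglik: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pick major/minor alleles by summed per-sample likelihood mass.

    ``loglik``: (S, L, 4).  Returns (major, minor) allele indices per site
    and the (S, L, 4) linear-scale likelihoods normalized per sample-site
    (so each sample's vector has max 1).  Ties in the summed mass are
    broken by alphabetical allele order (argsort stability).
    """
    shifted = loglik - loglik.max(axis=2, keepdims=True)
    lin = np.exp(shifted)
    mass = (lin / lin.sum(axis=2, keepdims=True)).sum(axis=0)  # (L, 4)
    # stable sort descending: negate, ties resolve to the lower allele index
    order = np.argsort(-mass, axis=1, kind="stable")
    return order[:, 0], order[:, 1], lin


@dataclass
class SnpScan:
    """Vectorized polymorphism scan over all sites of one genome."""

    positions: np.ndarray  # 1-based, all sites scanned
    major: np.ndarray  # allele index
    minor: np.ndarray
    minor_freq: np.ndarray
    lrt: np.ndarray
    p_value: np.ndarray
    covered_by_all: np.ndarray  # bool

    def snp_mask(self, p_threshold: float = 0.01) -> np.ndarray:
        return self.covered_by_all & (self.p_value < p_threshold)

    def calls(self, positions: Sequence[int] | None = None) -> list[SnpCall]:
        pos_set = None if positions is None else set(positions)
        out = []
        for k, pos in enumerate(self.positions):
            if pos_set is not None and int(pos) not in pos_set:
                continue
            out.append(
                SnpCall(
                    position=int(pos),
                    major=ALPHABET[int(self.major[k])],
                    minor=ALPHABET[int(self.minor[k])],
                    minor_freq=float(self.minor_freq[k]),
                    lrt=float(self.lrt[k]),
                    p_value=float(self.p_value[k]),
                    covered_by_all=bool(self.covered_by_all[k]),
                )
            )
        return out


def snp_scan(
    samples: Sequence[SampleSiteData],
    min_all_sample_coverage: int = 1,
    null: str = "chi2",
) -> SnpScan:
    """Run the minor-allele-frequency LRT at every reference site.

    ``null`` selects the LRT reference distribution: ``"chi2"`` (one df;
    conservative at the boundary) or ``"mixture"`` (the boundary-corrected
    1/2 chi2_0 + 1/2 chi2_1).
    """
    if null not in ("chi2", "mixture"):
        raise ValueError("null must be 'chi2' or 'mixture'")
    if len(samples) < 2:
        raise InsufficientDataError("need at least 2 samples")
    L = samples[0].n_sites
    for s in samples:
        if s.n_sites != L:
            raise ValueError("samples must share one reference length")
    depth = np.stack([s.depth for s in samples])  # (S, L)
    loglik = np.stack([s.loglik for s in samples]).astype(np.float64)  # (S, L, 4)
    covered = (depth >= min_all_sample_coverage).all(axis=0)

    major, minor, lin = _scaled_top_likelihoods(loglik)
    site_idx = np.arange(L)
    lmaj = lin[:, site_idx, major]  # (S, L)
    lmin = lin[:, site_idx, minor]

    f = np.zeros(L)
    lrt = np.zeros(L)
    # uncovered sites are never tested; restrict EM to covered sites
    cov_idx = np.nonzero(covered)[0]
    if cov_idx.size:
        f_c, ll_hat, ll_zero = _em_minor_frequency(lmaj[:, cov_idx], lmin[:, cov_idx])
        f[cov_idx] = f_c
        lrt[cov_idx] = np.maximum(0.0, 2.0 * (ll_hat - ll_zero))
    p = stats.chi2.sf(lrt, df=1)
    if null == "mixture":
        p = np.where(lrt == 0.0, 1.0, 0.5 * p)
    p[lrt == 0.0] = 1.0
    return SnpScan(
        positions=np.arange(1, L + 1),
        major=major,
        minor=minor,
        minor_freq=f,
        lrt=lrt,
        p_value=p,
        covered_by_all=covered,
    )


def ml_minor_allele_frequency(
    site_liks: Sequence[AlleleLikelihoods], major: str, minor: str
) -> tuple[float, float]:
    """EM estimate of the population minor-allele frequency at one site.

    Returns ``(f_hat, lnL(f_hat) - lnL(0))`` (the log-likelihood gain over
    the monomorphic model; per-sample scaling constants cancel).
    """
    covered = [sl for sl in site_liks if sl.depth >= 1]
    if len(covered) < 2:
        raise InsufficientDataError("need >= 2 covered samples")
    ll = np.stack([sl.loglik for sl in covered])[:, None, :]  # (S, 1, 4)
    lin = np.exp(ll - ll.max(axis=2, keepdims=True))
    a, b = ALPHABET.index(major), ALPHABET.index(minor)
    f, ll_hat, ll_zero = _em_minor_frequency(lin[:, :, a], lin[:, :, b])
    return float(f[0]), float(ll_hat[0] - ll_zero[0])


def snp_test(
    site_liks: Sequence[AlleleLikelihoods],
    position: int = 1,
    null: str = "chi2",
) -> SnpCall:
    """Single-site convenience wrapper around the vectorized scan."""
    depth = np.array([sl.depth for sl in site_liks])
    loglik = np.stack([sl.loglik for sl in site_liks])[:, None, :]
    samples = [
        SampleSiteData(
            sample_id=f"s{i}",
            depth=depth[i : i + 1].astype(np.int32),
            loglik=loglik[i].astype(np.float32),
        )
        for i in range(len(site_liks))
    ]
    scan = snp_scan(samples, null=null)
    call = scan.calls()[0]
    return SnpCall(
        position=position,
        major=call.major,
        minor=call.minor,
        minor_freq=call.minor_freq,
        lrt=call.lrt,
        p_value=call.p_value,
        covered_by_all=call.covered_by_all,
    )


# ---------------------------------------------------------------------------
# SNP-site selection and the posterior genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class PosteriorGenotypeMatrix:
    """Per-sample, per-SNP-site posterior probability vectors over the four
    alleles -- the pipeline's central intermediate."""

    sample_ids: list[str]
    positions: np.ndarray  # 1-based SNP positions
    P: np.ndarray  # (S, L_snp, 4)
    snp_calls: list[SnpCall] = field(default_factory=list)
    dropped_samples: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.P.shape[0] != len(self.sample_ids):
            raise ValueError("P rows must match sample_ids")
        if self.P.shape[1] != len(self.positions):
            raise ValueError("P columns must match positions")
        if self.P.size:
            sums = self.P.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("posterior vectors must sum to 1")

    @property
    def n_sites(self) -> int:
        return int(self.P.shape[1])

    def to_frame(self):
        """Long-format serialization (sample, position, P_A..P_T)."""
        import pandas as pd

        rows = []
        for i, sid in enumerate(self.sample_ids):
            for j, pos in enumerate(self.positions):
                rows.append(
                    [sid, int(pos)] + [float(v) for v in self.P[i, j]]
                )
        return pd.DataFrame(
            rows, columns=["sample_id", "position", "P_A", "P_C", "P_G", "P_T"]
        )


def select_snp_sites(
    samples: Sequence[SampleSiteData],
    lateral_coverage_cutoff: float = 0.10,
    min_samples: int = 3,
    p_threshold: float = 0.01,
    min_all_sample_coverage: int = 1,
    null: str = "chi2",
) -> PosteriorGenotypeMatrix:
    """Drop low-coverage samples, detect SNP sites among the rest, and
    assemble the posterior genotype matrix at those sites.

    Samples whose lateral coverage (fraction of reference sites with at
    least one read) falls below the cutoff are excluded first -- mirroring
    the exclusion of hosts with very low or missing reads for a symbiont.
    Fewer than ``min_samples`` survivors marks the genome as insufficient.
    """
    dropped = {
        s.sample_id: f"lateral coverage {s.lateral_coverage:.3f} < "
        f"{lateral_coverage_cutoff:.3f}"
        for s in samples
        if s.lateral_coverage < lateral_coverage_cutoff
    }
    retained = [s for s in samples if s.sample_id not in dropped]
    if len(retained) < min_samples:
        raise InsufficientDataError(
            f"only {len(retained)} samples at lateral coverage >= "
            f"{lateral_coverage_cutoff} (need {min_samples})"
        )
    scan = snp_scan(
        retained, min_all_sample_coverage=min_all_sample_coverage, null=null
    )
    mask = scan.snp_mask(p_threshold)
    idx = np.nonzero(mask)[0]
    loglik = np.stack([s.loglik for s in retained]).astype(np.float64)
    shifted = loglik[:, idx, :] - loglik[:, idx, :].max(axis=2, keepdims=True)
    lin = np.exp(shifted)
    P = lin / lin.sum(axis=2, keepdims=True)
    return PosteriorGenotypeMatrix(
        sample_ids=[s.sample_id for s in retained],
        positions=scan.positions[idx],
        P=P,
        snp_calls=scan.calls(positions=scan.positions[idx]),
        dropped_samples=dropped,
    )


# ---------------------------------------------------------------------------
# deterministic genotyping (method-comparison stand-in)
# ---------------------------------------------------------------------------


@dataclass
class DeterministicResult:
    """Majority-call genotypes at deeply covered sites."""

    sample_ids: list[str]
    positions: np.ndarray  # 1-based callable positions (no sample masked)
    calls: np.ndarray  # (S, L_callable) allele indices
    snp_positions: np.ndarray  # callable positions with >= 2 distinct calls

    @property
    def n_snps(self) -> int:
        return int(self.snp_positions.shape[0])


def deterministic_genotypes(
    samples: Sequence[SampleSiteData],
    min_depth: int = 5,
    min_fraction: float = 0.9,
    lateral_coverage_cutoff: float = 0.10,
    min_samples: int = 3,
) -> DeterministicResult:
    """Depth-thresholded majority-rule genotyping for method comparison.

    A sample is retained when at least ``lateral_coverage_cutoff`` of the
    reference reaches ``min_depth``.  A site is callable when every
    retained sample reaches ``min_depth`` there; the per-sample call is
    the majority base when its fraction reaches ``min_fraction``, else the
    site is dropped.  A SNP is a callable site with >= 2 distinct calls.
    """
    retained = [
        s
        for s in samples
        if s.counts is not None
        and float(np.mean(s.depth >= min_depth)) >= lateral_coverage_cutoff
    ]
    if len(retained) < min_samples:
        raise InsufficientDataError(
            f"only {len(retained)} samples reach {min_depth}x lateral coverage "
            f">= {lateral_coverage_cutoff}"
        )
    counts = np.stack([s.counts for s in retained])  # (S, L, 4)
    depth = counts.sum(axis=2)
    callable_all = (depth >= min_depth).all(axis=0)
    top = counts.argmax(axis=2)  # ties resolve to the lower allele index
    top_count = np.take_along_axis(counts, top[:, :, None], axis=2)[:, :, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top_count / np.maximum(depth, 1), 0.0)
    unambiguous = (frac >= min_fraction).all(axis=0)
    keep = callable_all & unambiguous
    idx = np.nonzero(keep)[0]
    calls = top[:, idx]
    polymorphic = (calls != calls[0]).any(axis=0)
    return DeterministicResult(
        sample_ids=[s.sample_id for s in retained],
        positions=idx + 1,
        calls=calls,
        snp_positions=idx[polymorphic] + 1,
    )
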