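# Methods

This note documents the statistical model, the simulator, the numerical
choices and the validation experiments behind `symfid`, including the
design decisions that were genuinely open and how they were settled.

## 1. Genotype model

All genotyped genomes are haploid (bacterial symbionts; the host
mitochondrion is treated as effectively haploid because it is maternally
inherited and homoplasmic at the analysed scale). Genotypes are therefore
modelled directly as single alleles over {A, C, G, T}; nothing emulates a
diploid homozygous-only model, which would be mathematically equivalent
for every likelihood used but harder to test.

Per site and sample, the per-read error model gives
`L(a) = prod_r [1 - e_r if b_r = a else e_r/3]` with
`e_r = 10^(-q_r/10)`, capped at 0.75 (a base call can never be worse than
uninformative). Likelihoods are computed and stored in log space;
zero-depth sites carry the all-zero log vector and a uniform posterior.
Posteriors use a uniform prior, so normalization is a stable
max-subtracted softmax of the log-likelihoods.

### SNP detection

The population minor-allele frequency `f` at a site maximizes
`L(f) = prod_i [f L_i(minor) + (1-f) L_i(major)]` over the retained
samples. Major and minor alleles are the two alleles with the largest
summed per-sample posterior mass; ties break alphabetically. `f` is
estimated by EM (start 0.1, tolerance 1e-8 on `|Δf|`, 200-iteration cap,
vectorized across sites with convergence masking); the start/tolerance
pair was chosen so EM agrees with an independent fine-grid search to
1e-6, which the test suite asserts. Per-sample likelihoods are rescaled
by their per-site maximum before the EM; the scaling cancels in the
update and in all likelihood differences. A floor of 1e-320 guards
against underflow at extreme depth.

The site is a SNP when (i) every retained sample covers it at ≥ 1× and
(ii) the LRT `2[ln L(f̂) − ln L(0)]` is significant at p < 0.01. The
default null is χ²₁ without boundary correction. Because `f = 0` lies on
the boundary of the parameter space, the asymptotically correct null is
the mixture `½χ²₀ + ½χ²₁`, available via `null="mixture"`; the plain χ²₁
default is strictly more conservative and matches common practice in
genotype-likelihood toolchains. In practice the test is conservative
under **either** null at moderate coverage: when the assumed error rate
matches the data, isolated sequencing errors are confidently explained by
the error model and the LRT piles up at zero. Near-nominal behaviour
appears only in the regime the method actually targets — many samples at
~1× coverage with noisy base calls — where two independent errors of the
same base can mimic a genuine low-frequency allele. The calibration
experiment (`lrt_calibration`) is therefore fixed at 80 samples, 1× mean
coverage and 5% base error, where the mixture-null type-I error is close
to nominal 0.05 and the default null stays below it.

### Sample exclusion

Samples whose lateral coverage (fraction of reference positions with at
least one read) is below 0.10 are dropped before SNP detection, and the
SNP set is recomputed over the remainder. The cutoff is configurable; a
genome left with fewer than `min_hosts` samples (default 8, i.e. roughly
two per host group) is reported as "insufficient" rather than analysed —
the same behaviour low-abundance symbionts trigger in real data.

### Deterministic branch

For method comparison, a conventional genotyper is included: a site is
callable only when **every** retained sample covers it at ≥ 5×
(configurable), the per-sample call is the majority base if it reaches
90% of the reads, and a SNP is a callable site with ≥ 2 distinct calls.
Sample retention for this branch requires 5× lateral coverage of ≥ 0.10.
At 2× mean coverage this branch retains essentially nothing while the
probabilistic branch still works; at 50× error-free coverage the two SNP
sets coincide exactly (both asserted by tests).

## 2. Distances, trees

Expected pairwise distance is the per-SNP-site expected mismatch under
independent posteriors. It is uncorrected (no Jukes-Cantor-style
transformation): the distances operate within species at divergences of
a few sites per genome, where multiple hits are negligible, and they are
normalized per SNP site. The implementation computes
`(L − Σ_s agreement_s)/L` so that point-mass posteriors reproduce a
brute-force Hamming count bit for bit. Self-distances are defined as 0.
Log scaling for display is left entirely to reporting.

Bootstrap replicates resample SNP sites with replacement (block length 1
— SNP sites are sparse across the genome, so independence is the natural
default), 100 replicates by default, seeded.

Trees are classical neighbor joining (Saitou–Nei Q criterion).
Justification for NJ over balanced minimal evolution with NNI: on
additive matrices both are consistent, the within-species matrices here
are near-additive and low-divergence, and classical NJ is fully
specifiable — ties in Q break on the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest leaf), so trees are
deterministic. Negative branch-length estimates are clamped to zero with
the deficit moved to the sibling edge, preserving the joined pair's
distance. Exact recovery of random additive matrices up to n = 32 (path
lengths to 1e-10) is asserted against an independent path-length oracle.
Bootstrap support of an internal edge is the percentage of replicate
trees containing the same bipartition. Maximum-likelihood trees are out
of scope; the distance trees carry the analysis.

The **basal split** of a tree is the bipartition induced by its longest
internal edge (ties: higher support, then lexicographically smallest
side). The **congruence score** assigns the two lineage labels to the two
sides so as to maximize matches and reports the matched fraction, with
the discordant hosts listed for manual review. For balanced binary labels
the score is floored at 0.5 by construction; its permutation null
concentrates near 0.5 (asserted by a Monte-Carlo test). This is a
deliberately simple formalization of "two clades, one per lineage" —
deeper clade structure is visible in the trees themselves.

## 3. Fidelity statistics

Host pairs are compared in three categories: *within* (same lineage, same
location), *mito* (different lineage, same location), *location* (same
lineage, different location). Pairs are matched randomly **without
replacement within a category** (each host used at most once per
category), seeded; disjointness is what makes the category samples
independent, which the weaker reading (no repeated pairs) would not
ensure. When a lineage is missing from a location, the restricted scheme
applies automatically: lineage contrasts use only locations where both
lineages occur, location contrasts only lineages present at both.

Distances across categories are compared with a tie-corrected
Kruskal–Wallis test and Dunn post hoc z-tests (tie-corrected pooled
variance) under Benjamini–Hochberg adjustment; the reported
`mito_effect_p` / `location_effect_p` are the adjusted Dunn p-values of
the within-vs-mito and within-vs-location contrasts.

Co-divergence uses a one-sided (greater) Mantel test: Pearson correlation
of upper-triangle entries, rows and columns of the second matrix permuted
jointly, `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, 999 permutations by
default, seeded; Pearson on raw (not log) distances matches the cited
ecology-package default. Across symbionts, Kendall's τ-b (exact p for
n ≤ 8 without ties) correlates Mantel R with relative abundance.

## 4. Abundance and within-sample diversity

The single-copy gene reference is purged of within-species duplicate gene
ids (all copies dropped) and of cross-species gene pairs with > 90%
global nucleotide identity (both dropped). Identity is computed as
`1 − edit_distance / max(length)` from a Needleman–Wunsch edit distance.
With cross-similar genes gone, unique-assignment read counting is
adequate, replacing EM-based multi-mapping resolution by design: per
species, score = mean over retained genes of `count / gene_length` (a
per-gene depth), normalized to percentages per sample. Abundances are
therefore *coverage shares*; the read simulator is defined on the same
scale, and a 7-species composition spanning 42% down to 0.3% is recovered
within ±2 percentage points (species ≥ 1%) from 200k reads. Detection is
breadth-based: a species is "detected" when ≥ 50% of its retained genes
receive at least one read (configurable stand-in for a deposition-level
detection rule that is not fully specified upstream).

Within-sample SNP density — the strain-diversity proxy that justifies
treating each symbiont in a host as a single genotype — counts callable
sites (depth ≥ 10) whose minor allele reaches ≥ 10% of reads and ≥ 2
reads, per **callable** kbp. Using callable rather than total reference
kbp prevents sparse coverage from deflating the estimate; this deviates
deliberately from a plain per-reference-kbp definition and is recorded in
the result object together with the thresholds used.

## 5. The simulator

`simulate_population` runs a discrete-generation forward simulation:

* Two founding mitochondrial lineages A and B separated by a configurable
  number of fixed differences (default 25 on a 15-kb mitochondrion;
  always ≥ 5 for symbionts). Maternal lines never cross lineages.
* Hosts live in lineage-by-location groups of constant size
  (Wright–Fisher reproduction within the group; mothers drawn from the
  same lineage's other location with probability `host_migration_rate`,
  default 0.02, which lets location structure emerge without isolating
  the bays).
* Founding hosts carry their lineage founder genotype plus
  `founder_diversity` (default 2) expected private mutations — standing
  variation at time zero.
* Each symbiont species is inherited vertically with probability
  `fidelity` per generation (mother's genotype plus Poisson new
  mutations) or horizontally from an environmental pool of K lineages
  (default K = 8) that is seeded from the two symbiont founders, diverges
  over a burn-in (default 100 generations), evolves neutrally alongside
  the hosts, and is structured globally or per location with migrant
  exchange.
* Carriage of a species by a sampled host is Bernoulli
  (`presence_prob`); internally every line propagates every species so
  the transmission event log is complete.
* Sequencing: per-site depth ~ Poisson(mean coverage); each read reports
  the true allele with probability 1−ε, each wrong allele with ε/3;
  Phred = round(−10 log₁₀ ε), capped at Q60 for ε = 0.

The default configuration mirrors the study scale: 80 hosts in 4 groups
of 20, seven species with relative abundances
{0.42, 0.28, 0.15, 0.06, 0.05, 0.03, 0.003}, coverage proportional to
abundance (total 50×), sequencing error 1% (Q20), and per-species
fidelities decreasing with abundance (1.0 for the dominant species down
to 0 for the rare spirochete-like species). `n_generations` defaults to
200; no empirical estimate exists for the generations separating the two
lineages, so this is a free parameter.

**What the simulator does not emulate** (and what passing tests therefore
do not show about real data): read-level artefacts (mapping errors,
duplicates, indels, reference bias — pileups are assumed pre-filtered),
within-host strain mixtures (except the two-strain mode used by the
SNP-density tests), recombination, selection, per-host variation in
symbiont load (coverage is homogeneous across hosts of a species), and
uneven quality scores within a sample.

## 6. Validation experiments

`symfid.experiments` freezes the designs the test suite runs:

* **Strict-fidelity congruence** — the defaults above with the dominant
  symbiont at 20× coverage; congruence must be 100% with no discordant
  hosts. This is also what `scripts/acceptance.py` recomputes.
* **Fidelity gradient** — four equally covered species (50-kb genomes,
  12×) with fidelities {1.0, 0.95, 0.6, 0.0}; the Mantel R ranking must
  match the fidelity ranking in ≥ 18/20 replicates and the f = 0 species
  must stay non-significant in ≥ 16/20. Two design choices matter and
  were fixed by power analysis before the test was frozen: the genealogy
  is **shallow** (2 generations past founding), because per-generation
  horizontal probabilities compound geometrically — after many
  generations the intact-chain fraction f^(2g) of host pairs is ~0 for
  every f < 1 and intermediate fidelities become statistically
  indistinguishable from 0; and the environmental pool is enlarged to 32
  lineages, because a small pool lets chance alignment of pool clusters
  with host lineages inflate the f = 0 null correlation.
* **Abundance correlation** — coverage proportional to abundance,
  fidelity increasing with abundance; Kendall τ between Mantel R and
  abundance positive in ≥ 18/20 replicates.
* **Method comparison** — probabilistic vs deterministic branches at 2×
  (dominance) and 50× error-free (identity), 12 hosts, 30-kb genomes.
* **Calibration** — Kruskal–Wallis (5000 null replicates) and Mantel
  (2000 replicates, 999 permutations) must land in [0.03, 0.07] at
  nominal 0.05; the SNP LRT is checked in its low-coverage regime (see
  §1) and for conservativeness under the default null.
* **Abundance recovery** — §4's ±2-point recovery at 200k reads.

Problem sizes (genome lengths of 10–50 kb, the replicate counts above)
are the package's chosen desk scale for routine verification; all designs
are seeded and deterministic.

## 7. Known limitations

* The congruence score formalizes only the basal (deepest) split;
  symbionts with more than two lineage-associated clades need the trees
  and the discordant-host list for interpretation.
* The qualitative fidelity labels (strict/strong/moderate/weak/absent)
  are interpretive and are not auto-assigned; the report carries the
  quantitative columns only.
* Mantel tests inherit the usual caveats about non-independence of
  pairwise distances; they are used here comparatively (ranking species),
  which the gradient experiment validates directly.
* The mpileup reader supports the substitution-relevant dialect subset
  only (indel blocks are skipped, not genotyped), and assumes upstream
  mapping-quality filtering.
* Statistical power at intermediate fidelity is intrinsically limited by
  generation depth (see §6); with deep genealogies only near-strict
  fidelity is detectable, which is a property of the biology, not of the
  implementation.
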