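"""The fidelity inference layer.

Four complementary measurements per symbiont species, mirroring how
partner fidelity between host maternal (mitochondrial) lineages and each
consortium member is quantified:

* pair-category distance tests -- pairwise genetic distances are compared
  across three host-pair categories ("within" the same lineage-by-location
  group, "mito" = between A- and B-hosts at the same location, "location"
  = between locations within a lineage) with a Kruskal-Wallis rank sum
  test and Dunn post hoc tests under Benjamini-Hochberg FDR control;
* co-divergence -- a one-sided Mantel permutation test correlating the
  symbiont's distance matrix with the host mitochondrial one;
* tree congruence -- the fraction of hosts whose placement in the symbiont
  tree's basal split matches their mitochondrial lineage under the
  best label assignment;
* across the consortium, Kendall's tau between per-species Mantel R and
  relative abundance.

Host pairs within each category are matched randomly WITHOUT replacement
(each host used at most once per category) so the category samples are
independent; the matching is seeded and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .distances import DistanceMatrix
from .io_formats import SampleTable
from .phylogeny import PhyloTree, basal_split

__all__ = [
    "PairCategorySample",
    "KruskalDunnResult",
    "MantelResult",
    "FidelityRow",
    "FidelityReport",
    "classify_pairs",
    "kruskal_dunn",
    "mantel_test",
    "congruence_score",
    "abundance_fidelity_correlation",
    "build_report",
]

CATEGORIES = ("within", "mito", "location")


@dataclass
class PairCategorySample:
    """Disjoint host pairs of one category and their genetic distances."""

    category: str
    pairs: list[tuple[str, str]]
    distances: np.ndarray
    seed: int
    restricted: bool = False  # True when a missing group forced the
    # restricted comparison scheme

    def __post_init__(self) -> None:
        used = [h for p in self.pairs for h in p]
        if len(used) != len(set(used)):
            raise ValueError(f"{self.category}: a host appears in two pairs")


def _match_disjoint(left: list[str], right: list[str], rng) -> list[tuple[str, str]]:
    """Random disjoint matching between two host sets (left != right) or
    within one set (left is right)."""
    if left is right:
        pool = list(left)
        rng.shuffle(pool)
        return [(pool[i], pool[i + 1]) for i in range(0, len(pool) - 1, 2)]
    a, b = list(left), list(right)
    rng.shuffle(a)
    rng.shuffle(b)
    return list(zip(a, b))


def classify_pairs(
    samples: SampleTable,
    D: DistanceMatrix,
    seed: int = 0,
    min_pairs: int = 1,
) -> dict[str, PairCategorySample]:
    """Randomly match hosts into disjoint pairs per category and collect
    their pairwise distances.

    Only hosts present in ``D`` participate.  When one lineage is missing
    from a location (or has a single host there), the restricted scheme
    applies: the "mito" category uses only locations where both lineages
    occur, and "location" only lineages present at both locations.
    Categories left with fewer than ``min_pairs`` pairs are omitted.
    """
    rng = np.random.default_rng(seed)
    present = samples.subset([s for s in samples.sample_ids if s in D.labels])
    frame = present.frame
    by_group: dict[tuple[str, str], list[str]] = {
        (lin, loc): list(sub["sample_id"])
        for (lin, loc), sub in frame.groupby(["lineage", "location"], sort=True)
    }
    lineages = sorted(frame["lineage"].unique())
    locations = sorted(frame["location"].unique())
    full = all(
        len(by_group.get((lin, loc), [])) >= 2
        for lin in ("A", "B")
        for loc in locations
    )

    out: dict[str, PairCategorySample] = {}

    def emit(category: str, pairs: list[tuple[str, str]]) -> None:
        if len(pairs) < min_pairs:
            return
        dvals = np.array([D.value(a, b) for a, b in pairs])
        out[category] = PairCategorySample(
            category=category,
            pairs=pairs,
            distances=dvals,
            seed=seed,
            restricted=not full,
        )

    # (a) within one lineage-by-location group
    within: list[tuple[str, str]] = []
    for key in sorted(by_group):
        hosts = by_group[key]
        within.extend(_match_disjoint(hosts, hosts, rng))
    emit("within", within)

    # (b) between A- and B-hosts at the same location
    mito: list[tuple[str, str]] = []
    for loc in locations:
        a_hosts = by_group.get(("A", loc), [])
        b_hosts = by_group.get(("B", loc), [])
        if a_hosts and b_hosts:
            mito.extend(_match_disjoint(a_hosts, b_hosts, rng))
    emit("mito", mito)

    # (c) between the two locations within one lineage
    location: list[tuple[str, str]] = []
    if len(locations) >= 2:
        for lin in lineages:
            l0 = by_group.get((lin, locations[0]), [])
            l1 = by_group.get((lin, locations[1]), [])
            if l0 and l1:
                location.extend(_match_disjoint(l0, l1, rng))
    emit("location", location)
    return out


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


@dataclass
class KruskalDunnResult:
    H: float
    p_value: float
    dunn: pd.DataFrame  # columns: group1, group2, z, p, p_adj


def kruskal_dunn(groups: dict[str, Sequence[float]]) -> KruskalDunnResult:
    """Kruskal-Wallis rank sum test with tie correction, plus Dunn pairwise
    post hoc z-tests (tie-corrected variance) under Benjamini-Hochberg FDR
    adjustment."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = [np.asarray(groups[g], dtype=float) for g in names]
    for g, arr in zip(names, data):
        if arr.size < 1:
            raise ValueError(f"group {g!r} is empty")
    pooled = np.concatenate(data)
    if np.allclose(pooled, pooled[0]):
        dunn = pd.DataFrame(
            [
                (names[i], names[j], 0.0, 1.0, 1.0)
                for i in range(len(names))
                for j in range(i + 1, len(names))
            ],
            columns=["group1", "group2", "z", "p", "p_adj"],
        )
        return KruskalDunnResult(H=0.0, p_value=1.0, dunn=dunn)

    H, p = stats.kruskal(*data)

    # Dunn: mean ranks over the pooled sample
    ranks = stats.rankdata(pooled)
    sizes = [arr.size for arr in data]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[k] : offsets[k + 1]].mean() for k in range(len(names))
    ]
    N = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(
                (N * (N + 1) / 12.0 - tie_term)
                * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            pz = 2.0 * stats.norm.sf(abs(z))
            rows.append((names[i], names[j], float(z), float(pz)))
    dunn = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    dunn["p_adj"] = multipletests(dunn["p"], method="fdr_bh")[1]
    return KruskalDunnResult(H=float(H), p_value=float(p), dunn=dunn)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    n: int


def mantel_test(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-sided (greater) Mantel permutation test.

    R is the Pearson correlation of the off-diagonal upper-triangle
    entries; the null distribution permutes rows and columns of ``D2``
    jointly; ``p = (1 + #{perm R >= observed}) / (1 + n_perm)``.
    """
    if set(D1.labels) != set(D2.labels):
        raise ValueError("matrices must share one label set")
    if D1.n < 4:
        raise ValueError("Mantel test needs n >= 4")
    D2 = D2.subset(D1.labels)
    n = D1.n
    iu = np.triu_indices(n, k=1)
    x = D1.D[iu]
    y = D2.D[iu]
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return MantelResult(r=np.nan, p_value=np.nan, n_perm=n_perm, n=n)
    r_obs = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    denom = np.sqrt((xc**2).sum() * ((y - y.mean()) ** 2).sum())
    # permuting D2's rows+columns leaves its upper-triangle mean/variance
    # unchanged, so only the cross product needs recomputing per permutation
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    M2 = D2.D
    permuted = M2[perms[:, :, None], perms[:, None, :]]  # (n_perm, n, n)
    cross = (permuted[:, iu[0], iu[1]] * xc).sum(axis=1)
    r_perm = cross / denom
    exceed = int(np.sum(r_perm >= r_obs - 1e-12))
    p = (1.0 + exceed) / (1.0 + n_perm)
    return MantelResult(r=r_obs, p_value=float(p), n_perm=n_perm, n=n)


# ---------------------------------------------------------------------------
# congruence and the abundance correlation
# ---------------------------------------------------------------------------


def congruence_score(
    tree: PhyloTree, lineages: SampleTable
) -> tuple[float, list[str]]:
    """Fraction of hosts whose basal-split clade matches their mitochondrial
    lineage under the matching-maximizing label assignment.

    Returns ``(score, discordant host ids)``.  For binary balanced labels
    the majority-matching assignment bounds the score below by 0.5.
    """
    side1, side2 = basal_split(tree)
    lin = {s: lineages.lineage_of(s) for s in side1 + side2}
    # two possible assignments of {A, B} to the two sides
    best_score = -1.0
    best_discordant: list[str] = []
    for a_side, b_side in ((side1, side2), (side2, side1)):
        matched = [h for h in a_side if lin[h] == "A"] + [
            h for h in b_side if lin[h] == "B"
        ]
        discordant = sorted(set(side1 + side2) - set(matched))
        score = len(matched) / len(lin)
        if score > best_score:
            best_score = score
            best_discordant = discordant
    return best_score, best_discordant


def abundance_fidelity_correlation(
    mantel_rs: Sequence[float], abundances: Sequence[float]
) -> tuple[float, float]:
    """Kendall tau-b between per-symbiont Mantel R and relative abundance.

    Exact p-value for small n (scipy's exact method when there are no
    ties), normal approximation otherwise.  Returns (nan, nan) with fewer
    than 3 complete pairs.
    """
    x = np.asarray(mantel_rs, dtype=float)
    y = np.asarray(abundances, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        return float("nan"), float("nan")
    x, y = x[keep], y[keep]
    method = "exact" if x.size <= 8 else "asymptotic"
    try:
        res = stats.kendalltau(x, y, method=method)
    except ValueError:  # ties prevent the exact method
        res = stats.kendalltau(x, y, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class FidelityRow:
    """Quantitative fidelity metrics for one symbiont species."""

    symbiont: str
    status: str = "analyzed"  # or "insufficient"
    reason: str = ""
    n_hosts_analyzed: int = 0
    n_snp_sites: int = 0
    mito_effect_p: float = float("nan")  # Dunn within-vs-mito, FDR adjusted
    location_effect_p: float = float("nan")  # Dunn within-vs-location
    kruskal_H: float = float("nan")
    kruskal_p: float = float("nan")
    mantel_r: float = float("nan")
    mantel_p: float = float("nan")
    congruence_fraction: float = float("nan")
    discordant_hosts: list[str] = field(default_factory=list)
    relative_abundance: float = float("nan")


@dataclass
class FidelityReport:
    """Per-symbiont fidelity metrics plus the across-consortium
    abundance/co-divergence correlation."""

    rows: list[FidelityRow]
    kendall_tau: float = float("nan")
    kendall_p: float = float("nan")

    def row(self, symbiont: str) -> FidelityRow:
        for r in self.rows:
            if r.symbiont == symbiont:
                return r
        raise KeyError(symbiont)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            d = asdict(r)
            d["discordant_hosts"] = ",".join(r.discordant_hosts)
            recs.append(d)
        return pd.DataFrame(recs)

    def to_json(self) -> str:
        payload = {
            "symbionts": [asdict(r) for r in self.rows],
            "kendall_tau": self.kendall_tau,
            "kendall_p": self.kendall_p,
        }

        def clean(o):
            if isinstance(o, float) and np.isnan(o):
                return None
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, list):
                return [clean(v) for v in o]
            return o

        return json.dumps(clean(payload), indent=1, sort_keys=True)


def build_report(rows: Sequence[FidelityRow]) -> FidelityReport:
    """Assemble the per-symbiont rows and the across-symbiont Kendall
    correlation between Mantel R and relative abundance (NA when fewer
    than 3 symbionts have both values)."""
    if not rows:
        raise ValueError("need at least one symbiont row")
    analyzed = [r for r in rows if r.status == "analyzed"]
    tau, p = abundance_fidelity_correlation(
        [r.mantel_r for r in analyzed],
        [r.relative_abundance for r in analyzed],
    )
    return FidelityReport(rows=list(rows), kendall_tau=tau, kendall_p=p)
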