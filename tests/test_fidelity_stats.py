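"""Pair-category matching, rank tests, Mantel, congruence and the
abundance correlation."""

import io

import numpy as np
import pandas as pd
import pytest

from symfid.distances import DistanceMatrix
from symfid.fidelity_stats import (
    FidelityRow,
    abundance_fidelity_correlation,
    build_report,
    classify_pairs,
    congruence_score,
    kruskal_dunn,
    mantel_test,
)
from symfid.io_formats import SampleTable
from conftest import two_cluster_tree


def make_table(per_group=20, lineages="AB", locations=("SA", "CA")):
    rows = []
    for lin in lineages:
        for loc in locations:
            for i in range(per_group):
                rows.append(
                    {"sample_id": f"{lin}{loc}{i:02d}", "lineage": lin,
                     "location": loc}
                )
    return SampleTable(pd.DataFrame(rows))


def random_distance_matrix(labels, rng):
    n = len(labels)
    M = rng.random((n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    return DistanceMatrix(labels=labels, D=M, n_sites=1)


class TestClassifyPairs:
    def test_study_scale_pair_counts(self, rng):
        table = make_table(20)
        D = random_distance_matrix(table.sample_ids, rng)
        cats = classify_pairs(table, D, seed=3)
        assert len(cats["within"].pairs) == 40  # 10 disjoint pairs per group
        assert len(cats["mito"].pairs) == 40  # 20 A-B pairs per location
        assert len(cats["location"].pairs) == 40  # 20 cross-location per lineage
        for sample in cats.values():
            used = [h for p in sample.pairs for h in p]
            assert len(used) == len(set(used))

    def test_category_definitions_respected(self, rng):
        table = make_table(4)
        D = random_distance_matrix(table.sample_ids, rng)
        cats = classify_pairs(table, D, seed=1)
        lin = dict(zip(table.frame["sample_id"], table.frame["lineage"]))
        loc = dict(zip(table.frame["sample_id"], table.frame["location"]))
        for a, b in cats["within"].pairs:
            assert lin[a] == lin[b] and loc[a] == loc[b]
        for a, b in cats["mito"].pairs:
            assert lin[a] != lin[b] and loc[a] == loc[b]
        for a, b in cats["location"].pairs:
            assert lin[a] == lin[b] and loc[a] != loc[b]

    def test_two_hosts_one_group_only_within(self, rng):
        rows = pd.DataFrame(
            [
                {"sample_id": "s1", "lineage": "A", "location": "X"},
                {"sample_id": "s2", "lineage": "A", "location": "X"},
            ]
        )
        table = SampleTable(rows)
        D = random_distance_matrix(["s1", "s2"], rng)
        cats = classify_pairs(table, D, seed=0)
        assert list(cats) == ["within"]
        assert len(cats["within"].pairs) == 1

    def test_missing_group_triggers_restricted_scheme(self, rng):
        """With no A-hosts at one location, lineage contrasts use only the
        location where both lineages occur, and location contrasts only
        the lineage present at both."""
        table = make_table(6)
        keep = [s for s in table.sample_ids if not s.startswith("ASA")]
        table = table.subset(keep)
        D = random_distance_matrix(keep, rng)
        cats = classify_pairs(table, D, seed=2)
        assert cats["mito"].restricted
        loc = dict(zip(table.frame["sample_id"], table.frame["location"]))
        lin = dict(zip(table.frame["sample_id"], table.frame["lineage"]))
        for a, b in cats["mito"].pairs:
            assert loc[a] == loc[b] == "CA"
        for a, b in cats["location"].pairs:
            assert lin[a] == lin[b] == "B"

    def test_deterministic_under_seed(self, rng):
        table = make_table(8)
        D = random_distance_matrix(table.sample_ids, rng)
        c1 = classify_pairs(table, D, seed=5)
        c2 = classify_pairs(table, D, seed=5)
        assert {k: v.pairs for k, v in c1.items()} == {
            k: v.pairs for k, v in c2.items()
        }


class TestKruskalDunn:
    def test_textbook_two_group_example(self):
        res = kruskal_dunn({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert res.H == pytest.approx(3.857142857, abs=1e-9)
        assert res.p_value == pytest.approx(0.04953, abs=1e-4)

    def test_identical_groups_are_null(self):
        res = kruskal_dunn({"g1": [2, 2, 2], "g2": [2, 2, 2]})
        assert res.H == 0.0
        assert res.p_value == 1.0
        assert (res.dunn["p_adj"] == 1.0).all()

    def test_dunn_flags_the_outlying_group(self):
        res = kruskal_dunn(
            {"a": [1, 2, 3, 4], "b": [1.5, 2.5, 3.5, 4.5], "c": [30, 31, 32, 33]}
        )
        frame = res.dunn.set_index(["group1", "group2"])
        assert frame.loc[("a", "c"), "p_adj"] < 0.05
        assert frame.loc[("a", "b"), "p_adj"] > 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_dunn({"a": [1.0], "b": []})


class TestMantel:
    def test_self_correlation_is_one_with_minimal_p(self, rng):
        labels = [f"s{i}" for i in range(10)]
        D = random_distance_matrix(labels, rng)
        res = mantel_test(D, D, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_anticorrelation(self, rng):
        labels = [f"s{i}" for i in range(8)]
        D1 = random_distance_matrix(labels, rng)
        flipped = D1.D.max() - D1.D
        np.fill_diagonal(flipped, 0.0)
        D2 = DistanceMatrix(labels=labels, D=flipped / flipped.max(), n_sites=1)
        res = mantel_test(D1, D2, n_perm=99, seed=0)
        # diagonal zeros are excluded, so the off-diagonal entries are
        # exactly anti-correlated
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_constant_matrix_reports_na(self, rng):
        labels = [f"s{i}" for i in range(6)]
        D1 = random_distance_matrix(labels, rng)
        flat = np.full((6, 6), 0.5)
        np.fill_diagonal(flat, 0.0)
        D2 = DistanceMatrix(labels=labels, D=flat, n_sites=1)
        res = mantel_test(D1, D2, n_perm=99, seed=0)
        assert np.isnan(res.r) and np.isnan(res.p_value)

    def test_label_alignment_not_order(self, rng):
        labels = [f"s{i}" for i in range(10)]
        D1 = random_distance_matrix(labels, rng)
        perm = rng.permutation(10)
        relabeled = DistanceMatrix(
            labels=[labels[i] for i in perm],
            D=D1.D[np.ix_(perm, perm)],
            n_sites=1,
        )
        res = mantel_test(D1, relabeled, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)


class TestCongruence:
    @staticmethod
    def table_for(hosts_lineages):
        rows = [
            {"sample_id": h, "lineage": l, "location": "X"}
            for h, l in hosts_lineages
        ]
        return SampleTable(pd.DataFrame(rows))

    def test_perfect_separation_scores_one(self):
        a_hosts = [f"a{i}" for i in range(20)]
        b_hosts = [f"b{i}" for i in range(20)]
        tree = two_cluster_tree(a_hosts, b_hosts)
        table = self.table_for([(h, "A") for h in a_hosts] +
                               [(h, "B") for h in b_hosts])
        score, discordant = congruence_score(tree, table)
        assert score == 1.0 and discordant == []

    def test_single_misplaced_host_counted(self):
        a_hosts = [f"a{i}" for i in range(20)]
        b_hosts = [f"b{i}" for i in range(20)]
        tree = two_cluster_tree(a_hosts, b_hosts)
        labels = [(h, "A") for h in a_hosts] + [(h, "B") for h in b_hosts]
        labels[5] = ("a5", "B")  # a B-host sitting inside the A side
        score, discordant = congruence_score(tree, self.table_for(labels))
        assert score == pytest.approx(39 / 40)
        assert discordant == ["a5"]

    def test_random_labels_score_near_half(self, rng):
        """Monte-Carlo null: balanced random labels on a fixed two-clade
        tree concentrate near the majority-matching floor 0.5."""
        side = [f"h{i:02d}" for i in range(40)]
        tree = two_cluster_tree(side[:20], side[20:])
        scores = []
        for _ in range(300):
            lineages = np.array(["A"] * 20 + ["B"] * 20)
            rng.shuffle(lineages)
            table = self.table_for(list(zip(side, lineages)))
            score, _ = congruence_score(tree, table)
            scores.append(score)
        assert all(s >= 0.5 for s in scores)
        assert np.mean(scores) < 0.65


class TestAbundanceCorrelation:
    def test_concordant_rankings(self):
        tau, p = abundance_fidelity_correlation(
            [0.1, 0.2, 0.3, 0.5, 0.7, 0.9], [1, 2, 3, 4, 5, 6]
        )
        assert tau == pytest.approx(1.0)
        assert p < 0.01

    def test_reversed_rankings(self):
        tau, _ = abundance_fidelity_correlation([3, 2, 1], [1, 2, 3])
        assert tau == pytest.approx(-1.0)

    def test_three_point_example(self):
        tau, _ = abundance_fidelity_correlation([1, 2, 3], [3, 1, 2])
        assert tau == pytest.approx(-1 / 3)

    def test_fewer_than_three_points_is_na(self):
        tau, p = abundance_fidelity_correlation([1, 2], [2, 1])
        assert np.isnan(tau) and np.isnan(p)


class TestBuildReport:
    def test_single_symbiont_has_na_correlation(self):
        report = build_report(
            [FidelityRow(symbiont="S", mantel_r=0.5, relative_abundance=0.4)]
        )
        assert np.isnan(report.kendall_tau)
        assert report.row("S").mantel_r == 0.5

    def test_insufficient_rows_carry_reason(self):
        rows = [
            FidelityRow(symbiont="ok", mantel_r=0.3, relative_abundance=0.5),
            FidelityRow(symbiont="rare", status="insufficient",
                        reason="carried by 4 hosts"),
        ]
        report = build_report(rows)
        frame = report.to_frame()
        assert frame.loc[frame["symbiont"] == "rare", "status"].iloc[0] == (
            "insufficient"
        )
        assert "4 hosts" in report.row("rare").reason

    def test_json_round_trips_na_as_null(self):
        import json

        report = build_report([FidelityRow(symbiont="S")])
        payload = json.loads(report.to_json())
        assert payload["kendall_tau"] is None
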