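"""Identity clustering and leakage-free splits."""

import numpy as np
import pytest

from protfeat.datasplit import (
    ClusterTable, audit_leakage, cluster_sequences, make_splits,
    pairwise_identity, read_cluster_tsv, read_split_tsv, write_cluster_tsv,
    write_split_tsv,
)
from protfeat.fixtures import make_toy_superfamily


def _needleman_identity(a: str, b: str) -> float:
    """Tiny independent DP oracle: global alignment, match +1, mismatch 0,
    linear gap -1 (ends penalized); identity = matches / alignment length."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = -np.arange(n + 1)
    score[0, :] = -np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = score[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
            score[i, j] = max(match, score[i - 1, j] - 1, score[i, j - 1] - 1)
    # traceback
    i, j, matches, length = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + \
                (1 if a[i - 1] == b[j - 1] else 0):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
        length += 1
    return matches / length


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKL") == 1.0

    def test_disjoint_sequences(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_brute_force_example(self):
        assert pairwise_identity("ACDEFG", "ACDEFA") == pytest.approx(5 / 6)
        assert _needleman_identity("ACDEFG", "ACDEFA") == pytest.approx(5 / 6)

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aas, size=int(rng.integers(5, 12))))
            b = "".join(rng.choice(aas, size=int(rng.integers(5, 12))))
            assert pairwise_identity(a, b) == pytest.approx(
                _needleman_identity(a, b), abs=1e-9)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_identity("", "ACD")


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        table = cluster_sequences({"a": "ACDEFGHIKL", "b": "ACDEFGHIKL",
                                   "c": "ACDEFGHIKL"})
        assert table.n_clusters == 1

    def test_unrelated_sequences_two_clusters(self):
        a, b = "AAAAAAAAAA", "TTTTTTTTTT"
        assert pairwise_identity(a, b) < 0.35
        table = cluster_sequences({"a": a, "b": b})
        assert table.n_clusters == 2

    def test_order_invariance(self):
        seqs = {"a": "ACDEFGHIKLMNP", "b": "ACDEFGHIKLMNQ", "c": "WWWWYYYYWWWW"}
        t1 = cluster_sequences(seqs)
        t2 = cluster_sequences(dict(reversed(list(seqs.items()))))
        assert t1.assignments == t2.assignments

    def test_ground_truth_recovery(self):
        _, truth = make_toy_superfamily(3, 4, seed=11, length=30)
        doms, truth = make_toy_superfamily(3, 4, seed=11, length=30)
        recovered = cluster_sequences({d: s for d, _, s in doms})

        def partition(table):
            groups = {}
            for d, c in table.assignments.items():
                groups.setdefault(c, set()).add(d)
            return {frozenset(g) for g in groups.values()}

        assert partition(recovered) == partition(truth)


class TestSplits:
    def test_ten_singletons_exact(self):
        table = ClusterTable({f"d{i}": i for i in range(10)}, 0.35)
        assignment = make_splits(table, seed=1)
        sizes = {s: len(assignment.domains_in(s))
                 for s in ("train", "validation", "test")}
        assert sizes == {"train": 8, "validation": 1, "test": 1}

    def test_thousand_singletons_80_10_10(self):
        table = ClusterTable({f"d{i}": i for i in range(1000)}, 0.35)
        fr = make_splits(table, seed=7).realized_fractions()
        assert fr["train"] == pytest.approx(0.8)
        assert fr["validation"] == pytest.approx(0.1)
        assert fr["test"] == pytest.approx(0.1)

    def test_deterministic_per_seed(self):
        table = ClusterTable({f"d{i}": i % 7 for i in range(40)}, 0.35)
        a = make_splits(table, seed=3).assignments
        b = make_splits(table, seed=3).assignments
        c = make_splits(table, seed=4).assignments
        assert a == b
        assert a != c

    def test_fraction_deviation_bound(self, rng):
        """|realized - target| <= (largest cluster)/(total domains)."""
        for trial in range(10):
            sizes = rng.integers(1, 8, size=12)
            assignments = {}
            d = 0
            for cid, size in enumerate(sizes):
                for _ in range(size):
                    assignments[f"d{d}"] = cid
                    d += 1
            table = ClusterTable(assignments, 0.35)
            assignment = make_splits(table, seed=trial)
            bound = sizes.max() / sizes.sum()
            for split, target in zip(("train", "validation", "test"),
                                     (0.8, 0.1, 0.1)):
                realized = assignment.realized_fractions()[split]
                assert abs(realized - target) <= bound + 1e-9

    def test_too_few_clusters(self):
        with pytest.raises(ValueError, match="at least 3"):
            make_splits(ClusterTable({"a": 0, "b": 1}, 0.35))

    def test_bad_fractions(self):
        table = ClusterTable({f"d{i}": i for i in range(5)}, 0.35)
        with pytest.raises(ValueError, match="sum to 1"):
            make_splits(table, fractions=(0.8, 0.1, 0.2))


class TestAudit:
    def test_make_splits_output_is_leak_free_over_seeds(self):
        table = ClusterTable({f"d{i}": i % 9 for i in range(45)}, 0.35)
        for seed in range(100):
            report = audit_leakage(make_splits(table, seed=seed), table)
            assert report.ok

    def test_bad_assignment_reports_violation(self):
        table = ClusterTable({"a": 0, "b": 0, "c": 1, "d": 2}, 0.35)
        assignment = make_splits(table, seed=0)
        assignment.assignments["a"] = "train"
        assignment.assignments["b"] = "test"
        report = audit_leakage(assignment, table)
        assert report.violations == [0]

    def test_fraction_formatting(self):
        table = ClusterTable({f"d{i}": i for i in range(3)}, 0.35)
        report = audit_leakage(make_splits(table, seed=0), table)
        for value in report.realized_fractions.values():
            assert value == round(value, 3)

    def test_coverage_mismatch_raises(self):
        table = ClusterTable({"a": 0, "b": 1, "c": 2}, 0.35)
        assignment = make_splits(table, seed=0)
        del assignment.assignments["a"]
        with pytest.raises(ValueError, match="coverage"):
            audit_leakage(assignment, table)


def test_tsv_round_trips():
    table = ClusterTable({"a": 0, "b": 0, "c": 1, "d": 2}, 0.35)
    assert read_cluster_tsv(write_cluster_tsv(table)).assignments == table.assignments
    assignment = make_splits(table, seed=0)
    assert read_split_tsv(write_split_tsv(assignment)).assignments == \
        assignment.assignments
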