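"""Hierarchical HDF5 store: layout, hard links, round-trips, iteration."""

import numpy as np
import pytest

from protfeat.datasplit import ClusterTable, make_splits
from protfeat.featurize import featurize_domain
from protfeat.fixtures import build_peptide
from protfeat.graph import build_residue_graph
from protfeat.store import (
    HierStore, init_store, sanitize_domain_id, superfamily_path, table_to_frame,
)


@pytest.fixture
def featurized():
    dom = build_peptide("AKDFG", [(-57, -47)] * 5, domain_id="dom1")
    table = featurize_domain(dom)
    graph = build_residue_graph(dom, table.residues)
    return dom, table, graph


@pytest.fixture
def store(tmp_path):
    st = init_store(tmp_path / "x.h5")
    yield st
    st.close()


class TestLifecycle:
    def test_new_store_is_empty_with_version(self, store):
        assert store.superfamilies() == []
        assert store.h5.attrs["format_version"] == "1.0"

    def test_reopen_preserves_version(self, tmp_path):
        path = tmp_path / "y.h5"
        init_store(path).close()
        with HierStore.open(path) as st:
            assert st.h5.attrs["format_version"] == "1.0"

    def test_existing_store_requires_force(self, tmp_path):
        path = tmp_path / "z.h5"
        init_store(path).close()
        with pytest.raises(FileExistsError, match="force"):
            init_store(path)
        init_store(path, force=True).close()


class TestPaths:
    @pytest.mark.parametrize("code", ["2.60.40.10", "2/60/40/10"])
    def test_superfamily_key_grammar(self, code):
        assert superfamily_path(code) == "2/60/40/10"

    def test_bad_code_rejected(self):
        with pytest.raises(ValueError):
            superfamily_path("2.60.40")

    def test_domain_id_sanitized(self):
        assert sanitize_domain_id("1abc A:1-100") == "1abc_A_1-100"


class TestWriteRead:
    def test_round_trip_bit_exact(self, store, featurized):
        dom, table, graph = featurized
        path = store.write_domain("2.60.40.10", "dom1", table, graph)
        assert path == "2/60/40/10/domains/dom1"
        atoms, residues, edges = store.read_domain("2.60.40.10", "dom1")
        frame = table_to_frame(atoms)
        assert list(frame.columns) == list(table.atoms.columns)
        for col in table.atoms.columns:
            stored = frame[col].to_numpy()
            original = table.atoms[col].to_numpy().astype(stored.dtype)
            assert np.array_equal(stored, original)
        assert len(edges) == len(graph.edges)

    def test_dtype_widths(self, store, featurized):
        dom, table, graph = featurized
        store.write_domain("2.60.40.10", "dom1", table, graph)
        atoms, residues, _ = store.read_domain("2.60.40.10", "dom1")
        assert atoms.dtype["C_elem"] == np.uint8
        assert atoms.dtype["charge"] == np.float32
        assert residues.dtype["ALA"] == np.uint8

    def test_duplicate_requires_overwrite(self, store, featurized):
        dom, table, graph = featurized
        store.write_domain("2.60.40.10", "dom1", table, graph)
        with pytest.raises(ValueError, match="overwrite"):
            store.write_domain("2.60.40.10", "dom1", table, graph)
        store.write_domain("2.60.40.10", "dom1", table, graph, overwrite=True)


class TestSplitLinks:
    def _write_ten(self, store, featurized):
        _, table, graph = featurized
        for i in range(10):
            store.write_domain("2.60.40.10", f"d{i}", table, graph)
        clusters = ClusterTable({f"d{i}": i for i in range(10)}, 0.35)
        return make_splits(clusters, seed=1)

    def test_counts_8_1_1(self, store, featurized):
        assignment = self._write_ten(store, featurized)
        counts = store.link_splits("2.60.40.10", assignment)
        assert counts == {"train": 8, "validation": 1, "test": 1}

    def test_hard_link_aliasing(self, store, featurized):
        assignment = self._write_ten(store, featurized)
        store.link_splits("2.60.40.10", assignment)
        for dom_id, split in assignment.assignments.items():
            direct = store.h5[f"2/60/40/10/domains/{dom_id}"]
            linked = store.h5[f"2/60/40/10/data_splits/{split}/{dom_id}"]
            assert direct == linked  # same underlying HDF5 object
            a1, _, _ = store.read_domain("2.60.40.10", dom_id)
            a2, _, _ = store.read_domain("2.60.40.10", dom_id, via_split=split)
            assert np.array_equal(a1, a2)

    def test_mutation_visible_through_alias(self, store, featurized):
        assignment = self._write_ten(store, featurized)
        store.link_splits("2.60.40.10", assignment)
        dom_id, split = next(iter(assignment.assignments.items()))
        store.h5[f"2/60/40/10/data_splits/{split}/{dom_id}/atoms"][0] = \
            store.h5[f"2/60/40/10/data_splits/{split}/{dom_id}/atoms"][1]
        a1, _, _ = store.read_domain("2.60.40.10", dom_id)
        a2, _, _ = store.read_domain("2.60.40.10", dom_id, via_split=split)
        assert np.array_equal(a1, a2)

    def test_relinking_idempotent(self, store, featurized):
        assignment = self._write_ten(store, featurized)
        c1 = store.link_splits("2.60.40.10", assignment)
        c2 = store.link_splits("2.60.40.10", assignment)
        assert c1 == c2

    def test_unwritten_domain_rejected(self, store, featurized):
        assignment = self._write_ten(store, featurized)
        assignment.assignments["ghost"] = "train"
        with pytest.raises(KeyError, match="ghost"):
            store.link_splits("2.60.40.10", assignment)


class TestIteration:
    def test_batch_sizes(self, store, featurized):
        _, table, graph = featurized
        for i in range(8):
            store.write_domain("2.60.40.10", f"d{i}", table, graph)
        clusters = ClusterTable({f"d{i}": 0 if i < 8 else i for i in range(8)}, 0.35)
        # force all 8 into train by linking a hand-made assignment
        from protfeat.datasplit import SplitAssignment
        assignment = SplitAssignment(
            {f"d{i}": "train" for i in range(8)}, (0.8, 0.1, 0.1), 0)
        store.link_splits("2.60.40.10", assignment)
        batches = list(store.iterate_split("2.60.40.10", "train", batch_size=3))
        assert [len(b) for b in batches] == [3, 3, 2]

    def test_shuffle_deterministic_and_exhaustive(self, store, featurized):
        _, table, graph = featurized
        from protfeat.datasplit import SplitAssignment
        for i in range(6):
            store.write_domain("2.60.40.10", f"d{i}", table, graph)
        assignment = SplitAssignment(
            {f"d{i}": ("train" if i < 4 else "validation" if i < 5 else "test")
             for i in range(6)}, (0.8, 0.1, 0.1), 0)
        store.link_splits("2.60.40.10", assignment)
        order1 = [d for b in store.iterate_split("2.60.40.10", "train", 2, 42)
                  for d, *_ in b]
        order2 = [d for b in store.iterate_split("2.60.40.10", "train", 2, 42)
                  for d, *_ in b]
        assert order1 == order2
        seen = set()
        for split in ("train", "validation", "test"):
            for batch in store.iterate_split("2.60.40.10", split, 2):
                seen.update(d for d, *_ in batch)
        assert seen == {f"d{i}" for i in range(6)}

    def test_unknown_split_rejected(self, store):
        with pytest.raises(ValueError, match="unknown split"):
            list(store.iterate_split("2.60.40.10", "holdout", 1))


class TestSummary:
    def test_empty_store(self, store):
        assert store.export_summary().empty

    def test_counts_match_links(self, store, featurized, tmp_path):
        _, table, graph = featurized
        for i in range(10):
            store.write_domain("2.60.40.10", f"d{i}", table, graph)
        clusters = ClusterTable({f"d{i}": i for i in range(10)}, 0.35)
        counts = store.link_splits("2.60.40.10", make_splits(clusters, seed=1))
        frame = store.export_summary()
        row = frame.iloc[0]
        assert row["superfamily"] == "2.60.40.10"
        assert row["n_domains"] == 10
        assert (row["n_train"], row["n_val"], row["n_test"]) == \
            (counts["train"], counts["validation"], counts["test"])
        out = tmp_path / "summary.tsv"
        frame.to_csv(out, sep="\t", index=False)
        import pandas as pd
        assert pd.read_csv(out, sep="\t").equals(frame)
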