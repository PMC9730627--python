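import numpy as np
import pytest

from abte.data import (
    DrugCatalog,
    load_interactions,
    write_edge_list,
    temporal_split,
    validation_split,
    negative_sample,
    interaction_counts,
)

from conftest import make_dataset


def _write(tmp_path, rows, name="edges.tsv"):
    p = tmp_path / name
    p.write_text("\n".join(rows) + "\n")
    return p


class TestLoadInteractions:
    def test_counts_from_path_graph(self, tmp_path):
        ds = load_interactions(_write(tmp_path, ["A\tB", "B\tC"]))
        assert ds.n_drugs == 3
        assert ds.catalog.drugs == ("A", "B", "C")
        np.testing.assert_array_equal(ds.counts, [1, 2, 1])

    def test_duplicate_and_reversed_rows_collapse(self, tmp_path):
        ds = load_interactions(_write(tmp_path, ["A\tB", "B\tA", "A\tB"]))
        assert ds.R_train.nnz == 2  # one undirected edge, stored twice
        np.testing.assert_array_equal(ds.counts, [1, 1])

    def test_comment_lines_ignored(self, tmp_path):
        ds = load_interactions(_write(tmp_path, ["# header", "A\tB"]))
        assert ds.R_train.nnz == 2

    def test_self_loop_rejected_with_line_number(self, tmp_path):
        path = _write(tmp_path, ["A\tB", "C\tC"])
        with pytest.raises(ValueError, match=r":2"):
            load_interactions(path)

    def test_unknown_id_with_supplied_catalog(self, tmp_path):
        catalog = DrugCatalog.from_ids(["A", "B"])
        path = _write(tmp_path, ["A\tZ"])
        with pytest.raises(KeyError, match="Z"):
            load_interactions(path, catalog)

    def test_symmetry_after_load(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = {f"D{a}\tD{b}" for a, b in rng.integers(0, 30, (100, 2)) if a != b}
        ds = load_interactions(_write(tmp_path, sorted(rows)))
        assert (ds.R_train != ds.R_train.T).nnz == 0
        assert not ds.R_train.diagonal().any()

    def test_roundtrip_via_writer(self, tmp_path):
        ds = load_interactions(_write(tmp_path, ["A\tB", "B\tC", "A\tC"]))
        out = tmp_path / "out.tsv"
        write_edge_list(ds, out)
        ds2 = load_interactions(out)
        assert (ds.R_train != ds2.R_train).nnz == 0


class TestTemporalSplit:
    def test_new_interaction_is_positive(self):
        train = make_dataset([("A", "B")], ids=["A", "B", "C"])
        test = make_dataset([("A", "B"), ("A", "C")], ids=["A", "B", "C"])
        batch = temporal_split(train, test)
        got = {(tuple(p), l) for p, l in zip(map(tuple, batch.pairs), batch.labels)}
        # A,B is a train positive -> dropped; A,C new positive; B,C negative
        assert got == {((0, 2), 1), ((1, 2), 0)}

    def test_no_new_interactions(self):
        train = make_dataset([("A", "B")], ids=["A", "B", "C"])
        batch = temporal_split(train, train)
        assert batch.labels.sum() == 0

    def test_pair_count_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        ids = [f"D{i}" for i in range(4)]
        edges = [("D0", "D1"), ("D2", "D3")]
        train = make_dataset(edges, ids=ids)
        test = make_dataset(edges + [("D0", "D2")], ids=ids)
        batch = temporal_split(train, test)
        assert len(batch) == 6 - 2  # C(4,2) minus train positives
        # brute force over all unordered pairs
        expect = {(i, j) for i in range(4) for j in range(i + 1, 4)}
        expect -= {(0, 1), (2, 3)}
        assert set(map(tuple, batch.pairs)) == expect

    def test_catalog_mismatch_rejected(self):
        a = make_dataset([("A", "B")], ids=["A", "B"])
        b = make_dataset([("A", "C")], ids=["A", "C"])
        with pytest.raises(ValueError):
            temporal_split(a, b)


class TestValidationSplit:
    def _ten_pos(self):
        edges = [(f"D{i}", f"D{i+1}") for i in range(10)]
        return make_dataset(edges)

    def test_fraction_of_positives_held_out(self):
        ds = self._ten_pos()
        sub, val = validation_split(ds, 0.2, seed=0)
        assert val.labels.sum() == 2
        assert sub.R_train.nnz // 2 == 8

    def test_same_seed_identical(self):
        ds = self._ten_pos()
        _, v1 = validation_split(ds, 0.2, seed=5)
        _, v2 = validation_split(ds, 0.2, seed=5)
        np.testing.assert_array_equal(v1.pairs, v2.pairs)
        np.testing.assert_array_equal(v1.labels, v2.labels)

    def test_positives_partition(self):
        ds = make_dataset([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        sub, val = validation_split(ds, 0.5, seed=1)
        orig = set(map(tuple, ds.train_pairs()))
        kept = set(map(tuple, sub.train_pairs()))
        held = {tuple(p) for p, l in zip(map(tuple, val.pairs), val.labels) if l == 1}
        assert kept | held == orig and not kept & held

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ValueError):
            validation_split(self._ten_pos(), fraction, seed=0)


class TestNegativeSample:
    def _ds(self):
        return make_dataset(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "A")]
        )

    def test_ratio_one_gives_one_negative_per_positive(self):
        batch = negative_sample(self._ds(), 1.0, rng_seed=0, epoch=0)
        assert len(batch) == 10
        assert batch.labels.sum() == 5

    def test_ratio_two(self):
        ds = make_dataset([("A", "B"), ("B", "C"), ("C", "D")],
                          ids=list("ABCDEF"))
        batch = negative_sample(ds, 2.0, rng_seed=0, epoch=0)
        assert (batch.labels == 0).sum() == 6

    def test_negatives_are_never_training_edges(self):
        ds = self._ds()
        edges = set(map(tuple, ds.train_pairs()))
        for epoch in range(50):
            batch = negative_sample(ds, 1.0, rng_seed=3, epoch=epoch)
            negs = {tuple(p) for p, l in zip(map(tuple, batch.pairs), batch.labels)
                    if l == 0}
            assert not negs & edges
            assert all(i < j for i, j in negs)

    def test_complete_graph_has_no_negative_pool(self):
        ds = make_dataset([("A", "B"), ("B", "C"), ("A", "C")])
        with pytest.raises(ValueError, match="non-edges"):
            negative_sample(ds, 1.0, rng_seed=0, epoch=0)

    def test_deterministic_per_epoch_and_fresh_across_epochs(self):
        ds = self._ds()
        b1 = negative_sample(ds, 1.0, rng_seed=9, epoch=4)
        b2 = negative_sample(ds, 1.0, rng_seed=9, epoch=4)
        np.testing.assert_array_equal(b1.pairs, b2.pairs)
        draws = {tuple(map(tuple, negative_sample(ds, 1.0, 9, e).pairs[5:]))
                 for e in range(20)}
        assert len(draws) > 1  # a different sample per epoch


class TestInteractionCounts:
    def test_empty_matrix(self):
        ds = make_dataset([], ids=["A", "B", "C"])
        np.testing.assert_array_equal(interaction_counts(ds), [0, 0, 0])

    def test_star_graph(self):
        ds = make_dataset([("C", f"L{i}") for i in range(4)])
        counts = interaction_counts(ds)
        assert counts[ds.catalog.index["C"]] == 4
        assert all(counts[ds.catalog.index[f"L{i}"]] == 1 for i in range(4))

    def test_matches_brute_force_row_sums(self):
        rng = np.random.default_rng(11)
        edges = {tuple(sorted((f"D{a}", f"D{b}")))
                 for a, b in rng.integers(0, 6, (12, 2)) if a != b}
        ds = make_dataset(sorted(edges), ids=[f"D{i}" for i in range(6)])
        dense = ds.R_train.toarray()
        np.testing.assert_array_equal(interaction_counts(ds), dense.sum(axis=1))
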