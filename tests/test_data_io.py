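"""Readers, preprocessing filters, normalization and splits."""

import numpy as np
import pandas as pd
import pytest

from markersel.data_io import (ExpressionDataset, ValidationError, coarse_filter,
                               filter_genes, load_expression, normalize,
                               read_markers, save_expression, split_dataset,
                               write_markers)
from markersel.selector import MarkerSet


def _labeled_counts(matrix, labels):
    matrix = np.asarray(matrix, dtype=float)
    n, d = matrix.shape
    return ExpressionDataset(matrix, [f"g{j}" for j in range(d)],
                             [f"c{i}" for i in range(n)],
                             labels=np.asarray(labels), stage="raw")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

class TestLoaders:
    def test_csv_identity_readback(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,gA,gB,gC\nc1,1,2,3\nc2,4,5,6\n")
        ds = load_expression(path, "csv")
        assert ds.matrix.shape == (2, 3)
        assert ds.gene_names == ["gA", "gB", "gC"]
        assert ds.labels is None
        assert np.array_equal(ds.matrix, [[1, 2, 3], [4, 5, 6]])

    def test_csv_label_column(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,gA,gB,label\nc1,1,2,x\nc2,4,5,y\n")
        ds = load_expression(path, "csv", label_field="label")
        assert list(ds.labels) == ["x", "y"]
        assert ds.n_genes == 2

    def test_duplicate_gene_name_is_named_in_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,gA,gA,gB\nc1,1,2,3\n")
        with pytest.raises(ValidationError, match="gA"):
            load_expression(path, "csv")

    def test_mtx_triplet_is_transposed_to_cells_by_genes(self, tmp_path):
        # genes-as-rows on disk: 3 genes x 2 cells
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            "3 2 3\n1 1 5\n2 2 7\n3 1 2\n")
        (tmp_path / "genes.tsv").write_text("gA\ngB\ngC\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        ds = load_expression(tmp_path, "mtx_triplet")
        assert ds.matrix.shape == (2, 3)
        assert ds.matrix[0, 0] == 5 and ds.matrix[1, 1] == 7 and ds.matrix[0, 2] == 2

    def test_h5ad_roundtrip_preserves_labels_and_stage(self, tmp_path):
        ds = _labeled_counts([[0, 3], [1, 0]], ["a", "b"])
        path = tmp_path / "d.h5ad"
        save_expression(ds, path, format="h5ad")
        back = load_expression(path, "h5ad", label_field="label")
        assert np.array_equal(back.matrix, ds.matrix)
        assert list(back.labels) == ["a", "b"]
        assert back.stage == "raw"

    def test_missing_file_raises_io_error(self):
        with pytest.raises(IOError):
            load_expression("/nonexistent/file.csv", "csv")


# ---------------------------------------------------------------------------
# gene filtering
# ---------------------------------------------------------------------------

class TestFilterGenes:
    def test_all_zero_gene_removed(self):
        X = np.zeros((10, 3))
        X[:3, 0] = 1.0   # present in 60% of type a only
        X[5:8, 2] = 1.0  # present in 60% of type b only
        ds = _labeled_counts(X, ["a"] * 5 + ["b"] * 5)
        kept = filter_genes(ds)
        assert kept.gene_names == ["g0", "g2"]

    def test_gene_detectable_in_one_type_is_kept(self):
        # presence 0.4 in type a, 0.0 in type b -> kept
        X = np.zeros((20, 2))
        X[:4, 0] = 1.0          # 4/10 of type a
        X[:, 1] = 1.0           # keeps the dataset non-empty but is ubiquitous
        ds = _labeled_counts(X, ["a"] * 10 + ["b"] * 10)
        kept = filter_genes(ds, max_presence=1.01)  # isolate the presence rule
        assert "g0" in kept.gene_names

    def test_gene_ubiquitous_in_enough_types_is_removed(self):
        # presence 0.8 in both of 2 types -> 100% of types > 75% -> removed
        rng = np.random.default_rng(0)
        X = np.zeros((40, 2))
        X[:10, 1] = 1.0  # survivor: 50% of type a only
        for block in (0, 20):
            idx = rng.choice(20, size=16, replace=False) + block
            X[idx, 0] = 1.0
        ds = _labeled_counts(X, ["a"] * 20 + ["b"] * 20)
        kept = filter_genes(ds, max_presence=0.75, type_fraction=0.50)
        assert "g0" not in kept.gene_names
        assert "g1" in kept.gene_names

    def test_exclusion_list_and_missing_labels(self):
        X = np.ones((6, 2))
        ds = _labeled_counts(X, ["a"] * 3 + ["b"] * 3)
        kept = filter_genes(ds, max_presence=1.01, exclusion_list={"g1"})
        assert kept.gene_names == ["g0"]
        with pytest.raises(ValidationError, match="labels"):
            filter_genes(ds.drop_labels())

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        X = (rng.random((60, 30)) < rng.random(30)).astype(float)
        X[:, 0] = 1.0  # guarantee a survivor under the relaxed threshold
        ds = _labeled_counts(X, ["a"] * 30 + ["b"] * 30)
        once = filter_genes(ds, max_presence=1.01)
        twice = filter_genes(once, max_presence=1.01)
        assert once.gene_names == twice.gene_names
        assert np.array_equal(once.matrix, twice.matrix)

    def test_coarse_filter_drops_rare_silent_genes(self):
        X = np.ones((100, 2))
        X[:, 1] = 0.0
        X[0, 1] = 0.5  # present in 1% of cells, low level
        ds = _labeled_counts(X, ["a"] * 100)
        kept = coarse_filter(ds)
        assert kept.gene_names == ["g0"]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_standard_gene_moments(self):
        rng = np.random.default_rng(2)
        ds = _labeled_counts(rng.poisson(3.0, (50, 20)) + 1, ["a"] * 50)
        out = normalize(ds, "standard")
        assert out.stage == "normalized_standard"
        out.validate_stage()
        assert np.abs(out.matrix.var(axis=0) - 1).max() < 1e-8

    def test_standard_equalizes_cell_totals_before_log(self):
        ds = _labeled_counts([[1, 1], [4, 4], [10, 10]], ["a"] * 3)
        totals = ds.matrix.sum(axis=1)
        target = np.median(totals)
        scaled = ds.matrix * (target / totals)[:, None]
        assert np.allclose(scaled.sum(axis=1), target)

    def test_generative_hand_computation(self):
        ds = _labeled_counts([[0, 3], [1, 0]], ["a", "b"])
        out = normalize(ds, "generative")
        logged = np.log2(1 + np.array([[0.0, 3.0], [1.0, 0.0]]))
        expected = (logged - logged.mean()) / logged.std()
        assert np.allclose(out.matrix, expected)
        assert abs(out.matrix.mean()) < 1e-12
        assert abs(out.matrix.var() - 1) < 1e-12

    def test_zero_total_cell_is_named(self):
        ds = _labeled_counts([[1, 1], [0, 0]], ["a", "b"])
        with pytest.raises(ValidationError, match="c1"):
            normalize(ds, "standard")

    def test_negative_entries_rejected(self):
        ds = ExpressionDataset(np.array([[-1.0, 2.0]]), ["g0", "g1"], ["c0"])
        with pytest.raises(ValidationError, match="negative"):
            normalize(ds, "standard")

    def test_constant_gene_left_at_zero(self):
        # equal cell totals keep gene 0 constant through the scaling step
        ds = _labeled_counts([[2, 3, 5], [2, 5, 3], [2, 4, 4]], ["a"] * 3)
        out = normalize(ds, "standard")
        assert np.allclose(out.matrix[:, 0], 0.0)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

class TestSplit:
    def test_stated_fraction_sizes(self):
        sp = split_dataset(10, (0.7, 0.1, 0.2), seed=0)
        assert (len(sp.train_idx), len(sp.val_idx), len(sp.test_idx)) == (7, 1, 2)

    def test_deterministic_and_partitioning(self):
        a = split_dataset(53, seed=11)
        b = split_dataset(53, seed=11)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.test_idx, b.test_idx)
        union = np.concatenate([a.train_idx, a.val_idx, a.test_idx])
        assert sorted(union) == list(range(53))

    def test_assignment_probability_matches_fraction(self):
        hits = sum(0 in split_dataset(10, seed=s).train_idx for s in range(1000))
        assert abs(hits / 1000 - 0.70) < 0.05

    def test_too_small_n_raises(self):
        with pytest.raises(ValidationError):
            split_dataset(3, (0.7, 0.1, 0.2), seed=0)


# ---------------------------------------------------------------------------
# marker files
# ---------------------------------------------------------------------------

class TestMarkerFiles:
    def test_roundtrip(self, tmp_path):
        markers = MarkerSet(indices=[4, 0, 2], scores=[0.5, 0.3, 0.2], budget=3)
        path = tmp_path / "m.tsv"
        write_markers(markers, [f"g{i}" for i in range(5)], path)
        df = pd.read_csv(path, sep="\t")
        assert list(df["rank"]) == [1, 2, 3]
        assert list(df["gene_name"]) == ["g4", "g0", "g2"]
        back = read_markers(path)
        assert back.indices == markers.indices
        assert np.allclose(back.scores, markers.scores)

    def test_empty_set_writes_header_only(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_markers(MarkerSet([], [], budget=0), ["g0"], path)
        assert len(path.read_text().strip().splitlines()) == 1

    def test_out_of_range_index_rejected(self, tmp_path):
        markers = MarkerSet(indices=[7], scores=[1.0], budget=1)
        with pytest.raises(ValidationError):
            write_markers(markers, ["g0", "g1"], tmp_path / "m.tsv")
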