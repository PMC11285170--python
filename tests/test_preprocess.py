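"""Preprocessing rules: binarization + prevalence filter, variance-based
feature selection, depth normalization, peak remapping, alignment, I/O."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from cellgate import preprocess as pp
from cellgate.preprocess import (ProcessedDataset, RawDataset, align_features,
                                 binarize_and_filter, normalize_rna, parse_peak,
                                 remap_source_to_target_peaks,
                                 select_highly_variable)


def make_atac(matrix, labels=None):
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    return RawDataset(matrix=matrix,
                      feature_ids=[f"chr1:{100 * i}-{100 * i + 50}"
                                   for i in range(m)],
                      cell_ids=[f"c{i}" for i in range(n)],
                      labels=labels, modality="atac")


class TestBinarizeAndFilter:
    def test_single_cell_peak_kept_at_small_n(self):
        # 5 cells: ceil(0.001 * 5) = 1, so one nonzero cell suffices
        ds = make_atac(np.array([[0, 3, 0, 0, 0]]).T)
        out = binarize_and_filter(ds, 0.001)
        np.testing.assert_array_equal(out.matrix.ravel(), [0, 1, 0, 0, 0])

    def test_all_zero_peak_removed(self):
        ds = make_atac(np.array([[1, 0], [1, 0], [2, 0]]))
        out = binarize_and_filter(ds, 0.001)
        assert out.n_features == 1
        assert out.feature_ids == [ds.feature_ids[0]]

    def test_threshold_rounds_up_at_2000_cells(self):
        # ceil(0.001 * 2000) = 2: a peak open in exactly 1 cell is dropped
        matrix = np.zeros((2000, 2))
        matrix[0, 0] = 5       # 1 cell -> dropped
        matrix[:2, 1] = 1      # 2 cells -> kept
        out = binarize_and_filter(make_atac(matrix), 0.001)
        assert out.feature_ids == [make_atac(matrix).feature_ids[1]]

    def test_idempotent(self, rng):
        ds = make_atac(rng.integers(0, 3, size=(40, 15)))
        once = binarize_and_filter(ds, 0.05)
        twice = binarize_and_filter(once, 0.05)
        np.testing.assert_array_equal(np.asarray(once.matrix),
                                      np.asarray(twice.matrix))
        assert once.feature_ids == twice.feature_ids

    def test_prevalence_brute_force_on_random_matrices(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 50))
            m = int(rng.integers(2, 20))
            frac = float(rng.uniform(0, 0.5))
            matrix = rng.integers(0, 2, size=(n, m)) * rng.integers(0, 4, size=(n, m))
            ds = make_atac(matrix)
            threshold = max(1, math.ceil(frac * n))
            expected = [ds.feature_ids[j] for j in range(m)
                        if np.count_nonzero(matrix[:, j]) >= threshold]
            if not expected:
                with pytest.raises(ValueError):
                    binarize_and_filter(ds, frac)
                continue
            out = binarize_and_filter(ds, frac)
            assert out.feature_ids == expected

    def test_sparse_input_supported(self):
        ds = RawDataset(matrix=sp.csr_matrix(np.array([[0, 2], [1, 3]])),
                        feature_ids=["chr1:0-10", "chr1:20-30"],
                        cell_ids=["a", "b"], modality="atac")
        out = binarize_and_filter(ds, 0.001)
        dense = np.asarray(out.matrix.todense())
        np.testing.assert_array_equal(dense, [[0, 1], [1, 1]])

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            binarize_and_filter(RawDataset(matrix=np.zeros((0, 3)),
                                           feature_ids=list("abc"), cell_ids=[],
                                           modality="atac"), 0.001)


class TestSelectHighlyVariable:
    def test_bernoulli_variance_peaks_at_half(self):
        n = 100
        col_a = np.array([1] * 50 + [0] * 50)  # open fraction 0.5
        col_b = np.array([1] * 1 + [0] * 99)   # open fraction 0.01
        ds = make_atac(np.column_stack([col_b, col_a]))
        out = select_highly_variable(ds, 1)
        assert out.selected_feature_ids == [ds.feature_ids[1]]

    def test_identity_when_n_exceeds_features(self, rng):
        ds = make_atac(rng.integers(0, 2, size=(20, 5)))
        out = select_highly_variable(ds, 50)
        assert out.selected_feature_ids == ds.feature_ids

    def test_tie_goes_to_lower_index(self):
        col = np.array([1, 0, 1, 0])
        ds = make_atac(np.column_stack([col, col, col]))
        out = select_highly_variable(ds, 2)
        assert out.selected_feature_ids == ds.feature_ids[:2]

    def test_monotone_nesting(self, rng):
        ds = make_atac(rng.integers(0, 2, size=(30, 12)))
        for n in range(1, 12):
            smaller = set(select_highly_variable(ds, n).selected_feature_ids)
            larger = set(select_highly_variable(ds, n + 1).selected_feature_ids)
            assert smaller <= larger


class TestNormalizeRNA:
    def test_hand_computed_example(self):
        ds = RawDataset(matrix=np.array([[100.0, 900.0]]),
                        feature_ids=["g1", "g2"], cell_ids=["c1"], modality="rna")
        out = normalize_rna(ds, 10_000)
        np.testing.assert_allclose(np.asarray(out.matrix).ravel(),
                                   [math.log(1001), math.log(9001)], rtol=1e-9)

    def test_identity_scaling_only_log1p(self):
        ds = RawDataset(matrix=np.array([[4000.0, 6000.0]]),
                        feature_ids=["g1", "g2"], cell_ids=["c1"], modality="rna")
        out = normalize_rna(ds, 10_000)
        np.testing.assert_allclose(np.asarray(out.matrix).ravel(),
                                   np.log1p([4000, 6000]))

    def test_zero_count_cell_named_in_error(self):
        ds = RawDataset(matrix=np.array([[1.0, 1.0], [0.0, 0.0]]),
                        feature_ids=["g1", "g2"], cell_ids=["ok", "empty"],
                        modality="rna")
        with pytest.raises(ValueError, match="empty"):
            normalize_rna(ds)

    def test_preserves_within_cell_rank_order(self, rng):
        matrix = rng.integers(0, 50, size=(10, 8)).astype(float) + 1
        ds = RawDataset(matrix=matrix, feature_ids=[f"g{i}" for i in range(8)],
                        cell_ids=[f"c{i}" for i in range(10)], modality="rna")
        out = normalize_rna(ds)
        for i in range(10):
            assert np.array_equal(np.argsort(matrix[i]),
                                  np.argsort(np.asarray(out.matrix)[i]))


class TestRemap:
    def test_identity_mapping(self, atac_raw):
        out = remap_source_to_target_peaks(atac_raw, list(atac_raw.feature_ids))
        np.testing.assert_array_equal(np.asarray(out.matrix),
                                      np.asarray(atac_raw.matrix))

    def test_overlap_aggregation(self):
        src = RawDataset(matrix=np.array([[2.0, 7.0]]),
                         feature_ids=["chr1:100-200", "chr2:0-50"],
                         cell_ids=["c"], modality="atac")
        out = remap_source_to_target_peaks(src, ["chr1:150-250", "chr3:0-10"])
        np.testing.assert_array_equal(np.asarray(out.matrix), [[2.0, 0.0]])

    def test_multiple_overlaps_sum(self):
        src = RawDataset(matrix=np.array([[1.0, 2.0, 4.0]]),
                         feature_ids=["chr1:0-100", "chr1:50-150", "chr1:300-400"],
                         cell_ids=["c"], modality="atac")
        out = remap_source_to_target_peaks(src, ["chr1:90-120"])
        assert np.asarray(out.matrix)[0, 0] == 3.0

    def test_half_open_intervals_do_not_touch(self):
        src = RawDataset(matrix=np.array([[5.0]]), feature_ids=["chr1:0-100"],
                         cell_ids=["c"], modality="atac")
        out = remap_source_to_target_peaks(src, ["chr1:100-200"])
        assert np.asarray(out.matrix)[0, 0] == 0.0

    def test_unparseable_peak_quoted(self):
        src = RawDataset(matrix=np.array([[1.0]]), feature_ids=["chr1:0-100"],
                         cell_ids=["c"], modality="atac")
        with pytest.raises(ValueError, match="banana"):
            remap_source_to_target_peaks(src, ["banana"])
        assert parse_peak("chrX:5-9") == ("chrX", 5, 9)


class TestAlignFeatures:
    def _processed(self, features, n_cells=3):
        return ProcessedDataset(
            matrix=np.arange(n_cells * len(features), dtype=np.float32
                             ).reshape(n_cells, len(features)),
            selected_feature_ids=list(features),
            cell_ids=[f"c{i}" for i in range(n_cells)], modality="atac")

    def test_identical_lists_unchanged(self):
        a, b = align_features(self._processed(["x", "y"]), self._processed(["x", "y"]))
        assert a.selected_feature_ids == b.selected_feature_ids == ["x", "y"]

    def test_subset_reduces_both_in_source_order(self):
        src = self._processed(["a", "b", "c"])
        tgt = self._processed(["c", "b"])
        a, b = align_features(src, tgt)
        assert a.selected_feature_ids == ["b", "c"]
        assert b.selected_feature_ids == ["b", "c"]
        np.testing.assert_array_equal(a.matrix, src.matrix[:, [1, 2]])

    def test_disjoint_errors(self):
        with pytest.raises(ValueError):
            align_features(self._processed(["a"]), self._processed(["b"]))


class TestIO:
    def test_h5ad_round_trip(self, tmp_path, atac_raw):
        out = binarize_and_filter(atac_raw, 0.001)
        path = tmp_path / "ds.h5ad"
        pp.write_h5ad(out, path)
        back = pp.read_h5ad(path, label_key="cell_type", modality="atac")
        np.testing.assert_array_equal(pp._as_dense(back.matrix),
                                      pp._as_dense(out.matrix))
        assert back.labels == out.labels
        assert back.feature_ids == out.feature_ids

    def test_mtx_reader_with_labels(self, tmp_path, rng):
        from scipy.io import mmwrite

        matrix = sp.csr_matrix(rng.integers(0, 3, size=(4, 3)).astype(float))
        mmwrite(tmp_path / "m.mtx", matrix)
        (tmp_path / "features.tsv").write_text("chr1:0-10\nchr1:20-30\nchr1:40-50\n")
        (tmp_path / "barcodes.tsv").write_text("b1\nb2\nb3\nb4\n")
        (tmp_path / "labels.csv").write_text(
            "cell_id,cell_type\nb1,T\nb2,T\nb3,B\nb4,B\n")
        ds = pp.read_mtx(tmp_path / "m.mtx", tmp_path / "features.tsv",
                         tmp_path / "barcodes.tsv", tmp_path / "labels.csv")
        assert ds.labels == ["T", "T", "B", "B"]
        np.testing.assert_array_equal(pp._as_dense(ds.matrix),
                                      matrix.toarray())

    def test_feature_list_writer(self, tmp_path):
        ds = ProcessedDataset(matrix=np.zeros((1, 2), dtype=np.float32),
                              selected_feature_ids=["f1", "f2"],
                              cell_ids=["c"], modality="atac")
        path = tmp_path / "features.txt"
        pp.write_feature_list(ds, path)
        assert path.read_text().splitlines() == ["f1", "f2"]
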