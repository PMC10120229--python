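"""I/O, normalization, binarization, shuffling, BBM storage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scbinary import (
    BinaryMatrix,
    CountMatrix,
    binarize,
    detection_rates,
    normalize_log_cp10k,
    read_bbm,
    read_counts,
    shuffle_nonzeros,
    storage_report,
    write_bbm,
    write_counts_mtx,
)
from scbinary.matrix import BBMFormatError


def _write(path, text):
    path.write_text(text)
    return path


class TestReadCounts:
    def test_mtx_triplets_transcribed(self, tmp_path):
        p = _write(
            tmp_path / "m.mtx",
            "%%MatrixMarket matrix coordinate integer general\n2 2 2\n1 1 3\n2 2 1\n",
        )
        m = read_counts(p, format="mtx")
        assert np.array_equal(m.values, [[3, 0], [0, 1]])

    def test_empty_body_is_all_zero(self, tmp_path):
        p = _write(
            tmp_path / "m.mtx",
            "%%MatrixMarket matrix coordinate integer general\n2 2 0\n",
        )
        assert np.array_equal(read_counts(p).values, np.zeros((2, 2)))

    def test_dense_tsv_single_gene(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "gene\tc1\tc2\ng1\t0\t5\n")
        m = read_counts(p, format="dense_tsv")
        assert np.array_equal(m.values, [[0, 5]])
        assert list(m.gene_ids) == ["g1"]

    def test_duplicate_coordinates_rejected(self, tmp_path):
        p = _write(
            tmp_path / "m.mtx",
            "%%MatrixMarket matrix coordinate integer general\n2 2 2\n1 1 3\n1 1 1\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_counts(p)

    def test_negative_values_rejected(self, tmp_path):
        p = _write(
            tmp_path / "m.mtx",
            "%%MatrixMarket matrix coordinate integer general\n2 2 1\n1 1 -3\n",
        )
        with pytest.raises(ValueError):
            read_counts(p)

    def test_metadata_join_and_offender_report(self, tmp_path, small_counts):
        d = write_counts_mtx(small_counts, tmp_path).parent
        meta = tmp_path / "meta.tsv"
        meta.write_text(
            "cell_id\tsample_id\tcondition\nc0\ts1\tA\nc1\ts1\tA\nc2\ts2\tB\n"
        )
        m = read_counts(d / "matrix.mtx", metadata_path=meta)
        assert list(m.sample_of_cell) == ["s1", "s1", "s2"]
        meta.write_text("cell_id\tsample_id\ncX\ts1\nc1\ts1\nc2\ts2\n")
        with pytest.raises(ValueError, match="c0"):
            read_counts(d / "matrix.mtx", metadata_path=meta)

    def test_mtx_roundtrip(self, small_counts, tmp_path):
        write_counts_mtx(small_counts, tmp_path)
        back = read_counts(tmp_path / "matrix.mtx")
        assert np.array_equal(back.values, small_counts.values)
        assert list(back.gene_ids) == list(small_counts.gene_ids)


class TestNormalize:
    def test_log_cp10k_values(self):
        m = CountMatrix(
            values=np.array([[1], [0], [3]]),
            gene_ids=np.array(["a", "b", "c"], dtype=object),
            cell_ids=np.array(["c0"], dtype=object),
        )
        norm = normalize_log_cp10k(m)
        np.testing.assert_allclose(
            norm.values[:, 0], [np.log(2501), 0.0, np.log(7501)], rtol=1e-12
        )

    def test_single_gene_cell(self):
        m = CountMatrix(
            values=np.array([[5]]),
            gene_ids=np.array(["a"], dtype=object),
            cell_ids=np.array(["c0"], dtype=object),
        )
        assert normalize_log_cp10k(m).values[0, 0] == pytest.approx(np.log(10001))

    def test_zero_total_cell_named_in_error(self):
        m = CountMatrix(
            values=np.array([[1, 0], [0, 0]]),
            gene_ids=np.array(["a", "b"], dtype=object),
            cell_ids=np.array(["good", "empty"], dtype=object),
        )
        with pytest.raises(ValueError, match="empty"):
            normalize_log_cp10k(m)

    def test_zero_pattern_preserved(self, small_counts):
        norm = normalize_log_cp10k(small_counts)
        assert np.array_equal(norm.values == 0, small_counts.values == 0)
        np.testing.assert_array_equal(
            detection_rates(binarize(norm)), detection_rates(binarize(small_counts))
        )


class TestBinarize:
    def test_indicator(self):
        m = CountMatrix(
            values=np.array([[0, 3], [2, 0]]),
            gene_ids=np.array(["a", "b"], dtype=object),
            cell_ids=np.array(["c0", "c1"], dtype=object),
        )
        assert np.array_equal(binarize(m).to_dense(), [[0, 1], [1, 0]])

    def test_all_zero(self):
        m = CountMatrix(
            values=np.zeros((2, 2), dtype=int),
            gene_ids=np.array(["a", "b"], dtype=object),
            cell_ids=np.array(["c0", "c1"], dtype=object),
        )
        assert binarize(m).to_dense().sum() == 0

    def test_idempotent(self, small_counts):
        b = binarize(small_counts)
        assert binarize(b) == b


class TestDetectionRates:
    def test_per_gene(self, small_counts):
        np.testing.assert_allclose(
            detection_rates(binarize(small_counts), axis="gene"),
            [2 / 3, 1 / 3, 1.0, 1 / 3],
        )

    def test_means_agree_with_overall(self, celltype_binary):
        b = celltype_binary
        overall = b.to_dense().mean()
        assert detection_rates(b, "gene").mean() == pytest.approx(overall)
        assert detection_rates(b, "cell").mean() == pytest.approx(overall)


class TestShuffleNonzeros:
    def test_detection_pattern_and_sums_invariant(self, small_counts):
        sh = shuffle_nonzeros(small_counts, seed=3)
        assert binarize(sh) == binarize(small_counts)
        np.testing.assert_array_equal(
            sh.values.sum(axis=1), small_counts.values.sum(axis=1)
        )

    def test_single_nonzero_gene_unchanged(self):
        m = CountMatrix(
            values=np.array([[0, 7, 0]]),
            gene_ids=np.array(["a"], dtype=object),
            cell_ids=np.array(["c0", "c1", "c2"], dtype=object),
        )
        assert np.array_equal(shuffle_nonzeros(m, seed=0).values, m.values)

    def test_seeded_reproducibility(self, celltype_data):
        m = celltype_data[0]
        a = shuffle_nonzeros(m, seed=5)
        b = shuffle_nonzeros(m, seed=5)
        assert np.array_equal(a.values, b.values)


def _random_binary(rng, n_genes, n_cells):
    dense = (rng.random((n_genes, n_cells)) < rng.random()).astype(np.uint8)
    return BinaryMatrix.from_dense(
        dense,
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        cell_ids=np.array([f"c{i}" for i in range(n_cells)], dtype=object),
    )


class TestBBM:
    def test_roundtrip_many_random(self, tmp_path):
        rng = np.random.default_rng(0)
        for i in range(100):
            b = _random_binary(rng, rng.integers(1, 20), rng.integers(1, 40))
            path = write_bbm(b, tmp_path / f"m{i}.bbm")
            assert read_bbm(path) == b

    def test_all_zero_and_all_one(self, tmp_path):
        for fill in (0, 1):
            dense = np.full((3, 17), fill, dtype=np.uint8)
            b = BinaryMatrix.from_dense(
                dense,
                gene_ids=np.array(["a", "b", "c"], dtype=object),
                cell_ids=np.array([f"c{i}" for i in range(17)], dtype=object),
            )
            path = write_bbm(b, tmp_path / f"fill{fill}.bbm")
            assert np.array_equal(read_bbm(path).to_dense(), dense)

    def test_pack_unpack_property(self):
        @settings(max_examples=50, deadline=None)
        @given(
            st.lists(
                st.lists(st.integers(0, 1), min_size=9, max_size=9),
                min_size=1,
                max_size=6,
            )
        )
        def check(rows):
            dense = np.array(rows, dtype=np.uint8)
            b = BinaryMatrix.from_dense(
                dense,
                gene_ids=np.array(
                    [f"g{i}" for i in range(dense.shape[0])], dtype=object
                ),
                cell_ids=np.array([f"c{i}" for i in range(9)], dtype=object),
            )
            assert np.array_equal(b.to_dense(), dense)

        check()

    def test_lsb_first_payload_byte(self, tmp_path):
        b = BinaryMatrix.from_dense(
            np.array([[1, 0, 0, 0, 0, 0, 0, 1]], dtype=np.uint8),
            gene_ids=np.array(["g"], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(8)], dtype=object),
        )
        raw = write_bbm(b, tmp_path / "m.bbm").read_bytes()
        assert raw[:4] == b"BBM1"
        assert raw[24] == 0x81

    def test_row_padding_to_whole_bytes(self):
        dense = np.ones((1, 9), dtype=np.uint8)
        b = BinaryMatrix.from_dense(
            dense,
            gene_ids=np.array(["g"], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(9)], dtype=object),
        )
        assert b.bits.shape == (1, 2)

    def test_distinct_format_errors(self, tmp_path):
        bad = tmp_path / "bad.bbm"
        bad.write_bytes(b"NOPE" + b"\x00" * 20)
        with pytest.raises(BBMFormatError, match="magic"):
            read_bbm(bad)
        b = _random_binary(np.random.default_rng(1), 4, 20)
        path = write_bbm(b, tmp_path / "m.bbm")
        raw = path.read_bytes()
        (tmp_path / "trunc.bbm").write_bytes(raw[:-2])
        with pytest.raises(BBMFormatError, match="truncated"):
            read_bbm(tmp_path / "trunc.bbm")
        (tmp_path / "extra.bbm").write_bytes(raw + b"\x00\x00")
        with pytest.raises(BBMFormatError, match="dimensions"):
            read_bbm(tmp_path / "extra.bbm")


class TestStorageReport:
    def test_hand_computed_byte_counts(self):
        rng = np.random.default_rng(0)
        values = np.zeros(100 * 100, dtype=np.int64)
        values[rng.choice(values.size, 1000, replace=False)] = 1 + rng.integers(
            0, 9, 1000
        )
        m = CountMatrix(
            values=values.reshape(100, 100),
            gene_ids=np.array([f"g{i}" for i in range(100)], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(100)], dtype=object),
        )
        rep = storage_report(m)
        assert rep.bytes_dense_float64 == 80_000
        assert rep.bytes_sparse_triplet == 12_000
        assert rep.bytes_bitpacked == 1_324
        assert rep.fold_vs_dense == pytest.approx(80_000 / 1_324)
        assert rep.detection_rate == pytest.approx(0.1)

    def test_one_row_fully_detected(self):
        m = CountMatrix(
            values=np.ones((1, 8), dtype=int),
            gene_ids=np.array(["g"], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(8)], dtype=object),
        )
        assert storage_report(m).bytes_bitpacked == 25

    def test_sparse_fold_monotone_in_detection(self):
        gene_ids = np.array([f"g{i}" for i in range(10)], dtype=object)
        cell_ids = np.array([f"c{i}" for i in range(80)], dtype=object)
        folds = []
        for nnz in (80, 400, 800):
            values = np.zeros(800, dtype=np.int64)
            values[:nnz] = 1
            m = CountMatrix(
                values=values.reshape(10, 80), gene_ids=gene_ids, cell_ids=cell_ids
            )
            folds.append(storage_report(m).fold_vs_sparse)
        assert folds[0] < folds[1] < folds[2]

    def test_bitpacked_bytes_match_file_size(self, tmp_path, small_counts):
        rep = storage_report(small_counts)
        path = write_bbm(binarize(small_counts), tmp_path / "m.bbm")
        assert path.stat().st_size == rep.bytes_bitpacked
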