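"""Container invariants, MTX round-trips, QC boundaries and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from scevolink import core_model as cm
from conftest import make_cell_matrix


class TestReadWrite:
    def test_mtx_triplet_expansion(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 2\n1 1 5\n2 2 7\n"
        )
        (tmp_path / "features.tsv").write_text("ga\ngb\ngc\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        m = cm.read_cell_matrix(
            tmp_path / "matrix.mtx", tmp_path / "features.tsv", tmp_path / "barcodes.tsv"
        )
        assert m.counts.toarray().tolist() == [[5, 0], [0, 7], [0, 0]]

    def test_duplicate_barcodes_rejected(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n1 2 1\n1 1 3\n"
        )
        (tmp_path / "features.tsv").write_text("ga\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc1\n")
        with pytest.raises(cm.ValidationError, match="barcode"):
            cm.read_cell_matrix(
                tmp_path / "matrix.mtx", tmp_path / "features.tsv", tmp_path / "barcodes.tsv"
            )

    def test_malformed_header_is_format_error(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text("not a matrix\n1 1 1\n")
        (tmp_path / "features.tsv").write_text("ga\n")
        (tmp_path / "barcodes.tsv").write_text("c1\n")
        with pytest.raises(cm.FormatError):
            cm.read_cell_matrix(
                tmp_path / "matrix.mtx", tmp_path / "features.tsv", tmp_path / "barcodes.tsv"
            )

    def test_missing_sex_column_defaults_to_unknown(self, tmp_path, caplog):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n1 2 2\n1 1 1\n1 2 2\n"
        )
        (tmp_path / "features.tsv").write_text("ga\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        (tmp_path / "meta.tsv").write_text("barcode\tsample\nc1\ts1\nc2\ts1\n")
        with caplog.at_level("WARNING", logger="scevolink"):
            m = cm.read_cell_matrix(
                tmp_path / "matrix.mtx", tmp_path / "features.tsv",
                tmp_path / "barcodes.tsv", tmp_path / "meta.tsv",
            )
        assert (m.cell_meta["sex"] == "unknown").all()
        assert any("sex" in r.message for r in caplog.records)

    def test_round_trip_identity(self, tiny_matrix, tmp_path):
        cm.write_cell_matrix(tiny_matrix, tmp_path)
        back = cm.read_cell_matrix(
            tmp_path / "matrix.mtx", tmp_path / "features.tsv",
            tmp_path / "barcodes.tsv", tmp_path / "cell_meta.tsv",
            mito_prefix="MT-",
        )
        assert (back.counts != tiny_matrix.counts).nnz == 0
        assert list(back.gene_ids) == list(tiny_matrix.gene_ids)
        assert list(back.cell_ids) == list(tiny_matrix.cell_ids)
        assert back.mito_genes == tiny_matrix.mito_genes
        pd.testing.assert_frame_equal(
            back.cell_meta.astype(object), tiny_matrix.cell_meta.astype(object),
            check_names=False,
        )


class TestValidation:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(cm.ValidationError, match="duplicate gene"):
            make_cell_matrix(np.ones((2, 2), int), gene_ids=["g", "g"])

    def test_negative_counts_rejected(self):
        with pytest.raises(cm.ValidationError, match="negative"):
            make_cell_matrix(np.array([[-1, 0], [0, 1]]))

    def test_mito_outside_genes_rejected(self):
        with pytest.raises(cm.ValidationError, match="mito"):
            make_cell_matrix(np.ones((2, 2), int), mito=["nope"])


class TestQC:
    def _matrix_with_numi(self, numis):
        """One gene per cell so nUMI is directly controlled."""
        n = len(numis)
        counts = np.diag(numis)
        return make_cell_matrix(counts)

    def test_umi_bounds_inclusive(self):
        m = self._matrix_with_numi([499, 500, 60000, 60001])
        kept = cm.apply_qc_filters(m, umi_min=500, umi_max=60000,
                                   ngene_min=1, ngene_max=10, min_cells_per_gene=0)
        assert list(kept.cell_ids) == ["c1", "c2"]

    def test_high_mito_cell_removed(self):
        counts = np.array([[60, 10], [40, 90]])  # cell c0: 60% mito
        m = make_cell_matrix(counts, gene_ids=["MT-a", "gb"], mito=["MT-a"])
        kept = cm.apply_qc_filters(m, mito_max=0.40, umi_min=1, umi_max=10**6,
                                   ngene_min=1, ngene_max=10, min_cells_per_gene=0)
        assert list(kept.cell_ids) == ["c1"]

    def test_gene_detection_boundary(self):
        # ga in 2 cells -> dropped; gb in 3 -> kept
        counts = np.array([[1, 1, 0, 0], [1, 1, 1, 0], [5, 5, 5, 5]])
        m = make_cell_matrix(counts)
        kept = cm.apply_qc_filters(m, umi_min=1, umi_max=100, ngene_min=1,
                                   ngene_max=10, min_cells_per_gene=3)
        assert list(kept.gene_ids) == ["g1", "g2"]

    def test_empty_result_names_first_filter(self):
        m = self._matrix_with_numi([10, 20])
        with pytest.raises(cm.EmptyResultError, match="nUMI"):
            cm.apply_qc_filters(m, umi_min=100, umi_max=200, ngene_min=1,
                                ngene_max=5, min_cells_per_gene=0)

    def test_cluster_level_qc_drops_majority_violating_cluster(self):
        # cluster k1: 2/3 cells under 1000 UMIs -> dropped under OR rule
        numis = [500, 600, 2000, 1500, 1600, 1700]
        counts = np.diag(numis)
        m = make_cell_matrix(counts, cluster=["k1"] * 3 + ["k2"] * 3)
        kept = cm.apply_qc_filters(
            m, cluster_qc=True, umi_min=1, umi_max=10**6,
            ngene_min=1, ngene_max=10, min_cells_per_gene=0,
        )
        assert set(kept.cell_meta["cluster"]) == {"k2"}

    def test_qc_idempotent(self, atlas):
        matrix, _ = atlas
        once = cm.apply_qc_filters(matrix)
        twice = cm.apply_qc_filters(once)
        assert (once.counts != twice.counts).nnz == 0
        assert list(once.cell_ids) == list(twice.cell_ids)
        assert list(once.gene_ids) == list(twice.gene_ids)


class TestNormalize:
    def test_formula_value(self):
        # count 100 in a cell with nUMI 10000, scale 10000 -> ln(101)
        counts = np.zeros((2, 1), int)
        counts[0, 0] = 100
        counts[1, 0] = 9900
        m = make_cell_matrix(counts)
        nm = cm.log_normalize(m, scale_factor=10000)
        assert nm.values[0, 0] == pytest.approx(np.log(101), rel=1e-12)

    def test_zero_count_zero_value(self, tiny_matrix):
        nm = cm.log_normalize(tiny_matrix)
        dense = nm.dense()
        raw = tiny_matrix.counts.toarray()
        assert (dense[raw == 0] == 0).all()

    def test_depth_invariance(self):
        counts = np.array([[3, 6], [7, 14]])  # cell 2 = doubled cell 1
        m = make_cell_matrix(counts)
        nm = cm.log_normalize(m)
        np.testing.assert_allclose(nm.dense()[:, 0], nm.dense()[:, 1], rtol=1e-12)

    def test_zero_total_cell_named(self):
        m = make_cell_matrix(np.array([[1, 0], [1, 0]]))
        with pytest.raises(cm.ValidationError, match="c1"):
            cm.log_normalize(m)


class TestSummarize:
    def test_pct_and_avg(self, tiny_matrix):
        nm = cm.log_normalize(tiny_matrix)
        cs = cm.summarize_clusters(nm, tiny_matrix)
        # gene gb expressed in 1/3 of k1 cells and 1/3 of k2 cells
        assert cs.pct_exp.loc["k1", "gb"] == pytest.approx(1 / 3)
        assert cs.n_cells.sum() == tiny_matrix.n_cells
        # single-cell cluster mean equals expm1 of the value
        single = tiny_matrix.subset(cell_mask=[True] + [False] * 5)
        nm1 = cm.log_normalize(single)
        cs1 = cm.summarize_clusters(nm1, single)
        assert cs1.avg_exp.loc["k1", "MT-a"] == pytest.approx(
            np.expm1(nm1.values[0, 0]), rel=1e-12
        )

    def test_unlabeled_cells_error(self, tiny_matrix):
        meta = tiny_matrix.cell_meta.copy()
        meta.loc[meta.index[0], "cluster"] = pd.NA
        bad = cm.CellMatrix(tiny_matrix.counts, tiny_matrix.gene_ids,
                            tiny_matrix.cell_ids, meta, tiny_matrix.mito_genes)
        with pytest.raises(cm.ValidationError, match="1 cells"):
            cm.summarize_clusters(cm.log_normalize(bad), bad)

    def test_weighted_means_recover_global_mean(self, atlas_norm, atlas_summary):
        qc, nm = atlas_norm
        cs = atlas_summary
        weighted = (
            cs.avg_exp.mul(cs.n_cells, axis=0).sum(axis=0) / cs.n_cells.sum()
        )
        delog = nm.values.copy()
        delog.data = np.expm1(delog.data)
        global_mean = np.asarray(delog.mean(axis=1)).ravel()
        np.testing.assert_allclose(weighted.to_numpy(), global_mean, rtol=1e-9)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    counts=hst.lists(
        hst.lists(hst.integers(min_value=0, max_value=50), min_size=3, max_size=3),
        min_size=2, max_size=6,
    )
)
def test_qc_idempotence_property(counts):
    """Applying the QC filters twice equals applying them once."""
    arr = np.array(counts)
    if arr.sum() == 0:
        return
    m = make_cell_matrix(arr)
    kwargs = dict(umi_min=1, umi_max=1000, ngene_min=1, ngene_max=10,
                  min_cells_per_gene=1)
    try:
        once = cm.apply_qc_filters(m, **kwargs)
    except cm.EmptyResultError:
        return
    twice = cm.apply_qc_filters(once, **kwargs)
    assert (once.counts != twice.counts).nnz == 0
    assert list(once.cell_ids) == list(twice.cell_ids)
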