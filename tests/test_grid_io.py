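"""Spot-table IO, QC filtering, and table <-> grid round-trips."""

import numpy as np
import pandas as pd
import pytest

from spavgn.grid_io import (SQUARE, VISIUM_HEX, EmptyResultError, ExpressionGrid,
                            SpotTable, from_grid, normalize_log1p_minmax,
                            qc_filter, read_spot_table, to_grid,
                            write_spot_table)


def _write_csv_pair(tmp_path, spots, expr_df):
    spots.to_csv(tmp_path / "spots.csv", index=False)
    expr_df.to_csv(tmp_path / "expr.csv")


class TestReaders:
    def test_csv_pair_shape_contract(self, tmp_path):
        spots = pd.DataFrame({"spot_id": ["a", "b", "c"],
                              "array_row": [0, 1, 2],
                              "array_col": [0, 1, 0]})
        expr = pd.DataFrame(np.arange(6.0).reshape(2, 3),
                            index=["g1", "g2"], columns=["a", "b", "c"])
        _write_csv_pair(tmp_path, spots, expr)
        t = read_spot_table(tmp_path, "csv_pair")
        assert t.expr.shape == (2, 3)
        assert t.gene_names == ["g1", "g2"]

    def test_h5ad_roundtrip_and_visium_inference(self, tmp_path, toy_table):
        # equal-parity coordinates -> lattice inferred as visium_hex
        t = SpotTable(spot_id=toy_table.spot_id,
                      array_row=np.array([0, 2, 1, 3, 2, 4]),
                      array_col=np.array([0, 0, 1, 1, 2, 2]),
                      lattice=VISIUM_HEX, expr=toy_table.expr,
                      gene_names=toy_table.gene_names)
        write_spot_table(t, tmp_path / "t.h5ad", format="h5ad")
        back = read_spot_table(tmp_path / "t.h5ad", "h5ad")
        assert back.lattice == VISIUM_HEX
        np.testing.assert_allclose(back.expr, t.expr)
        assert back.gene_names == t.gene_names

    def test_mtx_triplet_preserves_gene_order(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        expr = np.array([[0.0, 2.0], [3.0, 0.0], [1.0, 1.0]])
        mmwrite(tmp_path / "matrix.mtx", csr_matrix(expr))
        (tmp_path / "genes.tsv").write_text("gB\ngA\ngC\n")
        pd.DataFrame({"spot_id": ["x", "y"], "array_row": [0, 1],
                      "array_col": [0, 1]}).to_csv(
            tmp_path / "barcodes.tsv", sep="\t", index=False)
        t = read_spot_table(tmp_path, "mtx_triplet")
        assert t.gene_names == ["gB", "gA", "gC"]
        np.testing.assert_allclose(t.expr, expr)

    def test_duplicate_coordinates_rejected(self, tmp_path):
        spots = pd.DataFrame({"spot_id": ["a", "b"], "array_row": [0, 0],
                              "array_col": [1, 1]})
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        _write_csv_pair(tmp_path, spots, expr)
        with pytest.raises(ValueError, match="duplicate"):
            read_spot_table(tmp_path, "csv_pair")

    def test_missing_column_named_in_error(self, tmp_path):
        pd.DataFrame({"spot_id": ["a"], "array_row": [0]}).to_csv(
            tmp_path / "spots.csv", index=False)
        pd.DataFrame([[1.0]], index=["g"], columns=["a"]).to_csv(
            tmp_path / "expr.csv")
        with pytest.raises(ValueError, match="array_col"):
            read_spot_table(tmp_path, "csv_pair")


class TestQcFilter:
    def test_removes_rare_gene_and_empty_spot(self, toy_table):
        """With thresholds (2, 1): g5 (1 positive spot) and s6 (0 genes) go."""
        out = qc_filter(toy_table, min_spots_per_gene=2, min_genes_per_spot=1)
        assert out.gene_names == ["g1", "g2", "g3", "g4"]
        assert list(out.spot_id) == ["s1", "s2", "s3", "s4", "s5"]
        # brute-force check of survivor counts
        pos = toy_table.expr > 0
        for gi, name in enumerate(toy_table.gene_names):
            assert (name in out.gene_names) == (pos[gi].sum() >= 2)

    def test_zero_thresholds_identity(self, toy_table):
        out = qc_filter(toy_table, 0, 0)
        np.testing.assert_array_equal(out.expr, toy_table.expr)
        assert out.gene_names == toy_table.gene_names

    def test_all_spots_removed_raises(self, toy_table):
        with pytest.raises(EmptyResultError):
            qc_filter(toy_table, min_spots_per_gene=1, min_genes_per_spot=200)

    def test_idempotent_on_filtered_table(self, toy_table):
        once = qc_filter(toy_table, 2, 1)
        twice = qc_filter(once, 2, 1)
        np.testing.assert_array_equal(once.expr, twice.expr)

    def test_never_increases_dimensions(self, toy_table):
        out = qc_filter(toy_table, 3, 2)
        assert out.n_genes <= toy_table.n_genes
        assert out.n_spots <= toy_table.n_spots


class TestGridConversion:
    def test_single_spot_offset(self):
        t = SpotTable(spot_id=np.array(["s"], dtype=object),
                      array_row=np.array([5]), array_col=np.array([7]),
                      lattice=SQUARE, expr=np.array([[3.0]]), gene_names=["g"])
        g = to_grid(t)
        assert g.shape == (1, 1)
        assert g.origin_offset == (5, 7)
        assert g.data[0, 0, 0] == 3.0

    def test_sparse_placement(self):
        t = SpotTable(spot_id=np.array(["a", "b", "c"], dtype=object),
                      array_row=np.array([0, 0, 2]),
                      array_col=np.array([0, 2, 2]),
                      lattice=SQUARE,
                      expr=np.array([[1.0, 2.0, 3.0]]), gene_names=["g"])
        g = to_grid(t)
        assert g.shape == (3, 3)
        assert g.mask.sum() == 3
        assert g.data[0, 2, 2] == 3.0 and g.mask[1, 1] == 0

    @pytest.mark.parametrize("lattice", [SQUARE, VISIUM_HEX])
    def test_roundtrip_bit_exact(self, toy_table, lattice):
        t = toy_table
        if lattice == VISIUM_HEX:
            t = SpotTable(spot_id=t.spot_id,
                          array_row=np.array([0, 2, 1, 3, 2, 4]),
                          array_col=np.array([0, 0, 1, 1, 2, 2]),
                          lattice=VISIUM_HEX, expr=t.expr,
                          gene_names=t.gene_names)
        back = from_grid(to_grid(t))
        assert back.lattice == t.lattice
        # same coordinate set, expression preserved exactly
        orig = {(r, c): t.expr[:, i] for i, (r, c) in
                enumerate(zip(t.array_row, t.array_col))}
        for i, (r, c) in enumerate(zip(back.array_row, back.array_col)):
            np.testing.assert_array_equal(back.expr[:, i], orig[(r, c)])

    def test_from_grid_empty_mask_raises(self):
        g = ExpressionGrid(data=np.zeros((1, 2, 2)),
                           mask=np.zeros((2, 2), dtype=np.int8),
                           lattice=SQUARE)
        with pytest.raises(EmptyResultError):
            from_grid(g)

    def test_doubled_lattice_origin_preserved(self):
        g = ExpressionGrid(data=np.ones((1, 2, 2)),
                           mask=np.ones((2, 2), dtype=np.int8),
                           lattice=SQUARE, origin_offset=(6, 10))
        t = from_grid(g)
        assert t.array_row.min() == 6 and t.array_col.min() == 10

    def test_visium_parity_enforced(self):
        with pytest.raises(ValueError, match="parity"):
            SpotTable(spot_id=np.array(["a"], dtype=object),
                      array_row=np.array([0]), array_col=np.array([1]),
                      lattice=VISIUM_HEX, expr=np.array([[1.0]]),
                      gene_names=["g"])


def test_normalize_log1p_minmax(square_grid_4x4):
    g = ExpressionGrid(data=square_grid_4x4.data * 100,
                       mask=square_grid_4x4.mask, lattice=SQUARE)
    out = normalize_log1p_minmax(g)
    vals = out.data[:, out.mask == 1]
    assert vals.min() == 0.0 and vals.max() == 1.0
    assert (vals >= 0).all() and (vals <= 1).all()
    # monotone: ordering within each gene is preserved
    for gi in range(g.n_genes):
        orig = g.data[gi, g.mask == 1]
        assert (np.argsort(orig) == np.argsort(vals[gi])).all()


def test_as_4d_lossless(square_grid_4x4):
    x = square_grid_4x4.as_4d()
    assert x.shape == (3, 1, 4, 4)
    np.testing.assert_array_equal(x[:, 0], square_grid_4x4.data)
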