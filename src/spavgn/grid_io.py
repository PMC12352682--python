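"""Spot tables, dense expression grids, and the bridges between them.

Spot-level spatial transcriptomics comes as a table of capture locations
(``array_row``/``array_col`` on either a square ST lattice or the staggered
Visium honeycomb) together with a genes x spots expression matrix.  The
network consumes a dense ``G x H x W`` tensor with a binary tissue mask, so
this module owns the conversion in both directions, the standard QC filters
(genes expressed in too few spots, spots with too few detected genes) and
readers/writers for h5ad, CSV-pair and MTX-triplet layouts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

SQUARE = "square"
VISIUM_HEX = "visium_hex"
_LATTICES = (SQUARE, VISIUM_HEX)

__all__ = [
    "SpotTable", "ExpressionGrid", "read_spot_table", "write_spot_table",
    "qc_filter", "to_grid", "from_grid", "normalize_log1p_minmax",
    "save_grid", "load_grid", "SQUARE", "VISIUM_HEX",
]


class EmptyResultError(ValueError):
    """An operation removed every gene or every spot."""


@dataclasses.dataclass
class SpotTable:
    """Spots with integer lattice coordinates plus a genes x spots matrix.

    Visium honeycombs obey the parity constraint: ``array_row`` and
    ``array_col`` of every spot have equal parity, so only half the
    rectangular index grid is populated.
    """

    spot_id: np.ndarray          # (S,) str
    array_row: np.ndarray        # (S,) int >= 0
    array_col: np.ndarray        # (S,) int >= 0
    lattice: str
    expr: np.ndarray             # (G, S) non-negative
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.spot_id = np.asarray(self.spot_id, dtype=object)
        self.array_row = np.asarray(self.array_row, dtype=np.int64)
        self.array_col = np.asarray(self.array_col, dtype=np.int64)
        self.expr = np.asarray(self.expr, dtype=np.float64)
        self.gene_names = list(self.gene_names)
        self.validate()

    # number of spots / genes
    @property
    def n_spots(self) -> int:
        return self.expr.shape[1]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    def validate(self) -> None:
        if self.lattice not in _LATTICES:
            raise ValueError(f"unknown lattice {self.lattice!r}")
        s = len(self.spot_id)
        if not (len(self.array_row) == len(self.array_col) == s):
            raise ValueError("coordinate arrays disagree in length")
        if self.expr.ndim != 2 or self.expr.shape[1] != s:
            raise ValueError(
                f"expr must be genes x spots with {s} columns, got {self.expr.shape}")
        if len(self.gene_names) != self.expr.shape[0]:
            raise ValueError("gene_names length != number of expr rows")
        if (self.array_row < 0).any() or (self.array_col < 0).any():
            raise ValueError("negative array coordinates")
        if np.isfinite(self.expr).all() is np.False_ or (self.expr < 0).any():
            raise ValueError("expression must be finite and non-negative")
        coords = set(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(coords) != s:
            raise ValueError("duplicate (array_row, array_col) coordinates")
        if self.lattice == VISIUM_HEX:
            if ((self.array_row % 2) != (self.array_col % 2)).any():
                raise ValueError(
                    "visium_hex requires equal parity of array_row and array_col")


@dataclasses.dataclass
class ExpressionGrid:
    """Dense ``G x H x W`` expression tensor with an ``H x W`` tissue mask.

    Positions with ``mask == 0`` hold expression 0.  ``origin_offset``
    records the (row, col) shift applied when the spot coordinates were
    normalized to start at (0, 0), so grids can be mapped back to array
    coordinates.
    """

    data: np.ndarray             # (G, H, W)
    mask: np.ndarray             # (H, W) in {0, 1}
    lattice: str
    origin_offset: tuple[int, int] = (0, 0)
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.data.ndim != 3:
            raise ValueError("data must be G x H x W")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape must match the spatial dims of data")
        if self.lattice not in _LATTICES:
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        if not np.isfinite(self.data[:, self.mask == 1]).all():
            raise ValueError("expression is not finite inside the tissue mask")

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def as_4d(self) -> np.ndarray:
        """View as the network's G x 1 x H x W input layout (lossless)."""
        g, h, w = self.data.shape
        return self.data.reshape(g, 1, h, w)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_lattice(rows: np.ndarray, cols: np.ndarray) -> str:
    if len(rows) and ((rows % 2) == (cols % 2)).all():
        return VISIUM_HEX
    return SQUARE


def read_spot_table(path: str | Path, format: str,
                    lattice: str | None = None) -> SpotTable:
    """Read a spot table from ``h5ad``, ``csv_pair`` or ``mtx_triplet`` layout.

    ``csv_pair`` expects ``<path>/spots.csv`` (spot_id,array_row,array_col)
    and ``<path>/expr.csv`` (genes x spots, first column = gene name).
    ``mtx_triplet`` expects ``matrix.mtx`` (genes x spots), ``genes.tsv`` and
    ``barcodes.tsv`` with columns spot_id, array_row, array_col.
    When ``lattice`` is not given it is inferred: all-equal parity -> Visium.
    """
    path = Path(path)
    if format == "h5ad":
        import anndata as ad
        adata = ad.read_h5ad(path)
        for col in ("array_row", "array_col"):
            if col not in adata.obs:
                raise ValueError(f"h5ad file lacks obs column {col!r}")
        rows = adata.obs["array_row"].to_numpy(dtype=np.int64)
        cols = adata.obs["array_col"].to_numpy(dtype=np.int64)
        x = adata.X
        x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
        return SpotTable(
            spot_id=adata.obs_names.to_numpy(dtype=object),
            array_row=rows, array_col=cols,
            lattice=lattice or _infer_lattice(rows, cols),
            expr=x.T,                      # AnnData is spots x genes
            gene_names=list(adata.var_names),
        )
    if format == "csv_pair":
        spots = pd.read_csv(path / "spots.csv")
        for col in ("spot_id", "array_row", "array_col"):
            if col not in spots.columns:
                raise ValueError(f"spots.csv lacks column {col!r}")
        expr = pd.read_csv(path / "expr.csv", index_col=0)
        rows = spots["array_row"].to_numpy(dtype=np.int64)
        cols = spots["array_col"].to_numpy(dtype=np.int64)
        return SpotTable(
            spot_id=spots["spot_id"].to_numpy(dtype=object),
            array_row=rows, array_col=cols,
            lattice=lattice or _infer_lattice(rows, cols),
            expr=expr.to_numpy(dtype=np.float64),
            gene_names=list(expr.index.astype(str)),
        )
    if format == "mtx_triplet":
        from scipy.io import mmread
        mat = np.asarray(mmread(path / "matrix.mtx").todense(), dtype=np.float64)
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)
        bar = pd.read_csv(path / "barcodes.tsv", sep="\t")
        for col in ("spot_id", "array_row", "array_col"):
            if col not in bar.columns:
                raise ValueError(f"barcodes.tsv lacks column {col!r}")
        rows = bar["array_row"].to_numpy(dtype=np.int64)
        cols = bar["array_col"].to_numpy(dtype=np.int64)
        return SpotTable(
            spot_id=bar["spot_id"].to_numpy(dtype=object),
            array_row=rows, array_col=cols,
            lattice=lattice or _infer_lattice(rows, cols),
            expr=mat,
            gene_names=list(genes.iloc[:, 0].astype(str)),
        )
    raise ValueError(f"unknown format {format!r}")


def write_spot_table(t: SpotTable, path: str | Path, format: str = "csv_pair") -> None:
    path = Path(path)
    if format == "csv_pair":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "spot_id": t.spot_id,
            "array_row": t.array_row,
            "array_col": t.array_col,
        }).to_csv(path / "spots.csv", index=False)
        pd.DataFrame(t.expr, index=t.gene_names,
                     columns=t.spot_id).to_csv(path / "expr.csv")
        return
    if format == "h5ad":
        import anndata as ad
        adata = ad.AnnData(
            X=t.expr.T,
            obs=pd.DataFrame({"array_row": t.array_row, "array_col": t.array_col},
                             index=t.spot_id.astype(str)),
            var=pd.DataFrame(index=pd.Index(t.gene_names, dtype=str)),
        )
        adata.uns["lattice"] = t.lattice
        adata.write_h5ad(path)
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def qc_filter(t: SpotTable, min_spots_per_gene: int,
              min_genes_per_spot: int) -> SpotTable:
    """Drop lowly-observed genes, then low-coverage spots (single pass each).

    A gene is kept when its expression is strictly positive in at least
    ``min_spots_per_gene`` spots; afterwards a spot is kept when at least
    ``min_genes_per_spot`` of the surviving genes are positive in it.
    """
    if min_spots_per_gene < 0 or min_genes_per_spot < 0:
        raise ValueError("thresholds must be >= 0")
    pos = t.expr > 0
    gene_keep = pos.sum(axis=1) >= min_spots_per_gene
    if not gene_keep.any():
        raise EmptyResultError("qc_filter removed every gene")
    spot_keep = pos[gene_keep].sum(axis=0) >= min_genes_per_spot
    if not spot_keep.any():
        raise EmptyResultError("qc_filter removed every spot")
    return SpotTable(
        spot_id=t.spot_id[spot_keep],
        array_row=t.array_row[spot_keep],
        array_col=t.array_col[spot_keep],
        lattice=t.lattice,
        expr=t.expr[np.ix_(gene_keep, spot_keep)],
        gene_names=[g for g, k in zip(t.gene_names, gene_keep) if k],
    )


# ---------------------------------------------------------------------------
# table <-> grid
# ---------------------------------------------------------------------------

def to_grid(t: SpotTable) -> ExpressionGrid:
    """Place spots on a dense grid; coordinates are shifted to start at (0,0).

    For the Visium honeycomb the staggered (row, col) pairs are kept as-is on
    the rectangular index grid — the structurally empty half of the cells is
    simply carried as mask 0.
    """
    r0, c0 = int(t.array_row.min()), int(t.array_col.min())
    rows = t.array_row - r0
    cols = t.array_col - c0
    h, w = int(rows.max()) + 1, int(cols.max()) + 1
    data = np.zeros((t.n_genes, h, w), dtype=np.float64)
    mask = np.zeros((h, w), dtype=np.int8)
    data[:, rows, cols] = t.expr
    mask[rows, cols] = 1
    return ExpressionGrid(data=data, mask=mask, lattice=t.lattice,
                          origin_offset=(r0, c0), gene_names=list(t.gene_names))


def from_grid(g: ExpressionGrid, gene_names: list[str] | None = None,
              lattice: str | None = None) -> SpotTable:
    """One spot per mask=1 position; coordinates un-shifted by origin_offset."""
    rows, cols = np.nonzero(g.mask)
    if rows.size == 0:
        raise EmptyResultError("grid has an empty tissue mask")
    names = gene_names if gene_names is not None else g.gene_names
    if names is None:
        names = [f"gene_{i}" for i in range(g.n_genes)]
    r0, c0 = g.origin_offset
    return SpotTable(
        spot_id=np.array([f"spot_{r}_{c}" for r, c in
                          zip(rows + r0, cols + c0)], dtype=object),
        array_row=rows + r0,
        array_col=cols + c0,
        lattice=lattice or g.lattice,
        expr=g.data[:, rows, cols],
        gene_names=list(names),
    )


def normalize_log1p_minmax(g: ExpressionGrid) -> ExpressionGrid:
    """log1p then per-gene min–max scaling to [0, 1] over tissue positions.

    Counts are heavy-tailed; the log compresses the dynamic range and the
    per-gene scaling puts every gene on the loss's natural [0, 1] scale.
    Genes that are constant over the tissue map to 0.
    """
    data = np.log1p(g.data)
    tissue = g.mask == 1
    out = np.zeros_like(data)
    vals = data[:, tissue]                         # (G, S)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    out[:, tissue] = (vals - lo) / span
    return ExpressionGrid(data=out, mask=g.mask.copy(), lattice=g.lattice,
                          origin_offset=g.origin_offset,
                          gene_names=list(g.gene_names) if g.gene_names else None)


def save_grid(g: ExpressionGrid, path: str | Path) -> None:
    np.savez_compressed(
        Path(path), data=g.data, mask=g.mask, lattice=np.array(g.lattice),
        origin_offset=np.array(g.origin_offset),
        gene_names=np.array(g.gene_names if g.gene_names is not None else [],
                            dtype=object))


def load_grid(path: str | Path) -> ExpressionGrid:
    with np.load(Path(path), allow_pickle=True) as z:
        names = list(z["gene_names"]) or None
        return ExpressionGrid(data=z["data"], mask=z["mask"],
                              lattice=str(z["lattice"]),
                              origin_offset=tuple(int(v) for v in z["origin_offset"]),
                              gene_names=names)
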