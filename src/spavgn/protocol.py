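"""Geometric down-sampling / masking protocol for evaluation and training.

To benchmark imputation without extra data, a full-resolution grid is
down-sampled on the lattice: the retained spots form the simulated
low-resolution input and every other tissue position becomes a masked
location whose true expression is held out as ground truth.  Two dialects:

* ``square_step2`` — classic ST square grids keep every second row and
  column (step 2).
* ``visium_even_odd`` — the staggered Visium honeycomb keeps positions with
  both array coordinates even; on half-indices the retained set is again a
  regular coarser lattice.

Training pairs follow the self-supervised convention: the model learns the
2x mapping from the down-sampled grid back to the grid it came from, and is
then applied to the full grid to super-resolve it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .grid_io import SQUARE, VISIUM_HEX, EmptyResultError, ExpressionGrid

SQUARE_STEP2 = "square_step2"
VISIUM_EVEN_ODD = "visium_even_odd"

__all__ = ["DownsampleResult", "downsample_square", "downsample_visium",
           "downsample", "make_training_pair", "export_masked_positions"]


@dataclasses.dataclass
class DownsampleResult:
    low_res: ExpressionGrid
    masked_positions: list[tuple[int, int]]   # original-grid coordinates
    dialect: str


def _partition(g: ExpressionGrid, dialect: str) -> DownsampleResult:
    h, w = g.shape
    keep = np.zeros_like(g.mask, dtype=bool)
    keep[0::2, 0::2] = True                   # both coordinates even
    retained = keep & (g.mask == 1)
    masked = (~keep) & (g.mask == 1)
    if not retained.any():
        raise EmptyResultError("down-sampling retained no tissue position")

    hl, wl = (h + 1) // 2, (w + 1) // 2
    low_data = g.data[:, 0::2, 0::2].copy()
    low_mask = np.asarray(retained[0::2, 0::2], dtype=np.int8)
    low_data[:, low_mask == 0] = 0.0
    low = ExpressionGrid(data=low_data[:, :hl, :wl], mask=low_mask[:hl, :wl],
                         lattice=g.lattice, origin_offset=g.origin_offset,
                         gene_names=list(g.gene_names) if g.gene_names else None)
    pos = [(int(r), int(c)) for r, c in zip(*np.nonzero(masked))]
    return DownsampleResult(low_res=low, masked_positions=pos, dialect=dialect)


def downsample_square(g: ExpressionGrid) -> DownsampleResult:
    """Retain every second row/column of a square-lattice grid (step 2)."""
    if g.lattice != SQUARE:
        raise ValueError(f"expected a square-lattice grid, got {g.lattice!r}")
    h, w = g.shape
    if h < 2 or w < 2:
        raise ValueError(f"grid {h}x{w} too small to down-sample")
    return _partition(g, SQUARE_STEP2)


def downsample_visium(g: ExpressionGrid) -> DownsampleResult:
    """Alternating even-odd retention on the staggered Visium honeycomb.

    Keeps occupied positions with row and column both even; on the honeycomb
    this is the parity rule whose retained set is again a regular coarser
    lattice when re-indexed by half-coordinates.
    """
    if g.lattice != VISIUM_HEX:
        raise ValueError(f"expected a visium_hex grid, got {g.lattice!r}")
    if g.mask.sum() == 0:
        raise EmptyResultError("grid has an empty tissue mask")
    return _partition(g, VISIUM_EVEN_ODD)


def downsample(g: ExpressionGrid) -> DownsampleResult:
    """Dispatch on the grid's lattice dialect."""
    if g.lattice == SQUARE:
        return downsample_square(g)
    return downsample_visium(g)


def make_training_pair(
    g: ExpressionGrid,
) -> tuple[ExpressionGrid, ExpressionGrid, np.ndarray]:
    """Self-supervised pair: (down-sampled input, original target, target mask).

    The model's 2x output of ``input`` has shape ``2⌈H/2⌉ x 2⌈W/2⌉``; the
    target mask is the original tissue mask embedded in that canvas, so only
    real tissue positions the output can overlay contribute to the loss.
    """
    res = downsample(g)
    h, w = g.shape
    hl, wl = res.low_res.shape
    target_data = np.zeros((g.n_genes, 2 * hl, 2 * wl), dtype=np.float64)
    target_mask = np.zeros((2 * hl, 2 * wl), dtype=np.int8)
    target_data[:, :h, :w] = g.data
    target_mask[:h, :w] = g.mask
    target = ExpressionGrid(data=target_data, mask=target_mask,
                            lattice=g.lattice, origin_offset=g.origin_offset,
                            gene_names=list(g.gene_names) if g.gene_names else None)
    return res.low_res, target, target_mask


def export_masked_positions(res: DownsampleResult, path: str | Path) -> None:
    """Masked-location list as a BED-like TSV (row, col)."""
    with open(path, "w") as fh:
        fh.write("row\tcol\n")
        for r, c in res.masked_positions:
            fh.write(f"{r}\t{c}\n")
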