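import numpy as np
import pytest

from spavgn.grid_io import SQUARE, VISIUM_HEX, ExpressionGrid, SpotTable


@pytest.fixture
def toy_table() -> SpotTable:
    """5 genes x 6 spots on a square lattice.

    Gene g5 is positive in exactly 1 spot; spot s6 has no detected genes.
    """
    expr = np.array([
        [1, 2, 3, 4, 5, 0],
        [1, 1, 1, 1, 1, 0],
        [2, 0, 2, 0, 2, 0],
        [5, 5, 5, 5, 5, 0],
        [0, 0, 7, 0, 0, 0],   # g5: 1 positive spot
    ], dtype=float)
    return SpotTable(
        spot_id=np.array([f"s{i + 1}" for i in range(6)], dtype=object),
        array_row=np.array([0, 0, 1, 1, 2, 2]),
        array_col=np.array([0, 1, 0, 1, 0, 1]),
        lattice=SQUARE,
        expr=expr,
        gene_names=[f"g{i + 1}" for i in range(5)],
    )


@pytest.fixture
def square_grid_4x4() -> ExpressionGrid:
    rng = np.random.default_rng(0)
    return ExpressionGrid(data=rng.random((3, 4, 4)),
                          mask=np.ones((4, 4), dtype=np.int8),
                          lattice=SQUARE)


@pytest.fixture
def honeycomb_grid() -> ExpressionGrid:
    """6x8 Visium-style grid: tissue only at equal-parity positions."""
    rng = np.random.default_rng(1)
    mask = np.zeros((6, 8), dtype=np.int8)
    rr, cc = np.meshgrid(np.arange(6), np.arange(8), indexing="ij")
    mask[(rr % 2) == (cc % 2)] = 1
    data = rng.random((2, 6, 8)) * mask
    return ExpressionGrid(data=data, mask=mask, lattice=VISIUM_HEX)
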