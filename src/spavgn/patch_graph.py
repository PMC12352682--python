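"""Spatial graph over transformer patches.

Each patch gets a 2-D coordinate (its row/column index on the patch grid);
edges are weighted with a Gaussian kernel of the pairwise Euclidean
distances, pruned to each node's k nearest neighbors, and row-normalized:

    d_ij = ||p_i - p_j||            A_ij = exp(-d_ij^2 / (2 sigma^2))
    Ã_ij = A_ij M_ij / (sum_j A_ij M_ij + eps)

The graph depends only on geometry — it is built once per input shape and
reused across genes and epochs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["PatchGraph", "patch_coords", "build_adjacency", "aggregate",
           "export_adjacency_tsv"]


@dataclasses.dataclass
class PatchGraph:
    coords: np.ndarray        # (N, 2) int patch (row, col)
    adjacency: np.ndarray     # (N, N) row-normalized, <= k nonzeros per row
    sigma: float
    k: int
    epsilon: float


def patch_coords(grid_h: int, grid_w: int, patch_size: int) -> np.ndarray:
    """Row-major (row, col) indices of the patch grid.

    ``grid_h`` and ``grid_w`` must already be divisible by ``patch_size``;
    callers pad the expression grid (mask-aware) beforehand.
    """
    if grid_h % patch_size or grid_w % patch_size:
        raise ValueError(
            f"grid {grid_h}x{grid_w} not divisible by patch_size={patch_size}; "
            "pad the grid first (see model.pad_to_patch_multiple)")
    hp, wp = grid_h // patch_size, grid_w // patch_size
    rr, cc = np.meshgrid(np.arange(hp), np.arange(wp), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.int64)


def build_adjacency(coords: np.ndarray, sigma: float = 1.0, k: int = 4,
                    epsilon: float = 1e-8) -> PatchGraph:
    """Gaussian-kernel kNN adjacency with row normalization.

    Self is excluded from the neighbor set (a distance-0 self edge would
    dominate the kernel); ties on the kNN radius break toward the smaller
    linear index, which keeps the graph deterministic on integer lattices
    where four neighbors are often equidistant.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 patches")
    if sigma <= 0 or epsilon <= 0:
        raise ValueError("sigma and epsilon must be positive")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < N, got k={k}, N={n}")

    d = cdist(coords, coords)
    a = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    # kNN mask, self excluded; np.argsort is stable -> ties to smaller index
    mask = np.zeros((n, n), dtype=bool)
    d_noself = d.copy()
    np.fill_diagonal(d_noself, np.inf)
    order = np.argsort(d_noself, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    mask[rows, order[:, :k].ravel()] = True

    am = a * mask
    adj = am / (am.sum(axis=1, keepdims=True) + epsilon)
    return PatchGraph(coords=coords.astype(np.int64), adjacency=adj,
                      sigma=float(sigma), k=int(k), epsilon=float(epsilon))


def aggregate(graph: PatchGraph, z: np.ndarray) -> np.ndarray:
    """Message passing: weighted neighbor average ``Ã z``.

    ``z`` may be (N, D) or batched (..., N, D); output shape equals input.
    """
    z = np.asarray(z)
    n = graph.adjacency.shape[0]
    if z.shape[-2] != n:
        raise ValueError(f"z has {z.shape[-2]} rows, graph has {n} nodes")
    return graph.adjacency @ z


def export_adjacency_tsv(graph: PatchGraph, path: str | Path) -> None:
    """Write nonzero edges as (i, j, weight) triplets for inspection."""
    i, j = np.nonzero(graph.adjacency)
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{graph.adjacency[a, b]:.10g}\n")
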