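"""Masked multi-channel MSE loss, the training loop, and 2x enhancement.

The loss compares the network's four sub-pixel channels against the
channel-decomposed high-resolution target, but only at positions covered by
tissue:

    L = 1/(4N) * sum_k sum_ij M^(k)_ij (Yhat^(k)_ij - Y^(k)_ij)^2,
    N = sum_k sum_ij M^(k)_ij

with M^(k) the sub-sampled tissue mask (``subpixel.mask_subsample``).  The
``1/(4N)`` prefactor is kept exactly in this form; since N already counts
valid pixels across all four channels, a conventional per-valid-pixel mean
(``1/N``) is available via ``loss_norm="per_pixel"`` — the two differ by a
constant factor 4 and train identically up to the learning-rate scale.

Training is full-batch (genes are the batch), deterministic from the seed,
with Adam and a fixed epoch count (default 500); no early stopping.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autodiff import Tensor
from .grid_io import ExpressionGrid
from .model import (ModelConfig, NetworkState, _graph_for, forward,
                    forward_tensor, init_state, pad_to_patch_multiple)
from .subpixel import SubPixelOutput, deinterleave, interleave, mask_subsample

__all__ = ["LossResult", "TrainConfig", "TrainingError", "masked_mse",
           "train", "enhance"]


class TrainingError(RuntimeError):
    pass


@dataclasses.dataclass
class LossResult:
    value: float
    n_valid: int                      # N = total valid pixels over channels
    per_channel: np.ndarray           # 4-vector of partial squared-error sums


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    weight_decay: float = 0.0
    loss_norm: str = "4n"          # "4n": 1/(4N); "per_pixel": 1/N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss_norm not in ("4n", "per_pixel"):
            raise ValueError(f"unknown loss_norm {self.loss_norm!r}")


def _norm_factor(n_valid: int, loss_norm: str) -> float:
    return 1.0 / (4.0 * n_valid) if loss_norm == "4n" else 1.0 / n_valid


def masked_mse(pred: SubPixelOutput, target: np.ndarray, mask: np.ndarray,
               loss_norm: str = "4n") -> LossResult:
    """Masked multi-channel MSE between sub-pixel channels and a 2H x 2W target."""
    ch = pred.channels
    target4 = deinterleave(np.asarray(target, dtype=np.float64)).channels
    mask4 = mask_subsample(np.asarray(mask))
    if ch.shape != target4.shape:
        raise ValueError(f"pred {ch.shape} vs target channels {target4.shape}")
    n_valid = int(mask4.sum())
    if n_valid == 0:
        raise ZeroDivisionError("tissue mask is empty: loss normalizer N = 0")
    sq = mask4[None] * (ch - target4) ** 2          # (G,4,H,W)
    per_channel = sq.sum(axis=(0, 2, 3))
    return LossResult(value=float(per_channel.sum() * _norm_factor(n_valid, loss_norm)),
                      n_valid=n_valid, per_channel=per_channel)


def _masked_mse_tensor(pred: Tensor, target4: np.ndarray, mask4: np.ndarray,
                       loss_norm: str) -> Tensor:
    n_valid = int(mask4.sum())
    if n_valid == 0:
        raise ZeroDivisionError("tissue mask is empty: loss normalizer N = 0")
    diff = pred - Tensor(target4)
    return (diff * diff * Tensor(mask4[None])).sum() * _norm_factor(n_valid, loss_norm)


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, wd: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.lr, self.wd = params, lr, wd
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train(pair: tuple[ExpressionGrid, ExpressionGrid, np.ndarray],
          model_cfg: ModelConfig, train_cfg: TrainConfig,
          state: NetworkState | None = None) -> tuple[NetworkState, list[float]]:
    """Fit the network on a (low-res input, 2x target, target mask) pair.

    Returns the trained state and the per-epoch loss trace.  The input grid
    is zero-padded to patch-divisible dims; the target and its mask are
    embedded in the matching 2x canvas, so padded positions never enter the
    loss.
    """
    low, target, target_mask = pair
    p = model_cfg.patch_size
    data, _ = pad_to_patch_multiple(low.data, low.mask, p)
    x = data[:, None, :, :]
    _, _, hp, wp = x.shape

    th, tw = target_mask.shape
    canvas = np.zeros((low.n_genes, 2 * hp, 2 * wp))
    canvas[:, :th, :tw] = target.data
    mask_canvas = np.zeros((2 * hp, 2 * wp), dtype=target_mask.dtype)
    mask_canvas[:th, :tw] = target_mask
    target4 = deinterleave(canvas).channels
    mask4 = mask_subsample(mask_canvas).astype(np.float64)

    if state is None:
        cfg = dataclasses.replace(model_cfg, seed=train_cfg.seed or model_cfg.seed)
        state = init_state(cfg)
    state.pe_shape = (hp // p, wp // p)   # reference grid for PE resizing
    graph = _graph_for(hp // p, wp // p, model_cfg)
    if train_cfg.optimizer != "adam":
        raise ValueError(f"unknown optimizer {train_cfg.optimizer!r}")
    opt = _Adam(state.params, train_cfg.learning_rate, train_cfg.weight_decay)

    losses: list[float] = []
    for epoch in range(train_cfg.epochs):
        opt.zero_grad()
        pred = forward_tensor(x, model_cfg, state, graph)
        loss = _masked_mse_tensor(pred, target4, mask4, train_cfg.loss_norm)
        if not np.isfinite(loss.data):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return state, losses


def enhance(g: ExpressionGrid, state: NetworkState,
            cfg: ModelConfig) -> ExpressionGrid:
    """Super-resolve a grid to 2H x 2W.

    Observed positions map to even-even output coordinates; the output mask
    is the nearest-neighbor 2x expansion of the tissue mask, and evaluation
    downstream scores only positions inside the original tissue boundary.
    The origin offset doubles so the output lives on the doubled lattice.
    """
    pred = forward(g, cfg, state)
    hi = interleave(pred)
    mask2 = np.repeat(np.repeat(g.mask, 2, axis=0), 2, axis=1)
    hi = hi * (mask2 == 1)
    r0, c0 = g.origin_offset
    return ExpressionGrid(data=hi, mask=mask2, lattice=g.lattice,
                          origin_offset=(2 * r0, 2 * c0),
                          gene_names=list(g.gene_names) if g.gene_names else None)
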