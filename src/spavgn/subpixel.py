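"""Fixed 4-channel <-> 2x spatial interleaving (sub-pixel reconstruction).

The network predicts four spatially offset channels per low-resolution grid
cell; channel ``k`` maps to high-resolution position ``(2i + k // 2,
2j + k % 2)``:

    k=0 -> (2i, 2j)      k=1 -> (2i, 2j+1)
    k=2 -> (2i+1, 2j)    k=3 -> (2i+1, 2j+1)

Interleaving the channels yields the 2H x 2W map; the operations here are
exact index permutations (bit-exact inverses, no float arithmetic).
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: channel index -> (row offset, col offset) within each 2x2 block
CHANNEL_OFFSETS = {0: (0, 0), 1: (0, 1), 2: (1, 0), 3: (1, 1)}

__all__ = ["SubPixelOutput", "CHANNEL_OFFSETS", "interleave", "deinterleave",
           "mask_subsample"]


@dataclasses.dataclass
class SubPixelOutput:
    """``G x 4 x H x W`` prediction tensor with the fixed channel mapping."""

    channels: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 4 or self.channels.shape[1] != 4:
            raise ValueError(
                f"channels must be G x 4 x H x W, got {self.channels.shape}")


def interleave(s: SubPixelOutput | np.ndarray) -> np.ndarray:
    """Rearrange ``G x 4 x H x W`` channels into the ``G x 2H x 2W`` map."""
    ch = s.channels if isinstance(s, SubPixelOutput) else np.asarray(s)
    if ch.ndim != 4 or ch.shape[1] != 4:
        raise ValueError(f"expected G x 4 x H x W, got {ch.shape}")
    g, _, h, w = ch.shape
    out = np.empty((g, 2 * h, 2 * w), dtype=ch.dtype)
    for k, (dr, dc) in CHANNEL_OFFSETS.items():
        out[:, dr::2, dc::2] = ch[:, k]
    return out


def deinterleave(y: np.ndarray) -> SubPixelOutput:
    """Split a ``G x 2H x 2W`` map into its four sub-pixel channels."""
    y = np.asarray(y)
    if y.ndim != 3:
        raise ValueError(f"expected G x 2H x 2W, got {y.shape}")
    g, h2, w2 = y.shape
    if h2 % 2 or w2 % 2:
        raise ValueError(f"spatial dims must be even, got {h2} x {w2}")
    ch = np.empty((g, 4, h2 // 2, w2 // 2), dtype=y.dtype)
    for k, (dr, dc) in CHANNEL_OFFSETS.items():
        ch[:, k] = y[:, dr::2, dc::2]
    return SubPixelOutput(ch)


def mask_subsample(m: np.ndarray) -> np.ndarray:
    """Down-sample a ``2H x 2W`` tissue mask to per-channel masks ``4 x H x W``.

    ``M^(k)[i, j] = M[2i + k // 2, 2j + k % 2]`` — the binary indicator each
    sub-pixel channel sees during the masked loss.
    """
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] % 2 or m.shape[1] % 2:
        raise ValueError(f"mask must be 2D with even dims, got {m.shape}")
    h, w = m.shape[0] // 2, m.shape[1] // 2
    out = np.empty((4, h, w), dtype=m.dtype)
    for k, (dr, dc) in CHANNEL_OFFSETS.items():
        out[k] = m[dr::2, dc::2]
    return out
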