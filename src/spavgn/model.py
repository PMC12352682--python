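"""The SpaVGN network.

Gene-expression grids are treated as stacks of single-channel images (one
gene per batch element).  The forward path is:

1. two stacked 3x3 convolutions with ReLU (local texture / co-expression),
2. patch embedding — a pxp, stride-p convolution, flattened to N patch
   tokens of width D — plus fixed sinusoidal positional encoding,
3. ``n_blocks`` pre-norm transformer blocks, each containing multi-head
   self-attention, a graph step that averages each patch's k nearest
   spatial neighbors under a Gaussian kernel (see :mod:`spavgn.patch_graph`),
   and a 2-layer MLP, all with residual connections,
4. an inverse-patch head projecting each token to 4·p² values, unfolded to
   a 4-channel map of the input's spatial size (the four sub-pixel channels
   of :mod:`spavgn.subpixel`).

Everything runs on the in-package numpy autodiff core (:mod:`spavgn._autodiff`),
so initialization and the forward pass are exactly reproducible from a seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, conv2d, relu, softmax
from .grid_io import ExpressionGrid
from .patch_graph import PatchGraph, build_adjacency, patch_coords
from .subpixel import SubPixelOutput

__all__ = ["ModelConfig", "NetworkState", "init_state", "positional_encoding",
           "cnn_forward", "patch_embed", "mhsa", "transformer_block",
           "forward", "forward_tensor", "pad_to_patch_multiple",
           "save_state", "load_state"]


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are sized so a full classic-ST grid (a few thousand spots)
    trains in minutes on a single CPU; all of them are free choices of this
    implementation except ``gnn_k`` (k = 4 nearest neighbors).
    """

    cnn_channels: tuple[int, int] = (32, 32)
    cnn_kernel: int = 3
    patch_size: int = 2
    embed_dim: int = 128
    n_heads: int = 4
    n_blocks: int = 4
    mlp_ratio: int = 2
    gnn_sigma: float = 1.0
    gnn_k: int = 4
    gnn_epsilon: float = 1e-8
    use_pe: bool = True           # ablation: sinusoidal positional encoding
    use_gnn: bool = True          # ablation: graph step inside each block
    global_residual: str = "nearest"   # "nearest" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.cnn_kernel % 2 == 0 or self.cnn_kernel < 1:
            raise ValueError("cnn_kernel must be odd and positive")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if self.global_residual not in ("nearest", "none"):
            raise ValueError("global_residual must be 'nearest' or 'none'")


@dataclasses.dataclass
class NetworkState:
    """All learnable tensors, keyed by role, plus the seed that made them.

    ``pe_shape`` records the patch-grid shape the state was trained on; when
    the model later runs at a different resolution the positional table is
    resized to the new patch grid (standard ViT practice) so positions keep
    their spatial meaning across scales.
    """

    params: dict[str, Tensor]
    seed: int
    pe_shape: tuple[int, int] | None = None

    def named(self):
        return self.params.items()


def init_state(cfg: ModelConfig) -> NetworkState:
    """Seeded initialization: He-scaled convs, truncated-normal projections,
    unit/zero LayerNorm, zero head bias."""
    rng = np.random.default_rng(cfg.seed)
    c1, c2 = cfg.cnn_channels
    k, p, d = cfg.cnn_kernel, cfg.patch_size, cfg.embed_dim
    params: dict[str, np.ndarray] = {}

    def he(shape, fan_in):
        return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

    def trunc(shape, std=0.02):
        return np.clip(rng.standard_normal(shape) * std, -2 * std, 2 * std)

    params["conv1.w"] = he((c1, 1, k, k), k * k)
    params["conv1.b"] = np.zeros(c1)
    params["conv2.w"] = he((c2, c1, k, k), c1 * k * k)
    params["conv2.b"] = np.zeros(c2)
    params["patch.w"] = he((d, c2, p, p), c2 * p * p)
    params["patch.b"] = np.zeros(d)
    hidden = cfg.mlp_ratio * d
    for i in range(cfg.n_blocks):
        pre = f"block{i}."
        for ln in ("ln1", "ln2", "ln3"):
            params[pre + ln + ".g"] = np.ones(d)
            params[pre + ln + ".b"] = np.zeros(d)
        for w in ("wq", "wk", "wv", "wo"):
            params[pre + "attn." + w] = trunc((d, d))
        params[pre + "attn.bo"] = np.zeros(d)
        params[pre + "gnn.w"] = trunc((d, d))
        params[pre + "gnn.b"] = np.zeros(d)
        params[pre + "mlp.w1"] = trunc((d, hidden))
        params[pre + "mlp.b1"] = np.zeros(hidden)
        params[pre + "mlp.w2"] = trunc((hidden, d))
        params[pre + "mlp.b2"] = np.zeros(d)
    params["head_ln.g"] = np.ones(d)
    params["head_ln.b"] = np.zeros(d)
    params["head.w"] = trunc((d, 4 * p * p))
    params["head.b"] = np.zeros(4 * p * p)
    return NetworkState(
        params={k_: Tensor(v, requires_grad=True) for k_, v in params.items()},
        seed=cfg.seed)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def positional_encoding(n_patches: int, embed_dim: int) -> np.ndarray:
    """Fixed sinusoidal table: PE(pos, 2i) = sin(pos / 10000^{2i/D}),
    PE(pos, 2i+1) = cos(pos / 10000^{2i/D})."""
    if embed_dim % 2:
        raise ValueError("embed_dim must be even for sinusoidal encoding")
    pos = np.arange(n_patches)[:, None]
    i = np.arange(embed_dim // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / embed_dim)
    pe = np.empty((n_patches, embed_dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def _resized_pe(hp: int, wp: int, ref: tuple[int, int],
                embed_dim: int) -> np.ndarray:
    """Positional table for an (hp, wp) patch grid, resized from the
    reference grid the model was trained on (bilinear over the 2-D layout)."""
    href, wref = ref
    if (hp, wp) == (href, wref):
        return positional_encoding(hp * wp, embed_dim)
    table = positional_encoding(href * wref, embed_dim).reshape(href, wref, -1)
    ri = (np.arange(hp) * (href - 1) / max(hp - 1, 1)) if hp > 1 else np.zeros(1)
    ci = (np.arange(wp) * (wref - 1) / max(wp - 1, 1)) if wp > 1 else np.zeros(1)
    r0 = np.clip(np.floor(ri).astype(int), 0, max(href - 2, 0))
    c0 = np.clip(np.floor(ci).astype(int), 0, max(wref - 2, 0))
    fr = (ri - r0)[:, None, None]
    fc = (ci - c0)[None, :, None]
    r1 = np.minimum(r0 + 1, href - 1)
    c1 = np.minimum(c0 + 1, wref - 1)
    out = (table[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
           + table[np.ix_(r0, c1)] * (1 - fr) * fc
           + table[np.ix_(r1, c0)] * fr * (1 - fc)
           + table[np.ix_(r1, c1)] * fr * fc)
    return out.reshape(hp * wp, embed_dim)


def cnn_forward(x: Tensor | np.ndarray, cfg: ModelConfig,
                state: NetworkState) -> Tensor:
    """Two same-padded convolutions, each followed by ReLU (B,1,H,W -> B,C2,H,W)."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if not np.isfinite(x.data).all():
        raise ValueError("non-finite values in network input")
    pad = cfg.cnn_kernel // 2
    p = state.params
    z = relu(conv2d(x, p["conv1.w"], p["conv1.b"], padding=pad))
    return relu(conv2d(z, p["conv2.w"], p["conv2.b"], padding=pad))


def patch_embed(z: Tensor, cfg: ModelConfig, state: NetworkState) -> Tensor:
    """pxp stride-p convolution, flattened row-major to (B, N, D) tokens."""
    _, _, h, w = z.shape
    p = cfg.patch_size
    if h % p or w % p:
        raise ValueError(
            f"spatial dims {h}x{w} not divisible by patch_size={p}; "
            "pad the input first (pad_to_patch_multiple)")
    out = conv2d(z, state.params["patch.w"], state.params["patch.b"], stride=p)
    b, d, hp, wp = out.shape
    return out.reshape(b, d, hp * wp).transpose(0, 2, 1)


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + eps) ** -0.5) * gamma + beta


def mhsa(z: Tensor, cfg: ModelConfig, state: NetworkState,
         prefix: str) -> Tensor:
    """Multi-head scaled dot-product self-attention over patch tokens."""
    b, n, d = z.shape
    h = cfg.n_heads
    dh = d // h
    p = state.params

    def heads(t: Tensor) -> Tensor:          # (B,N,D) -> (B,H,N,dh)
        return t.reshape(b, n, h, dh).transpose(0, 2, 1, 3)

    q = heads(z @ p[prefix + "attn.wq"])
    k = heads(z @ p[prefix + "attn.wk"])
    v = heads(z @ p[prefix + "attn.wv"])
    att = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)), axis=-1)
    out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
    return out @ p[prefix + "attn.wo"] + p[prefix + "attn.bo"]


def transformer_block(z: Tensor, graph: PatchGraph | None, cfg: ModelConfig,
                      state: NetworkState, index: int,
                      use_gnn: bool | None = None) -> Tensor:
    """Pre-norm residual block: MHSA, then graph aggregation, then MLP."""
    pre = f"block{index}."
    p = state.params
    z = z + mhsa(_layer_norm(z, p[pre + "ln1.g"], p[pre + "ln1.b"]),
                 cfg, state, pre)
    gnn_on = cfg.use_gnn if use_gnn is None else use_gnn
    if gnn_on and graph is not None:
        zn = _layer_norm(z, p[pre + "ln2.g"], p[pre + "ln2.b"])
        agg = Tensor(graph.adjacency) @ zn      # Ã z, broadcast over batch
        z = z + agg @ p[pre + "gnn.w"] + p[pre + "gnn.b"]
    zn = _layer_norm(z, p[pre + "ln3.g"], p[pre + "ln3.b"])
    z = z + relu(zn @ p[pre + "mlp.w1"] + p[pre + "mlp.b1"]) @ p[pre + "mlp.w2"] \
        + p[pre + "mlp.b2"]
    return z


def pad_to_patch_multiple(data: np.ndarray, mask: np.ndarray,
                          patch_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad (G,H,W) data and (H,W) mask up to patch-divisible dims."""
    g, h, w = data.shape
    hp = -h % patch_size
    wp = -w % patch_size
    if hp == 0 and wp == 0:
        return data, mask
    return (np.pad(data, ((0, 0), (0, hp), (0, wp))),
            np.pad(mask, ((0, hp), (0, wp))))


def _graph_for(hp: int, wp: int, cfg: ModelConfig) -> PatchGraph | None:
    n = hp * wp
    if n < 2:
        return None
    k_eff = min(cfg.gnn_k, n - 1)  # tiny inputs: clamp rather than refuse
    coords = patch_coords(hp * cfg.patch_size, wp * cfg.patch_size,
                          cfg.patch_size)
    return build_adjacency(coords, cfg.gnn_sigma, k_eff, cfg.gnn_epsilon)


def forward_tensor(x: np.ndarray, cfg: ModelConfig, state: NetworkState,
                   graph: PatchGraph | None = None) -> Tensor:
    """Differentiable forward pass: (B,1,H,W), patch-divisible -> (B,4,H,W)."""
    b, _, h, w = x.shape
    p = cfg.patch_size
    hp, wp = h // p, w // p
    if graph is None:
        graph = _graph_for(hp, wp, cfg)
    z = cnn_forward(Tensor(x), cfg, state)
    z = patch_embed(z, cfg, state)
    if cfg.use_pe:
        ref = state.pe_shape or (hp, wp)
        z = z + Tensor(_resized_pe(hp, wp, ref, cfg.embed_dim))
    for i in range(cfg.n_blocks):
        z = transformer_block(z, graph, cfg, state, i)
    z = _layer_norm(z, state.params["head_ln.g"], state.params["head_ln.b"])
    z = z @ state.params["head.w"] + state.params["head.b"]   # (B, N, 4p²)
    # inverse patch reconstruction: token -> 4-channel pxp block
    z = z.reshape(b, hp, wp, 4, p, p).transpose(0, 3, 1, 4, 2, 5)
    z = z.reshape(b, 4, hp * p, wp * p)
    if cfg.global_residual == "nearest":
        # sub-pixel channels predict deviations from the low-res cell value
        # (residual learning against the trivial nearest upsample)
        z = z + Tensor(np.broadcast_to(x, (b, 4, h, w)))
    return z


def forward(g: ExpressionGrid, cfg: ModelConfig,
            state: NetworkState) -> SubPixelOutput:
    """Run the network on a grid; returns the G x 4 x H x W sub-pixel tensor
    cropped back to the grid's original spatial dims."""
    h, w = g.shape
    data, mask = pad_to_patch_multiple(g.data, g.mask, cfg.patch_size)
    x = data[:, None, :, :]
    out = forward_tensor(x, cfg, state)
    return SubPixelOutput(out.data[:, :, :h, :w])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_state(state: NetworkState, cfg: ModelConfig, path: str | Path) -> None:
    arrays = {k: t.data for k, t in state.params.items()}
    arrays["__seed__"] = np.array(state.seed)
    arrays["__pe_shape__"] = np.array(state.pe_shape if state.pe_shape else (0, 0))
    arrays["__config__"] = np.frombuffer(
        json.dumps(dataclasses.asdict(cfg)).encode(), dtype=np.uint8)
    np.savez_compressed(Path(path), **arrays)


def load_state(path: str | Path) -> tuple[NetworkState, ModelConfig]:
    with np.load(Path(path)) as z:
        cfg_d = json.loads(bytes(z["__config__"].tobytes()).decode())
        cfg_d["cnn_channels"] = tuple(cfg_d["cnn_channels"])
        cfg = ModelConfig(**cfg_d)
        params = {k: Tensor(z[k], requires_grad=True) for k in z.files
                  if not k.startswith("__")}
        pe_shape = tuple(int(v) for v in z["__pe_shape__"])
        return NetworkState(params=params, seed=int(z["__seed__"]),
                            pe_shape=pe_shape if pe_shape != (0, 0) else None), cfg
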