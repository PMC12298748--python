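"""Dynamic-gated multi-head cross-channel attention fusion.

This is the fusion mechanism at the heart of the model. Given per-channel
temporal features X in [B, C, L, D]:

1.  A single shared linear layer projects X to queries, keys and values
    (3D features), which are split into H heads of d_h = D / H.
2.  For every head h and every ordered channel pair (i, j), scaled
    dot-product scores A = Q_i K_j^T / sqrt(d_h) are formed over temporal
    positions and softmax-normalized over key positions — so each query
    position distributes one unit of attention over channel j's timeline,
    for every j separately.
3.  Channel i's fused value is the plain sum over all key channels j
    (including j = i) of the attention-weighted values; heads are
    concatenated back to D features and linearly projected by W_O.
4.  A dynamic gate — a sigmoid of a linear read-out of the input's global
    mean over channels and time — produces one scalar G in (0, 1) per
    sample, scaling the attention branch before the residual addition
    Y = X + G * O'.

No layer normalization or positional encoding is used anywhere; the
temporal convolution upstream is the only source of position information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax

__all__ = [
    "AttentionParams",
    "AttentionMaps",
    "project_qkv",
    "cross_channel_attention",
    "merge_heads_project",
    "dynamic_gate",
    "fuse_layer",
    "fuse_stack",
]


class AttentionParams:
    """Parameters of one fusion layer (shared across channels/positions)."""

    def __init__(self, d: int, heads: int = 4,
                 rng: np.random.Generator | None = None):
        if d % heads:
            raise ValueError(f"feature dim {d} not divisible by {heads} heads")
        rng = rng or np.random.default_rng(0)
        self.d = d
        self.heads = heads
        self.head_dim = d // heads
        scale = 1.0 / np.sqrt(d)
        self.qkv_weight = Tensor(rng.normal(0, scale, size=(d, 3 * d)),
                                 requires_grad=True)
        self.qkv_bias = Tensor(np.zeros(3 * d), requires_grad=True)
        self.out_weight = Tensor(rng.normal(0, scale, size=(d, d)),
                                 requires_grad=True)
        self.out_bias = Tensor(np.zeros(d), requires_grad=True)
        self.gate_weight = Tensor(np.zeros((d, 1)), requires_grad=True)
        self.gate_bias = Tensor(np.zeros(1), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.qkv_weight, self.qkv_bias, self.out_weight,
                self.out_bias, self.gate_weight, self.gate_bias]


@dataclass
class AttentionMaps:
    """Attention weights of one fusion layer.

    ``weights``: [B, H, C, C, L, L] — (sample, head, query channel, key
    channel, query position, key position). Each key-position row is a
    probability distribution.
    """

    weights: np.ndarray
    layer_index: int = 0


def project_qkv(x: Tensor | np.ndarray,
                p: AttentionParams) -> tuple[Tensor, Tensor, Tensor]:
    """Position-wise projection to Q, K, V, each [B, C, L, H, d_h]."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    b, c, length, d = x.shape
    if d != p.d:
        raise ValueError(f"feature dim {d} != parameter dim {p.d}")
    qkv = x @ p.qkv_weight + p.qkv_bias          # [B, C, L, 3D]
    q = qkv[..., :d]
    k = qkv[..., d:2 * d]
    v = qkv[..., 2 * d:]
    shape = (b, c, length, p.heads, p.head_dim)
    return q.reshape(shape), k.reshape(shape), v.reshape(shape)


def cross_channel_attention(q: Tensor, k: Tensor,
                            v: Tensor) -> tuple[Tensor, AttentionMaps]:
    """Scaled dot-product attention across every ordered channel pair.

    Inputs are [B, C, L, H, d_h]. Output is [B, C, L, D]: for query
    channel i, the sum over key channels j of softmax(Q_i K_j^T /
    sqrt(d_h)) V_j, heads concatenated.
    """
    b, c, length, h, dh = q.shape
    # -> [B, H, C, L, dh]
    qh = q.transpose(0, 3, 1, 2, 4)
    kh = k.transpose(0, 3, 1, 2, 4)
    vh = v.transpose(0, 3, 1, 2, 4)
    # broadcast query channel i against key channel j
    qi = qh.reshape(b, h, c, 1, length, dh)
    kj = kh.reshape(b, h, 1, c, length, dh)
    scores = (qi @ kj.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
    if not np.isfinite(scores.data).all():
        raise FloatingPointError("non-finite attention scores")
    weights = softmax(scores, axis=-1)           # [B, H, C, C, L, L]
    vj = vh.reshape(b, h, 1, c, length, dh)
    partial = weights @ vj                       # [B, H, C, C, L, dh]
    summed = partial.sum(axis=3)                 # [B, H, C, L, dh]
    out = summed.transpose(0, 2, 3, 1, 4).reshape(b, c, length, h * dh)
    return out, AttentionMaps(weights=np.array(weights.data))


def merge_heads_project(o: Tensor, p: AttentionParams) -> Tensor:
    """Position-wise output projection O' = O W_O + b_O."""
    if o.shape[-1] != p.d:
        raise ValueError(f"feature dim {o.shape[-1]} != parameter dim {p.d}")
    return o @ p.out_weight + p.out_bias


def dynamic_gate(x: Tensor | np.ndarray, p: AttentionParams) -> Tensor:
    """Per-sample sigmoid gate G in (0,1), shape [B].

    The input's mean over channel and time axes (a D-vector per sample)
    is passed through a linear layer and a sigmoid.
    """
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if x.shape[-1] != p.d:
        raise ValueError(f"feature dim {x.shape[-1]} != parameter dim {p.d}")
    x_mean = x.mean(axis=(1, 2))                 # [B, D]
    logits = x_mean @ p.gate_weight + p.gate_bias  # [B, 1]
    return logits.sigmoid().reshape(x.shape[0])


def fuse_layer(x: Tensor | np.ndarray,
               p: AttentionParams,
               layer_index: int = 0) -> tuple[Tensor, AttentionMaps]:
    """One fusion layer: Y = X + G * O' with O' the projected attention."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    q, k, v = project_qkv(x, p)
    o, maps = cross_channel_attention(q, k, v)
    o_proj = merge_heads_project(o, p)
    g = dynamic_gate(x, p)
    b = x.shape[0]
    y = x + g.reshape(b, 1, 1, 1) * o_proj
    maps.layer_index = layer_index
    return y, maps


def fuse_stack(x: Tensor | np.ndarray,
               params_list: list[AttentionParams]) -> tuple[Tensor, list[AttentionMaps]]:
    """Sequential application of independent fusion layers."""
    if not params_list:
        raise ValueError("fuse_stack requires at least one layer")
    if not isinstance(x, Tensor):
        x = Tensor(x)
    maps: list[AttentionMaps] = []
    for idx, p in enumerate(params_list):
        x, m = fuse_layer(x, p, layer_index=idx)
        maps.append(m)
    return x, maps
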