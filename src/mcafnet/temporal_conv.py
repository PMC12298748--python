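"""Per-channel temporal feature extraction (TemporalConv).

Each signal channel's [L, D] spectrogram sequence is processed
independently: the tensor is transposed to put features on the
convolution axis, a kernel-3 same-padded 1-D convolution widens the
feature count to 2D, a GELU nonlinearity is applied, and a 1x1
convolution projects back to D. Sequence length is preserved for every L.

Two convolution flavours are available. The default is the depthwise
separable form (groups = D, channel multiplier 2, then pointwise 1x1);
a dense variant, where the widening convolution mixes all D input
features, can be selected with ``dense=True``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, stack

__all__ = ["TemporalConvParams", "temporal_conv_forward", "per_channel_apply"]


class TemporalConvParams:
    """Parameters of one TemporalConv block.

    Depthwise form: ``depthwise_kernel`` [2, D, k] (multiplier m, input
    feature d, tap), ``depthwise_bias`` [2D]; dense form:
    ``dense_kernel`` [2D, D, k]. Both share ``pointwise_kernel`` [D, 2D]
    and ``pointwise_bias`` [D]. Output feature 2d + m of the depthwise
    stage is multiplier m applied to input feature d.
    """

    def __init__(self, d: int, kernel: int = 3, dense: bool = False,
                 rng: np.random.Generator | None = None):
        if kernel % 2 == 0:
            raise ValueError("kernel length must be odd for same padding")
        rng = rng or np.random.default_rng(0)
        self.d = d
        self.kernel = kernel
        self.dense = dense
        if dense:
            scale = 1.0 / np.sqrt(d * kernel)
            self.conv_kernel = Tensor(
                rng.normal(0.0, scale, size=(2 * d, d, kernel)),
                requires_grad=True)
        else:
            scale = 1.0 / np.sqrt(kernel)
            self.conv_kernel = Tensor(
                rng.normal(0.0, scale, size=(2, d, kernel)), requires_grad=True)
        self.conv_bias = Tensor(np.zeros(2 * d), requires_grad=True)
        self.pointwise_kernel = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(2 * d), size=(d, 2 * d)),
            requires_grad=True)
        self.pointwise_bias = Tensor(np.zeros(d), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.conv_kernel, self.conv_bias,
                self.pointwise_kernel, self.pointwise_bias]


def _widening_conv(x: Tensor, p: TemporalConvParams) -> Tensor:
    """Same-padded kernel-k convolution along time of x [B, D, L] -> [B, 2D, L]."""
    k = p.kernel
    half = (k - 1) // 2
    b, d, length = x.shape
    xp = x.pad(((0, 0), (0, 0), (half, half)))
    taps = [xp[:, :, t:t + length] for t in range(k)]  # each [B, D, L]
    if p.dense:
        # out[b, o, l] = sum_{d,t} w[o, d, t] * x[b, d, l+t-half]
        stacked = stack(taps, axis=2)                # [B, D, k, L]
        flat = stacked.reshape(b, d * k, length)     # [B, D*k, L]
        w = p.conv_kernel.reshape(2 * d, d * k)      # [2D, D*k]
        out = w @ flat                               # broadcast to [B, 2D, L]
    else:
        # Depthwise, multiplier 2: feature 2d+m from input feature d.
        per_mult = []
        for m in range(2):
            acc = None
            for t in range(k):
                term = taps[t] * p.conv_kernel[m, :, t].reshape(1, d, 1)
                acc = term if acc is None else acc + term
            per_mult.append(acc)                     # [B, D, L]
        interleaved = stack(per_mult, axis=2)        # [B, D, 2, L]
        out = interleaved.reshape(b, 2 * d, length)
    return out + p.conv_bias.reshape(1, 2 * d, 1)


def temporal_conv_forward(x: Tensor | np.ndarray,
                          p: TemporalConvParams) -> Tensor:
    """TemporalConv on one channel: [B, L, D] -> [B, L, D]."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if x.ndim != 3 or x.shape[2] != p.d:
        raise ValueError(
            f"expected [B, L, {p.d}] input, got shape {x.shape}")
    h = x.swapaxes(1, 2)                       # [B, D, L]
    h = _widening_conv(h, p).gelu()            # [B, 2D, L]
    h = p.pointwise_kernel @ h                 # [B, D, L]
    h = h + p.pointwise_bias.reshape(1, p.d, 1)
    return h.swapaxes(1, 2)                    # [B, L, D]


def per_channel_apply(x: Tensor | np.ndarray,
                      params_list: list[TemporalConvParams]) -> Tensor:
    """Apply channel c's TemporalConv to slice [:, c]; channels never mix.

    ``x``: [B, C, L, D]; ``params_list`` must hold one parameter set per
    channel.
    """
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if x.ndim != 4:
        raise ValueError(f"expected [B, C, L, D] input, got shape {x.shape}")
    if x.shape[1] != len(params_list):
        raise ValueError(
            f"{x.shape[1]} channels but {len(params_list)} parameter sets")
    outs = [temporal_conv_forward(x[:, c], p)
            for c, p in enumerate(params_list)]
    return stack(outs, axis=1)
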