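"""End-to-end model: TemporalConv -> attention fusion -> classifier head.

The classifier consumes a [B, C, L, D] stack of standardized log-power
spectrograms. Per-channel temporal convolutions extract channel-specific
features, a stack of dynamic-gated cross-channel attention layers fuses
the channels, the temporal axis is reduced (mean by default), the result
is flattened to C*D features, and a two-layer head (hidden width HF,
ReLU, dropout, linear, softmax) yields the five stage probabilities in
the fixed order W, N1, N2, N3, REM.

Ablation variants are pure configuration: ``use_temporal_conv=False``
and/or ``use_fusion=False`` drop the corresponding block (the latter is
the naive-concatenation baseline), and single-channel models are built
by setting C=1 and feeding one channel.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, no_grad, softmax
from .mcaf_fusion import AttentionMaps, AttentionParams, fuse_stack
from .temporal_conv import TemporalConvParams, per_channel_apply

__all__ = ["ModelConfig", "StagePrediction", "MCAFNet", "count_parameters",
           "save_checkpoint", "load_checkpoint"]

_CHECKPOINT_VERSION = "mcafnet-checkpoint-1"


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults mirror the full-size model: D=128 spectral features, C=3
    channels, L=29 frames, H=4 heads, two fusion layers, three temporal
    convolution modules, a 512-unit hidden layer and dropout 0.5.
    """

    d: int = 128
    c: int = 3
    l: int = 29
    heads: int = 4
    n_fusion_layers: int = 2
    hidden: int = 512
    n_classes: int = 5
    dropout: float = 0.5
    kernel: int = 3
    expansion: int = 2
    temporal_pool: str = "mean"          # mean | last | max
    dense_temporal_conv: bool = False
    use_temporal_conv: bool = True
    use_fusion: bool = True

    def validate(self) -> None:
        if self.d % self.heads:
            raise ValueError("D must be divisible by H")
        if self.expansion != 2:
            raise ValueError("only expansion factor 2 is supported")
        if self.temporal_pool not in ("mean", "last", "max"):
            raise ValueError(f"unknown temporal_pool {self.temporal_pool!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StagePrediction:
    """Classifier output for one epoch."""

    probabilities: np.ndarray
    predicted_stage: int
    logits: np.ndarray


class MCAFNet:
    """The assembled network.

    ``training`` toggles dropout; ``keep_attention_maps`` retains the
    per-layer attention weights of the most recent forward pass in
    ``last_attention_maps`` (off by default to bound memory).
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 keep_attention_maps: bool = False):
        self.config = config or ModelConfig()
        self.config.validate()
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        keys = ss.spawn(cfg.c + cfg.n_fusion_layers + 2)
        self.temporal_convs = [
            TemporalConvParams(cfg.d, kernel=cfg.kernel,
                               dense=cfg.dense_temporal_conv,
                               rng=np.random.default_rng(keys[i]))
            for i in range(cfg.c)
        ]
        self.fusion_layers = [
            AttentionParams(cfg.d, heads=cfg.heads,
                            rng=np.random.default_rng(keys[cfg.c + i]))
            for i in range(cfg.n_fusion_layers)
        ]
        head_rng = np.random.default_rng(keys[-2])
        d_in = cfg.c * cfg.d
        self.fc1_weight = Tensor(
            head_rng.normal(0, np.sqrt(2.0 / d_in), size=(d_in, cfg.hidden)),
            requires_grad=True)
        self.fc1_bias = Tensor(np.zeros(cfg.hidden), requires_grad=True)
        self.fc2_weight = Tensor(
            head_rng.normal(0, np.sqrt(2.0 / cfg.hidden),
                            size=(cfg.hidden, cfg.n_classes)),
            requires_grad=True)
        self.fc2_bias = Tensor(np.zeros(cfg.n_classes), requires_grad=True)
        self._dropout_rng = np.random.default_rng(keys[-1])
        self.training = False
        self.keep_attention_maps = keep_attention_maps
        self.last_attention_maps: list[AttentionMaps] = []

    # -- bookkeeping ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        if self.config.use_temporal_conv:
            for tc in self.temporal_convs:
                ps.extend(tc.params())
        if self.config.use_fusion:
            for fl in self.fusion_layers:
                ps.extend(fl.params())
        ps.extend([self.fc1_weight, self.fc1_bias,
                   self.fc2_weight, self.fc2_bias])
        return ps

    def train(self) -> "MCAFNet":
        self.training = True
        return self

    def eval(self) -> "MCAFNet":
        self.training = False
        return self

    def state_arrays(self) -> list[np.ndarray]:
        """All parameter arrays, including disabled blocks (for checkpoints)."""
        ps: list[Tensor] = []
        for tc in self.temporal_convs:
            ps.extend(tc.params())
        for fl in self.fusion_layers:
            ps.extend(fl.params())
        ps.extend([self.fc1_weight, self.fc1_bias,
                   self.fc2_weight, self.fc2_bias])
        return [p.data for p in ps]

    # -- forward -------------------------------------------------------------
    def forward_logits(self, x: Tensor | np.ndarray) -> Tensor:
        cfg = self.config
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4 or x.shape[1:] != (cfg.c, cfg.l, cfg.d):
            raise ValueError(
                f"expected [B, {cfg.c}, {cfg.l}, {cfg.d}] input, "
                f"got {x.shape}")
        h = x
        if cfg.use_temporal_conv:
            h = per_channel_apply(h, self.temporal_convs)
        if cfg.use_fusion:
            h, maps = fuse_stack(h, self.fusion_layers)
            self.last_attention_maps = maps if self.keep_attention_maps else []
        else:
            self.last_attention_maps = []
        if cfg.temporal_pool == "mean":
            pooled = h.mean(axis=2)
        elif cfg.temporal_pool == "last":
            pooled = h[:, :, -1, :]
        else:  # max, with gradient routed through the argmax positions
            mask = (h.data == h.data.max(axis=2, keepdims=True))
            mask = mask / mask.sum(axis=2, keepdims=True)
            pooled = (h * Tensor(mask)).sum(axis=2)
        flat = pooled.reshape(x.shape[0], cfg.c * cfg.d)
        hid = (flat @ self.fc1_weight + self.fc1_bias).relu()
        if self.training and cfg.dropout > 0.0:
            keep = 1.0 - cfg.dropout
            mask = (self._dropout_rng.random(hid.shape) < keep) / keep
            hid = hid * Tensor(mask)
        return hid @ self.fc2_weight + self.fc2_bias

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """Stage probabilities [B, n_classes] (softmax of the logits)."""
        return softmax(self.forward_logits(x), axis=-1)

    def predict(self, x: np.ndarray) -> list[StagePrediction]:
        """Inference on a raw array; no graph is recorded."""
        with no_grad():
            logits = self.forward_logits(x)
            probs = softmax(logits, axis=-1)
        return [
            StagePrediction(probabilities=p, predicted_stage=int(np.argmax(p)),
                            logits=lg)
            for p, lg in zip(probs.data, logits.data)
        ]


def count_parameters(model: MCAFNet) -> dict[str, int]:
    """Trainable scalar counts, total and per submodule.

    With the default configuration the depthwise temporal convolutions
    contribute ~0.10M, the two fusion layers ~0.13M and the classifier
    head ~0.20M, for a total near 0.43M. (The dense convolution variant
    raises the total to ~0.73M.)
    """
    counts: dict[str, int] = {}
    if model.config.use_temporal_conv:
        counts["temporal_conv"] = sum(
            p.data.size for tc in model.temporal_convs for p in tc.params())
    if model.config.use_fusion:
        counts["fusion"] = sum(
            p.data.size for fl in model.fusion_layers for p in fl.params())
    counts["classifier_head"] = sum(
        t.data.size for t in (model.fc1_weight, model.fc1_bias,
                              model.fc2_weight, model.fc2_bias))
    counts["total"] = sum(counts.values())
    return counts


def save_checkpoint(model: MCAFNet, path) -> None:
    """Single-file checkpoint: JSON config header + parameter arrays."""
    header = json.dumps({"version": _CHECKPOINT_VERSION,
                         "config": model.config.to_dict()})
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    with open(path, "wb") as f:
        np.savez(f, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path, expected_config: ModelConfig | None = None) -> MCAFNet:
    """Load a checkpoint; raises on version/config mismatch or corruption."""
    try:
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            arrays = [data[f"param_{i}"]
                      for i in range(len(data.files) - 1)]
    except (ValueError, OSError, KeyError, json.JSONDecodeError,
            zipfile.BadZipFile) as exc:
        raise ValueError(f"unreadable checkpoint {path}: {exc}") from exc
    if header.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unknown checkpoint version {header.get('version')!r}")
    cfg = ModelConfig(**header["config"])
    if expected_config is not None:
        for key, val in expected_config.to_dict().items():
            got = cfg.to_dict()[key]
            if got != val:
                raise ValueError(
                    f"checkpoint config mismatch on {key!r}: "
                    f"checkpoint has {got!r}, expected {val!r}")
    model = MCAFNet(cfg)
    targets: list[Tensor] = []
    for tc in model.temporal_convs:
        targets.extend(tc.params())
    for fl in model.fusion_layers:
        targets.extend(fl.params())
    targets.extend([model.fc1_weight, model.fc1_bias,
                    model.fc2_weight, model.fc2_bias])
    if len(targets) != len(arrays):
        raise ValueError("checkpoint parameter count mismatch")
    for t, a in zip(targets, arrays):
        if t.data.shape != a.shape:
            raise ValueError("checkpoint parameter shape mismatch")
        t.data = a.astype(np.float64)
    return model
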