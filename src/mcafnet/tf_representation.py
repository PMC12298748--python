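"""Time-frequency preprocessing: STFT log-power spectrograms.

Each 30 s epoch is framed with a 2 s Hamming window at 50% overlap and
transformed with a 256-point FFT, giving T = 29 frames. Powers are floored
and log-scaled, the one-sided spectrum is reduced from 129 to 128 bins
(Nyquist dropped by default), and each channel's T x F matrix is
standardized to zero mean, unit variance. The resulting [C, 29, 128]
tensor is the model input; the frequency axis doubles as the feature
dimension D of the network.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .records import EpochRecord

__all__ = [
    "StftConfig",
    "TimeFrequencyTensor",
    "stft_log_power",
    "reduce_bins",
    "standardize",
    "epoch_to_tensor",
    "epochs_to_dataset",
    "pool_frequency_bins",
    "save_tf_dataset",
    "load_tf_dataset",
]


@dataclass
class StftConfig:
    """Spectrogram parameters.

    ``bin_reduction`` selects which of the 129 one-sided bins is dropped to
    reach the even feature dimension of 128: ``"drop_nyquist"`` (default)
    removes the highest bin, ``"drop_dc"`` removes the zero-frequency bin.
    """

    n_fft: int = 256
    window_seconds: float = 2.0
    overlap_fraction: float = 0.5
    window_kind: str = "hamming"
    log_epsilon: float = 1e-10
    bin_reduction: str = "drop_nyquist"

    def validate(self, sampling_rate: float) -> None:
        win = self.window_samples(sampling_rate)
        if win > self.n_fft:
            raise ValueError(
                f"window length {win} samples exceeds n_fft={self.n_fft}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.bin_reduction not in ("drop_nyquist", "drop_dc"):
            raise ValueError(f"unknown bin_reduction {self.bin_reduction!r}")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")

    def window_samples(self, sampling_rate: float) -> int:
        return int(round(self.window_seconds * sampling_rate))

    def hop_samples(self, sampling_rate: float) -> int:
        hop = int(round(self.window_samples(sampling_rate)
                        * (1.0 - self.overlap_fraction)))
        return max(hop, 1)

    def n_frames(self, n_samples: int, sampling_rate: float) -> int:
        win = self.window_samples(sampling_rate)
        hop = self.hop_samples(sampling_rate)
        if n_samples < win:
            raise ValueError("epoch too short")
        return (n_samples - win) // hop + 1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TimeFrequencyTensor:
    """Standardized log-power spectrogram stack, [C, T, F]."""

    values: np.ndarray
    label: str | None = None
    subject_id: str = ""
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be [channels, frames, bins]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def stft_log_power(epoch: EpochRecord, cfg: StftConfig | None = None) -> np.ndarray:
    """Log-power one-sided spectrogram per channel, [C, T, n_fft//2 + 1].

    Frames the raw signal with hop = window * (1 - overlap), no edge
    padding, applies a periodic window, and takes ``log(|DFT|^2 + eps)``.
    """
    cfg = cfg or StftConfig()
    cfg.validate(epoch.sampling_rate)
    win = cfg.window_samples(epoch.sampling_rate)
    hop = cfg.hop_samples(epoch.sampling_rate)
    x = epoch.signals
    if x.shape[1] < win:
        raise ValueError("epoch too short")
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")
    # [C, T, win] view of overlapping frames
    frames = sliding_window_view(x, win, axis=1)[:, ::hop, :]
    window = get_window(cfg.window_kind, win, fftbins=True)
    spec = np.fft.rfft(frames * window, n=cfg.n_fft, axis=-1)
    power = np.abs(spec) ** 2
    return np.log(power + cfg.log_epsilon)


def reduce_bins(spec: np.ndarray, cfg: StftConfig | None = None) -> np.ndarray:
    """Drop one bin of the one-sided spectrum, 129 -> 128 under defaults."""
    cfg = cfg or StftConfig()
    expected = cfg.n_fft // 2 + 1
    if spec.shape[-1] != expected:
        raise ValueError(
            f"expected {expected} one-sided bins, got {spec.shape[-1]}")
    if cfg.bin_reduction == "drop_nyquist":
        return spec[..., :-1]
    if cfg.bin_reduction == "drop_dc":
        return spec[..., 1:]
    raise ValueError(f"unknown bin_reduction {cfg.bin_reduction!r}")


def standardize(tf: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling of each channel's full T x F matrix.

    Uses the population standard deviation. Raises on a constant channel.
    """
    tf = np.asarray(tf, dtype=np.float64)
    if not np.isfinite(tf).all():
        raise ValueError("non-finite input")
    mean = tf.mean(axis=(-2, -1), keepdims=True)
    std = tf.std(axis=(-2, -1), keepdims=True)
    if np.any(std == 0):
        raise ValueError("degenerate channel: zero variance")
    return (tf - mean) / std


def epoch_to_tensor(epoch: EpochRecord,
                    cfg: StftConfig | None = None) -> TimeFrequencyTensor:
    """Full preprocessing of one epoch: STFT -> log power -> 128 bins -> z-score."""
    cfg = cfg or StftConfig()
    spec = reduce_bins(stft_log_power(epoch, cfg), cfg)
    return TimeFrequencyTensor(
        values=standardize(spec),
        label=epoch.label,
        subject_id=epoch.subject_id,
        epoch_index=epoch.epoch_index,
    )


def pool_frequency_bins(values: np.ndarray, factor: int) -> np.ndarray:
    """Average adjacent frequency bins in groups of ``factor``.

    Coarsens the feature dimension (e.g. 128 -> 32 at factor 4, about
    1.6 Hz per pooled bin) for reduced-size model configurations; the
    stage-discriminative bands remain separable at that resolution.
    """
    f = values.shape[-1]
    if factor < 1 or f % factor:
        raise ValueError(f"bin count {f} not divisible by factor {factor}")
    shape = values.shape[:-1] + (f // factor, factor)
    return values.reshape(shape).mean(axis=-1)


def epochs_to_dataset(
    epochs: Iterable[EpochRecord],
    cfg: StftConfig | None = None,
    pool_factor: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Preprocess an epoch stream into stacked arrays.

    Returns ``(X, y, subjects)`` with X [N, C, T, F], integer labels y [N]
    (-1 for unlabeled epochs) and subject ids [N].
    """
    from .records import STAGE_TO_INDEX

    cfg = cfg or StftConfig()
    xs, ys, subjects = [], [], []
    for ep in epochs:
        t = epoch_to_tensor(ep, cfg)
        v = t.values
        if pool_factor > 1:
            v = standardize(pool_frequency_bins(v, pool_factor))
        xs.append(v)
        ys.append(STAGE_TO_INDEX[ep.label] if ep.label is not None else -1)
        subjects.append(ep.subject_id)
    if not xs:
        raise ValueError("no epochs to preprocess")
    return np.stack(xs), np.asarray(ys, dtype=np.int64), np.asarray(subjects)


def save_tf_dataset(path, X: np.ndarray, y: np.ndarray,
                    subjects: Sequence[str], cfg: StftConfig) -> None:
    """Write a preprocessed dataset to an HDF5 container.

    Datasets: ``tf`` [N, C, T, F], ``labels`` [N], ``subjects`` [N];
    the STFT configuration is stored in root attributes. Timestamp
    tracking is disabled so identical inputs give identical files.
    """
    import h5py

    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("tf", data=np.asarray(X, dtype=np.float32),
                         track_times=False)
        f.create_dataset("labels", data=np.asarray(y, dtype=np.int64),
                         track_times=False)
        subj = np.asarray([str(s) for s in subjects], dtype="S64")
        f.create_dataset("subjects", data=subj, track_times=False)
        for k, v in cfg.to_dict().items():
            f.attrs[k] = v


def load_tf_dataset(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, StftConfig]:
    import h5py

    with h5py.File(path, "r") as f:
        X = np.asarray(f["tf"], dtype=np.float64)
        y = np.asarray(f["labels"], dtype=np.int64)
        subjects = np.asarray([s.decode() for s in f["subjects"][()]])
        cfg = StftConfig(**{k: f.attrs[k] for k in StftConfig().to_dict()})
    return X, y, subjects, cfg
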