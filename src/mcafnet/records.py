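"""Core record types shared across the package.

The classification unit throughout is the 30 s polysomnography epoch: a
small multi-channel slab of signal (two EEG derivations plus one horizontal
EOG by default) with a five-class sleep-stage label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical stage order; index positions are used everywhere (labels,
#: confusion matrices, classifier outputs).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
STAGE_TO_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Default channel roles, frontal EEG / parieto-occipital EEG / horizontal EOG.
DEFAULT_CHANNELS: tuple[str, ...] = ("EEG Fpz-Cz", "EEG Pz-Oz", "EOG horizontal")

EPOCH_SECONDS = 30


@dataclass
class EpochRecord:
    """One 30 s multi-channel signal segment.

    Parameters
    ----------
    signals
        Array [C, S] in microvolts, C channels by S samples.
    sampling_rate
        Samples per second; S must equal ``sampling_rate * 30`` exactly.
    label
        Stage code in {W, N1, N2, N3, REM}, or None for unlabeled epochs.
    subject_id
        Opaque identifier used for subject-wise cross-validation splits.
    epoch_index
        Position of the epoch within its source recording.
    """

    signals: np.ndarray
    sampling_rate: float = 100.0
    label: str | None = None
    subject_id: str = ""
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D [channels, samples] array")
        expected = int(round(self.sampling_rate * EPOCH_SECONDS))
        if self.signals.shape[1] != expected:
            raise ValueError(
                f"epoch must contain sampling_rate*30 = {expected} samples, "
                f"got {self.signals.shape[1]}")
        if not np.isfinite(self.signals).all():
            raise ValueError("signals contain non-finite values")
        if self.label is not None and self.label not in STAGE_TO_INDEX:
            raise ValueError(f"unknown stage label {self.label!r}")
        if self.epoch_index < 0:
            raise ValueError("epoch_index must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def label_index(self) -> int:
        if self.label is None:
            raise ValueError("epoch has no label")
        return STAGE_TO_INDEX[self.label]
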