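"""Stage-conditioned synthetic polysomnography generator.

Produces 30 s, 100 Hz, 3-channel epochs (frontal EEG, posterior EEG,
horizontal EOG) whose spectral content carries the features a sleep
stager exploits:

* W   — 8-12 Hz alpha (posterior-dominant) plus frequent EOG deflections,
* N1  — 4-7 Hz theta with slow eye movements in the EOG,
* N2  — theta background with 12-14 Hz spindle bursts and K-complexes,
* N3  — high-amplitude 0.5-2 Hz slow waves,
* REM — low-amplitude mixed-frequency EEG with rapid EOG saccades,

all riding on broadband Gaussian noise. Oscillations are realized as
narrowband-filtered Gaussian noise (4th-order Butterworth band-pass,
zero-phase) rather than pure sinusoids; transient events are placed
uniformly at random with rejection so they always lie fully inside the
epoch. Amplitudes are nominal microvolts in physiological EEG ranges;
absolute scale is irrelevant after per-epoch standardization but is kept
realistic for EDF export.

Everything is driven by explicit NumPy generators, so one seed yields a
bit-identical dataset.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .records import EPOCH_SECONDS, STAGES, EpochRecord

__all__ = [
    "Oscillation", "Transient", "ChannelSignature", "StageSignatureConfig",
    "SyntheticDataset", "default_signature_config", "eog_only_cue_config",
    "generate_epoch", "generate_dataset",
]

SAMPLING_RATE = 100.0
NYQUIST = SAMPLING_RATE / 2.0
#: Channel roles in signal order; these map onto DEFAULT_CHANNELS.
CHANNEL_ROLES: tuple[str, ...] = ("eeg_frontal", "eeg_posterior", "eog")

TRANSIENT_KINDS = ("spindle", "k_complex", "saccade", "slow_eye_movement")


@dataclass
class Oscillation:
    """Narrowband component: center frequency, full bandwidth, amplitude.

    The realized component is band-limited Gaussian noise scaled so its
    RMS equals ``amplitude_uv / sqrt(2)`` (the RMS of a sinusoid with
    that peak amplitude).
    """

    center_hz: float
    bandwidth_hz: float
    amplitude_uv: float


@dataclass
class Transient:
    """Poisson-placed event: kind, expected count per epoch, duration,
    peak amplitude."""

    kind: str
    rate_per_epoch: float
    duration_s: float
    amplitude_uv: float


@dataclass
class ChannelSignature:
    oscillations: list[Oscillation] = field(default_factory=list)
    transients: list[Transient] = field(default_factory=list)
    noise_sigma_uv: float = 10.0


@dataclass
class StageSignatureConfig:
    """Per-stage, per-channel-role signal recipe plus subject jitter ranges."""

    signatures: dict[str, dict[str, ChannelSignature]] = field(default_factory=dict)
    amplitude_jitter: float = 0.15   # per-subject uniform multiplier half-range
    frequency_jitter: float = 0.05

    def validate(self) -> None:
        for stage, channels in self.signatures.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            for role, sig in channels.items():
                if role not in CHANNEL_ROLES:
                    raise ValueError(f"unknown channel role {role!r}")
                for osc in sig.oscillations:
                    if not 0 < osc.center_hz < NYQUIST:
                        raise ValueError(
                            f"oscillation at {osc.center_hz} Hz out of band")
                    if osc.bandwidth_hz <= 0 or osc.amplitude_uv <= 0:
                        raise ValueError("bandwidth and amplitude must be positive")
                for tr in sig.transients:
                    if tr.kind not in TRANSIENT_KINDS:
                        raise ValueError(f"unknown transient kind {tr.kind!r}")
                    if min(tr.rate_per_epoch, tr.duration_s,
                           tr.amplitude_uv) <= 0:
                        raise ValueError("transient parameters must be positive")
                if sig.noise_sigma_uv < 0:
                    raise ValueError("noise sigma must be nonnegative")

    def jittered(self, rng: np.random.Generator) -> "StageSignatureConfig":
        """Per-subject copy with random amplitude/frequency perturbation."""
        out = copy.deepcopy(self)
        amp = 1.0 + rng.uniform(-self.amplitude_jitter, self.amplitude_jitter)
        freq = 1.0 + rng.uniform(-self.frequency_jitter, self.frequency_jitter)
        for channels in out.signatures.values():
            for sig in channels.values():
                for osc in sig.oscillations:
                    osc.amplitude_uv *= amp
                    osc.center_hz = min(osc.center_hz * freq, NYQUIST - 1.0)
                for tr in sig.transients:
                    tr.amplitude_uv *= amp
                sig.noise_sigma_uv *= amp
        return out


def default_signature_config() -> StageSignatureConfig:
    """The standard stage recipes (amplitudes in microvolts)."""
    s = {
        "W": {
            "eeg_frontal": ChannelSignature(
                [Oscillation(10.0, 4.0, 30.0)], [], 12.0),
            "eeg_posterior": ChannelSignature(
                [Oscillation(10.0, 4.0, 45.0)], [], 12.0),
            "eog": ChannelSignature(
                [], [Transient("saccade", 6.0, 0.3, 80.0)], 12.0),
        },
        "N1": {
            "eeg_frontal": ChannelSignature(
                [Oscillation(5.5, 3.0, 30.0)], [], 10.0),
            "eeg_posterior": ChannelSignature(
                [Oscillation(5.5, 3.0, 25.0)], [], 10.0),
            "eog": ChannelSignature(
                [], [Transient("slow_eye_movement", 3.0, 1.5, 60.0)], 10.0),
        },
        "N2": {
            "eeg_frontal": ChannelSignature(
                [Oscillation(5.5, 3.0, 25.0)],
                [Transient("spindle", 3.0, 1.0, 50.0),
                 Transient("k_complex", 1.5, 0.8, 120.0)], 10.0),
            "eeg_posterior": ChannelSignature(
                [Oscillation(5.5, 3.0, 20.0)],
                [Transient("spindle", 3.0, 1.0, 40.0),
                 Transient("k_complex", 1.5, 0.8, 80.0)], 10.0),
            "eog": ChannelSignature([], [], 8.0),
        },
        "N3": {
            "eeg_frontal": ChannelSignature(
                [Oscillation(1.25, 1.5, 140.0)], [], 12.0),
            "eeg_posterior": ChannelSignature(
                [Oscillation(1.25, 1.5, 100.0)], [], 12.0),
            "eog": ChannelSignature(
                [Oscillation(1.25, 1.5, 30.0)], [], 8.0),
        },
        "REM": {
            "eeg_frontal": ChannelSignature(
                [Oscillation(5.5, 3.0, 15.0)], [], 10.0),
            "eeg_posterior": ChannelSignature(
                [Oscillation(6.5, 3.0, 15.0)], [], 10.0),
            "eog": ChannelSignature(
                [], [Transient("saccade", 8.0, 0.25, 100.0)], 8.0),
        },
    }
    return StageSignatureConfig(signatures=s)


def eog_only_cue_config() -> StageSignatureConfig:
    """Variant in which REM and N1 share identical EEG signatures.

    The only feature separating REM from N1 is the EOG channel (rapid
    saccades vs slow eye movements), so a model without access to the
    EOG cannot tell the two apart. Used to probe the value of
    cross-channel fusion.
    """
    cfg = default_signature_config()
    cfg.signatures["REM"]["eeg_frontal"] = copy.deepcopy(
        cfg.signatures["N1"]["eeg_frontal"])
    cfg.signatures["REM"]["eeg_posterior"] = copy.deepcopy(
        cfg.signatures["N1"]["eeg_posterior"])
    return cfg


@dataclass
class SyntheticDataset:
    epochs: list[EpochRecord]
    stage_proportions: dict[str, float]
    seed: int

    @property
    def subjects(self) -> list[str]:
        return sorted({e.subject_id for e in self.epochs})


# -- waveform primitives -------------------------------------------------------

def _bandlimited_noise(n: int, osc: Oscillation,
                       rng: np.random.Generator) -> np.ndarray:
    lo = max(osc.center_hz - osc.bandwidth_hz / 2.0, 0.05)
    hi = min(osc.center_hz + osc.bandwidth_hz / 2.0, NYQUIST - 0.5)
    sos = butter(4, [lo, hi], btype="bandpass", fs=SAMPLING_RATE,
                 output="sos")
    white = rng.standard_normal(n + 400)      # extra samples absorb edges
    band = sosfiltfilt(sos, white)[200:200 + n]
    rms = np.sqrt(np.mean(band**2))
    if rms == 0:
        return np.zeros(n)
    return band * (osc.amplitude_uv / np.sqrt(2.0) / rms)


def _transient_waveform(tr: Transient, rng: np.random.Generator) -> np.ndarray:
    n = max(int(round(tr.duration_s * SAMPLING_RATE)), 2)
    t = np.arange(n) / SAMPLING_RATE
    d = tr.duration_s
    if tr.kind == "spindle":
        env = np.hanning(n)
        phase = rng.uniform(0, 2 * np.pi)
        return tr.amplitude_uv * env * np.sin(2 * np.pi * 13.0 * t + phase)
    if tr.kind == "k_complex":
        # one full biphasic cycle under a Hann envelope
        return tr.amplitude_uv * np.hanning(n) * np.sin(2 * np.pi * t / d)
    if tr.kind == "saccade":
        tau = 0.02 * d
        sign = rng.choice((-1.0, 1.0))
        pulse = (1.0 / (1.0 + np.exp(-(t - 0.15 * d) / tau))
                 - 1.0 / (1.0 + np.exp(-(t - 0.85 * d) / tau)))
        return sign * tr.amplitude_uv * pulse
    if tr.kind == "slow_eye_movement":
        sign = rng.choice((-1.0, 1.0))
        return sign * tr.amplitude_uv * np.sin(np.pi * t / d)
    raise ValueError(f"unknown transient kind {tr.kind!r}")


def _place_events(tr: Transient, rng: np.random.Generator,
                  n_samples: int) -> list[tuple[int, np.ndarray]]:
    """Poisson count, uniform placement rejection-resampled to fit inside."""
    count = rng.poisson(tr.rate_per_epoch)
    dur = int(round(tr.duration_s * SAMPLING_RATE))
    events = []
    for _ in range(count):
        if dur >= n_samples:
            start = 0
        else:
            start = int(rng.integers(0, n_samples - dur + 1))
        events.append((start, _transient_waveform(tr, rng)))
    return events


def generate_epoch(stage: str,
                   cfg: StageSignatureConfig | None = None,
                   rng: np.random.Generator | None = None,
                   subject_id: str = "synthetic",
                   epoch_index: int = 0,
                   include_noise: bool = True,
                   include_oscillations: bool = True,
                   channel_roles: tuple[str, ...] = CHANNEL_ROLES,
                   ) -> EpochRecord:
    """One synthetic 30 s epoch of the given stage.

    ``include_noise`` / ``include_oscillations`` allow noise-free or
    transients-only renders for diagnostics.
    """
    cfg = cfg or default_signature_config()
    if stage not in cfg.signatures:
        raise ValueError(f"invalid stage {stage!r}")
    rng = rng or np.random.default_rng(0)
    n = int(SAMPLING_RATE * EPOCH_SECONDS)
    signals = np.zeros((len(channel_roles), n))
    for ci, role in enumerate(channel_roles):
        sig = cfg.signatures[stage].get(role, ChannelSignature())
        x = np.zeros(n)
        if include_oscillations:
            for osc in sig.oscillations:
                x += _bandlimited_noise(n, osc, rng)
        for tr in sig.transients:
            for start, wave in _place_events(tr, rng, n):
                x[start:start + len(wave)] += wave
        if include_noise and sig.noise_sigma_uv > 0:
            x += rng.normal(0.0, sig.noise_sigma_uv, size=n)
        signals[ci] = x
    return EpochRecord(signals=signals, sampling_rate=SAMPLING_RATE,
                       label=stage, subject_id=subject_id,
                       epoch_index=epoch_index)


def _quota(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n epochs to stages."""
    if abs(sum(proportions.values()) - 1.0) > 1e-6:
        raise ValueError("stage proportions must sum to 1")
    if any(p < 0 for p in proportions.values()):
        raise ValueError("stage proportions must be nonnegative")
    raw = {s: n * p for s, p in proportions.items()}
    counts = {s: int(np.floor(v)) for s, v in raw.items()}
    remainder = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda s: raw[s] - counts[s], reverse=True)
    for s in by_frac[:remainder]:
        counts[s] += 1
    return counts


def generate_dataset(n_epochs: int,
                     n_subjects: int,
                     stage_proportions: dict[str, float] | None = None,
                     cfg: StageSignatureConfig | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Seeded multi-subject dataset with exact-quota stage counts.

    Each synthetic subject gets its own jittered copy of the stage
    recipes (amplitude and frequency scaling), and epochs are dealt to
    subjects round-robin so every subject sees every stage.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    cfg = cfg or default_signature_config()
    cfg.validate()
    proportions = stage_proportions or {s: 0.2 for s in STAGES}
    counts = _quota(n_epochs, proportions)
    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(n_subjects + 1)
    order_rng = np.random.default_rng(subj_seeds[-1])
    subject_cfgs = []
    subject_rngs = []
    for i in range(n_subjects):
        sr = np.random.default_rng(subj_seeds[i])
        subject_cfgs.append(cfg.jittered(sr))
        subject_rngs.append(sr)
    labels = [s for s in STAGES for _ in range(counts.get(s, 0))]
    order_rng.shuffle(labels)
    epochs: list[EpochRecord] = []
    next_index = [0] * n_subjects
    for i, stage in enumerate(labels):
        si = i % n_subjects
        epochs.append(generate_epoch(
            stage, cfg=subject_cfgs[si], rng=subject_rngs[si],
            subject_id=f"SYN{si:03d}", epoch_index=next_index[si]))
        next_index[si] += 1
    return SyntheticDataset(epochs=epochs,
                            stage_proportions=dict(proportions), seed=seed)
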