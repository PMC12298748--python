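"""EDF polysomnography I/O and R&K label handling.

Reading goes through MNE (signals) and MNE's annotation reader
(hypnograms). Writing uses a small built-in EDF/EDF+ serializer: signals
are stored as 16-bit integers against a fixed physical range, and the
hypnogram goes into a separate EDF+ file holding only an annotation
channel, mirroring the file layout of public sleep archives (one
``*-PSG.edf`` plus one ``*-Hypnogram.edf`` per recording).

Label policy: the eight R&K codes map onto the modern five classes with
S3 and S4 merged into N3; MOVEMENT and UNKNOWN epochs are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import DEFAULT_CHANNELS, EPOCH_SECONDS, EpochRecord
from .synthetic_psg import SyntheticDataset

__all__ = ["LabelMap", "load_recording", "trim_to_in_bed", "write_edf"]

EXCLUDE = "EXCLUDE"

#: Annotation text used in EDF+ hypnograms, per R&K code.
RK_TO_ANNOTATION = {
    "W": "Sleep stage W",
    "S1": "Sleep stage 1",
    "S2": "Sleep stage 2",
    "S3": "Sleep stage 3",
    "S4": "Sleep stage 4",
    "REM": "Sleep stage R",
    "MOVEMENT": "Movement time",
    "UNKNOWN": "Sleep stage ?",
}
ANNOTATION_TO_RK = {v: k for k, v in RK_TO_ANNOTATION.items()}

#: Physical range used when quantizing to 16-bit EDF samples.
PHYS_RANGE_UV = 1000.0
DIG_MAX = 32767


@dataclass
class LabelMap:
    """R&K eight-code to five-class mapping (S3+S4 -> N3; MOVEMENT and
    UNKNOWN -> EXCLUDE)."""

    mapping: dict[str, str] = field(default_factory=lambda: {
        "W": "W", "S1": "N1", "S2": "N2", "S3": "N3", "S4": "N3",
        "REM": "REM", "MOVEMENT": EXCLUDE, "UNKNOWN": EXCLUDE,
    })

    def __call__(self, rk_code: str) -> str:
        if rk_code not in self.mapping:
            raise ValueError(f"unknown R&K code {rk_code!r}")
        return self.mapping[rk_code]


def _subject_from_filename(path) -> str:
    stem = Path(path).stem.split("-")[0]
    # Sleep-cassette/telemetry style names: SC4ssN / ST7ssN with subject
    # number in characters 3-4, night digit in character 5.
    if len(stem) >= 6 and stem[:2] in ("SC", "ST") and stem[2:6].isdigit():
        return stem[:5]
    return stem


def _expand_annotations(onsets, durations, descriptions,
                        label_map: LabelMap) -> dict[int, str]:
    """Annotation intervals -> {epoch index: 5-class label or EXCLUDE}."""
    labels: dict[int, str] = {}
    for onset, duration, desc in zip(onsets, durations, descriptions):
        desc = str(desc).strip()
        if desc not in ANNOTATION_TO_RK:
            continue  # non-stage annotations are ignored
        stage = label_map(ANNOTATION_TO_RK[desc])
        first = int(round(onset / EPOCH_SECONDS))
        count = int(round(duration / EPOCH_SECONDS))
        for e in range(first, first + max(count, 1)):
            labels[e] = stage
    return labels


def load_recording(psg_path, hypnogram_path,
                   channel_names=DEFAULT_CHANNELS,
                   label_map: LabelMap | None = None) -> list[EpochRecord]:
    """Read an EDF recording + EDF+ hypnogram into labeled 30 s epochs.

    Requested channels must be present; non-100 Hz signals are resampled
    by polyphase filtering with a warning. Epochs labeled MOVEMENT or
    UNKNOWN (or falling outside the annotated span) are dropped.
    """
    import mne

    label_map = label_map or LabelMap()
    raw = mne.io.read_raw_edf(psg_path, preload=True, verbose="error")
    missing = [c for c in channel_names if c not in raw.ch_names]
    if missing:
        raise ValueError(
            f"channels {missing} not found; available: {raw.ch_names}")
    data = raw.get_data(picks=list(channel_names)) * 1e6  # V -> uV
    sfreq = float(raw.info["sfreq"])
    if abs(sfreq - 100.0) > 1e-6:
        from scipy.signal import resample_poly
        from fractions import Fraction

        frac = Fraction(100, int(round(sfreq))).limit_denominator(1000)
        warnings.warn(
            f"resampling {psg_path} from {sfreq} Hz to 100 Hz")
        data = resample_poly(data, frac.numerator, frac.denominator, axis=1)
    ann = mne.read_annotations(hypnogram_path)
    labels = _expand_annotations(ann.onset, ann.duration, ann.description,
                                 label_map)
    samples_per_epoch = int(100 * EPOCH_SECONDS)
    n_epochs = data.shape[1] // samples_per_epoch
    subject = _subject_from_filename(psg_path)
    records: list[EpochRecord] = []
    for e in range(n_epochs):
        stage = labels.get(e)
        if stage is None or stage == EXCLUDE:
            continue
        seg = data[:, e * samples_per_epoch:(e + 1) * samples_per_epoch]
        records.append(EpochRecord(signals=seg, sampling_rate=100.0,
                                   label=stage, subject_id=subject,
                                   epoch_index=e))
    return records


def trim_to_in_bed(records: list[EpochRecord],
                   before_after_minutes: float = 30.0) -> list[EpochRecord]:
    """Keep the window from 30 min before sleep onset to 30 min after
    the final sleep offset (first/last non-W epoch), clipped to the
    recording bounds. An all-wake recording is returned unchanged with a
    warning."""
    non_wake = [r.epoch_index for r in records if r.label != "W"]
    if not non_wake:
        warnings.warn("recording contains no sleep epochs; not trimmed")
        return list(records)
    margin = int(round(before_after_minutes * 60 / EPOCH_SECONDS))
    lo = min(non_wake) - margin
    hi = max(non_wake) + margin
    return [r for r in records if lo <= r.epoch_index <= hi]


# -- EDF writing ---------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long: {text!r}")
    return b + b" " * (width - len(b))


def _edf_header(n_records: int, record_seconds: float,
                signal_labels: list[str], samples_per_record: list[int],
                physical: list[tuple[float, float, str]],
                edf_plus: bool = False) -> bytes:
    ns = len(signal_labels)
    head = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2000 X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("EDF+C" if edf_plus else "", 44),
        _pad(str(n_records), 8),
        _pad(f"{record_seconds:g}", 8),
        _pad(str(ns), 4),
    ])
    cols = [
        [_pad(lbl, 16) for lbl in signal_labels],
        [_pad("", 80)] * ns,                                # transducer
        [_pad(dim, 8) for (_, _, dim) in physical],
        [_pad(f"{lo:g}", 8) for (lo, _, _) in physical],
        [_pad(f"{hi:g}", 8) for (_, hi, _) in physical],
        [_pad(str(-DIG_MAX - 1), 8)] * ns,
        [_pad(str(DIG_MAX), 8)] * ns,
        [_pad("", 80)] * ns,                                # prefiltering
        [_pad(str(s), 8) for s in samples_per_record],
        [_pad("", 32)] * ns,
    ]
    return head + b"".join(b"".join(col) for col in cols)


def _quantize(x: np.ndarray) -> np.ndarray:
    # EDF affine convention: digital = (phys - physmin) / step + digmin
    step = 2 * PHYS_RANGE_UV / (2 * DIG_MAX + 1)
    dig = np.round((x + PHYS_RANGE_UV) / step) - DIG_MAX - 1
    return np.clip(dig, -DIG_MAX - 1, DIG_MAX).astype("<i2")


def _write_psg_edf(path, signals: np.ndarray, channel_names) -> None:
    """Plain EDF with one 30 s data record per epoch."""
    c, total = signals.shape
    spr = int(100 * EPOCH_SECONDS)
    n_records = total // spr
    physical = [(-PHYS_RANGE_UV, PHYS_RANGE_UV, "uV")] * c
    header = _edf_header(n_records, EPOCH_SECONDS, list(channel_names),
                         [spr] * c, physical)
    digital = _quantize(signals)
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            for ch in range(c):
                f.write(digital[ch, r * spr:(r + 1) * spr].tobytes())


def _tal(onset: float, duration: float | None, text: str) -> bytes:
    out = f"+{onset:g}"
    if duration is not None:
        out += f"\x15{duration:g}"
    out += f"\x14{text}\x14\x00"
    return out.encode("ascii")


def _write_hypnogram_edf(path, stage_runs: list[tuple[float, float, str]],
                         total_seconds: float) -> None:
    """EDF+ file holding only an annotation channel.

    ``stage_runs``: (onset_s, duration_s, annotation text) per run of
    identical stages.
    """
    payload = _tal(0.0, None, "")  # timekeeping TAL of the single record
    for onset, duration, text in stage_runs:
        payload += _tal(onset, duration, text)
    if len(payload) % 2:
        payload += b"\x00"
    spr = len(payload) // 2
    header = _edf_header(1, total_seconds, ["EDF Annotations"], [spr],
                         [(-1.0, 1.0, "")], edf_plus=True)
    with open(path, "wb") as f:
        f.write(header)
        f.write(payload)


_FIVE_TO_RK = {"W": "W", "N1": "S1", "N2": "S2", "N3": "S3", "REM": "REM"}


def write_edf(dataset: SyntheticDataset, out_dir) -> list[Path]:
    """Write one PSG EDF + hypnogram EDF+ pair per synthetic subject.

    Signals are quantized to 16 bits over +/-1000 uV (step ~0.03 uV);
    ``load_recording`` round-trips the labels exactly and the signals to
    within that quantization step. N3 epochs are annotated with the R&K
    code S3.
    """
    if not dataset.epochs:
        raise ValueError("empty dataset")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for subject in dataset.subjects:
        eps = sorted((e for e in dataset.epochs if e.subject_id == subject),
                     key=lambda e: e.epoch_index)
        signals = np.concatenate([e.signals for e in eps], axis=1)
        psg_path = out_dir / f"{subject}-PSG.edf"
        _write_psg_edf(psg_path, signals, DEFAULT_CHANNELS)
        runs: list[tuple[float, float, str]] = []
        for i, e in enumerate(eps):
            text = RK_TO_ANNOTATION[_FIVE_TO_RK[e.label]]
            onset = i * float(EPOCH_SECONDS)
            if runs and runs[-1][2] == text and \
                    abs(runs[-1][0] + runs[-1][1] - onset) < 1e-9:
                runs[-1] = (runs[-1][0], runs[-1][1] + EPOCH_SECONDS, text)
            else:
                runs.append((onset, float(EPOCH_SECONDS), text))
        hyp_path = out_dir / f"{subject}-Hypnogram.edf"
        _write_hypnogram_edf(hyp_path, runs, len(eps) * float(EPOCH_SECONDS))
        paths.extend([psg_path, hyp_path])
    return paths
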