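"""Evaluation: confusion matrices, agreement statistics, hypnograms,
attention-weight aggregation.

All metrics are stored as fractions; rendering to percent happens only
in reports. Stage order is fixed as (W, N1, N2, N3, REM) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .mcaf_fusion import AttentionMaps
from .records import STAGES, STAGE_TO_INDEX

__all__ = ["StageMetrics", "build_confusion", "metrics_from_confusion",
           "render_hypnogram", "aggregate_attention"]


@dataclass
class StageMetrics:
    """Confusion matrix (rows = truth, columns = predicted) plus the
    derived per-class and overall statistics, all as fractions."""

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    kappa: float
    macro_f1: float
    sensitivity: float
    specificity: float
    degenerate_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": {
                s: {"precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i])}
                for i, s in enumerate(STAGES)
            },
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "macro_f1": self.macro_f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "degenerate_classes": self.degenerate_classes,
        }


def _to_indices(seq: Sequence) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int64)
    for i, s in enumerate(seq):
        if isinstance(s, str):
            if s not in STAGE_TO_INDEX:
                raise ValueError(f"unknown stage label {s!r}")
            out[i] = STAGE_TO_INDEX[s]
        else:
            v = int(s)
            if not 0 <= v < len(STAGES):
                raise ValueError(f"stage index {v} out of range")
            out[i] = v
    return out


def build_confusion(truth: Sequence, pred: Sequence) -> np.ndarray:
    """5x5 count matrix; rows are ground truth, columns predictions.

    Labels may be stage names or indices 0-4.
    """
    if len(truth) != len(pred):
        raise ValueError("truth and pred lengths differ")
    t = _to_indices(truth)
    p = _to_indices(pred)
    n = len(STAGES)
    conf = np.zeros((n, n), dtype=np.int64)
    np.add.at(conf, (t, p), 1)
    return conf


def metrics_from_confusion(confusion: np.ndarray) -> StageMetrics:
    """All reported statistics from a count matrix.

    precision_c = diag_c / colsum_c, recall_c = diag_c / rowsum_c, F1 the
    harmonic mean; accuracy = trace / total; Cohen's kappa =
    (p_o - p_e) / (1 - p_e) with p_e = sum_c rowsum_c * colsum_c / total^2;
    macro-F1 is the unweighted mean of the five F1 values; sensitivity is
    macro recall and specificity the macro-averaged one-vs-rest
    TN / (TN + FP). Empty rows/columns follow the 0/0 -> 0 convention and
    are listed in ``degenerate_classes``.
    """
    conf = np.asarray(confusion)
    if conf.shape != (len(STAGES), len(STAGES)):
        raise ValueError(f"expected 5x5 matrix, got {conf.shape}")
    if (conf < 0).any():
        raise ValueError("negative counts")
    total = conf.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(conf).astype(float)
    rows = conf.sum(axis=1).astype(float)
    cols = conf.sum(axis=0).astype(float)

    def safe_div(a, b):
        return np.divide(a, b, out=np.zeros_like(a, dtype=float),
                         where=b != 0)

    precision = safe_div(diag, cols)
    recall = safe_div(diag, rows)
    f1 = safe_div(2 * precision * recall, precision + recall)
    accuracy = float(diag.sum() / total)
    p_e = float((rows * cols).sum() / total**2)
    kappa = float((accuracy - p_e) / (1.0 - p_e)) if p_e < 1.0 else 1.0
    tn = total - rows - cols + diag
    fp = cols - diag
    specificity = float(np.mean(safe_div(tn, tn + fp)))
    degenerate = [STAGES[i] for i in range(len(STAGES))
                  if rows[i] == 0 or cols[i] == 0]
    return StageMetrics(
        confusion=conf.astype(np.int64),
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        kappa=kappa,
        macro_f1=float(f1.mean()),
        sensitivity=float(recall.mean()),
        specificity=specificity,
        degenerate_classes=degenerate,
    )


def render_hypnogram(truth: Sequence, pred: Sequence, out_png=None,
                     out_csv=None, epoch_seconds: float = 30.0):
    """Two-panel step plot of scored vs predicted stages over the night.

    The y-axis uses the conventional top-to-bottom depth ordering
    (W, REM, N1, N2, N3). Returns the matplotlib figure; optionally
    writes a PNG and a tidy CSV of (time_s, truth, pred).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if len(truth) != len(pred):
        raise ValueError("truth and pred lengths differ")
    t = _to_indices(truth)
    p = _to_indices(pred)
    # plot position per stage index, deeper stages lower
    display_order = [STAGE_TO_INDEX[s] for s in ("W", "REM", "N1", "N2", "N3")]
    position = np.empty(len(STAGES))
    for depth, idx in enumerate(display_order):
        position[idx] = -depth
    times = np.arange(len(t)) * epoch_seconds
    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(10, 4))
    for ax, seq, title in ((axes[0], t, "Scored"), (axes[1], p, "Predicted")):
        ax.step(times, position[seq], where="post", lw=0.8)
        ax.set_yticks([-d for d in range(len(STAGES))])
        ax.set_yticklabels(["W", "REM", "N1", "N2", "N3"])
        ax.set_ylabel(title)
    axes[1].set_xlabel("time (s)")
    fig.tight_layout()
    if out_png is not None:
        fig.savefig(out_png, dpi=120)
    if out_csv is not None:
        import csv

        with open(out_csv, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["time_s", "truth", "pred"])
            for time, ti, pi in zip(times, t, p):
                w.writerow([float(time), STAGES[ti], STAGES[pi]])
    return fig


def aggregate_attention(maps: Iterable[AttentionMaps],
                        predicted_stages: Sequence) -> dict[str, np.ndarray]:
    """Stage-conditioned channel-to-channel attention summaries.

    For each stage, attention weights of the epochs predicted as that
    stage are averaged over heads, both temporal axes, and epochs,
    yielding one C x C matrix (query channel x key channel). Stages with
    no epochs yield all-NaN matrices.
    """
    maps = list(maps)
    stages = _to_indices(predicted_stages)
    per_epoch: list[np.ndarray] = []
    for m in maps:
        w = np.asarray(m.weights)
        if w.ndim != 6:
            raise ValueError("expected [B, H, C, C, L, L] attention weights")
        per_epoch.extend(w.mean(axis=(1, 4, 5)))  # [C, C] per sample
    per_epoch_arr = np.asarray(per_epoch)
    if len(per_epoch_arr) != len(stages):
        raise ValueError(
            f"{len(per_epoch_arr)} attention maps vs {len(stages)} predictions")
    out: dict[str, np.ndarray] = {}
    c = per_epoch_arr.shape[1] if len(per_epoch_arr) else 0
    for i, s in enumerate(STAGES):
        sel = per_epoch_arr[stages == i]
        out[s] = sel.mean(axis=0) if len(sel) else np.full((c, c), np.nan)
    return out
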