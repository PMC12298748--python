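"""Confusion matrices, agreement statistics, hypnogram, attention summaries."""

import csv

import numpy as np
import pytest

from mcafnet import benchmarks
from mcafnet.eval_metrics import (aggregate_attention, build_confusion,
                                  metrics_from_confusion, render_hypnogram)
from mcafnet.mcaf_fusion import AttentionMaps
from mcafnet.records import STAGES


def one_vs_rest_reference(conf):
    """Independent scalar recomputation of every statistic."""
    conf = np.asarray(conf, dtype=float)
    n = conf.shape[0]
    total = conf.sum()
    prec, rec, f1, spec = [], [], [], []
    for c in range(n):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        tn = total - tp - fp - fn
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(2 * p * r / (p + r) if p + r else 0.0)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
    acc = np.trace(conf) / total
    pe = sum(conf[c, :].sum() * conf[:, c].sum() for c in range(n)) / total**2
    kappa = (acc - pe) / (1 - pe) if pe < 1 else 1.0
    return dict(precision=prec, recall=rec, f1=f1, accuracy=acc,
                kappa=kappa, macro_f1=np.mean(f1),
                sensitivity=np.mean(rec), specificity=np.mean(spec))


class TestBuildConfusion:
    def test_perfect_agreement_is_diagonal(self):
        seq = ["W", "N1", "N2", "N3", "REM", "N2"]
        conf = build_confusion(seq, seq)
        assert np.array_equal(conf, np.diag([1, 1, 2, 1, 1]))

    def test_empty_sequences_give_zero_matrix(self):
        assert build_confusion([], []).sum() == 0

    def test_hand_traced_counts(self):
        conf = build_confusion(["W", "W", "N1"], ["W", "N1", "N1"])
        assert conf[0, 0] == 1 and conf[0, 1] == 1 and conf[1, 1] == 1
        assert conf.sum() == 3

    def test_length_mismatch_and_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            build_confusion(["W"], ["W", "N1"])
        with pytest.raises(ValueError):
            build_confusion(["W"], ["SLEEP"])


class TestMetricsFromConfusion:
    def test_agrees_with_scalar_recomputation_on_random_matrices(self, rng):
        for _ in range(1000):
            conf = rng.integers(0, 50, size=(5, 5))
            if conf.sum() == 0:
                continue
            got = metrics_from_confusion(conf)
            ref = one_vs_rest_reference(conf)
            assert np.abs(got.precision - ref["precision"]).max() < 1e-12
            assert np.abs(got.recall - ref["recall"]).max() < 1e-12
            assert np.abs(got.f1 - ref["f1"]).max() < 1e-12
            for k in ("accuracy", "kappa", "macro_f1", "sensitivity",
                      "specificity"):
                assert abs(getattr(got, k) - ref[k]) < 1e-12

    def test_kappa_one_iff_no_off_diagonal(self):
        assert metrics_from_confusion(np.diag([5, 5, 5, 5, 5])).kappa == 1.0
        conf = np.diag([5, 5, 5, 5, 5])
        conf[0, 1] = 1
        assert metrics_from_confusion(conf).kappa < 1.0

    def test_kappa_zero_for_chance_level_agreement(self):
        conf = np.zeros((5, 5), dtype=int)
        conf[:2, :2] = 25
        assert abs(metrics_from_confusion(conf).kappa) < 1e-12

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((5, 5), dtype=int))

    def test_degenerate_class_flagged_with_zero_convention(self):
        conf = np.zeros((5, 5), dtype=int)
        conf[0, 0] = 10
        conf[2, 2] = 5
        got = metrics_from_confusion(conf)
        assert "N1" in got.degenerate_classes
        assert got.f1[1] == 0.0

    @pytest.mark.parametrize("conf,per_class", [
        (benchmarks.SLEEP_EDF20_CONFUSION, benchmarks.SLEEP_EDF20_PER_CLASS),
        (benchmarks.SLEEP_EDF78_CONFUSION, benchmarks.SLEEP_EDF78_PER_CLASS),
    ])
    def test_reproduces_published_per_class_values(self, conf, per_class):
        got = metrics_from_confusion(conf)
        for i, stage in enumerate(STAGES):
            pr, re, f1 = per_class[stage]
            # half-up rounding to the printed one-decimal precision
            assert round(got.precision[i] * 100, 1) == pr
            assert round(got.recall[i] * 100, 1) == re
            assert round(got.f1[i] * 100, 1) == f1


class TestRenderHypnogram:
    def test_constant_wake_and_csv_row_count(self, tmp_path):
        truth = ["W"] * 12
        png = tmp_path / "h.png"
        csv_path = tmp_path / "h.csv"
        fig = render_hypnogram(truth, truth, out_png=png, out_csv=csv_path)
        assert png.exists()
        with open(csv_path) as f:
            rows = list(csv.DictReader(f))
        assert len(rows) == 12
        assert all(r["truth"] == "W" and r["pred"] == "W" for r in rows)
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_alternating_stages_have_60s_period(self, tmp_path):
        seq = ["N2", "N3"] * 5
        csv_path = tmp_path / "h.csv"
        fig = render_hypnogram(seq, seq, out_csv=csv_path)
        with open(csv_path) as f:
            rows = list(csv.DictReader(f))
        times = [float(r["time_s"]) for r in rows if r["truth"] == "N2"]
        assert np.allclose(np.diff(times), 60.0)
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            render_hypnogram(["W"], ["W", "N1"])


class TestAggregateAttention:
    def _maps(self, weights):
        return [AttentionMaps(weights=np.asarray(weights))]

    def test_uniform_weights_aggregate_to_one_over_l(self):
        L = 4
        w = np.full((2, 3, 3, 3, L, L), 1.0 / L)
        agg = aggregate_attention(self._maps(w), ["W", "N1"])
        assert np.allclose(agg["W"], 1.0 / L)
        assert np.isnan(agg["REM"]).all()

    def test_single_epoch_single_head_equals_temporal_mean(self, rng):
        w = rng.uniform(size=(1, 1, 3, 3, 4, 4))
        agg = aggregate_attention(self._maps(w), ["N2"])
        assert np.allclose(agg["N2"], w[0, 0].mean(axis=(2, 3)))

    def test_two_epochs_average_elementwise(self, rng):
        w = rng.uniform(size=(2, 2, 3, 3, 4, 4))
        both = aggregate_attention(self._maps(w), ["N3", "N3"])
        first = aggregate_attention(self._maps(w[:1]), ["N3"])
        second = aggregate_attention(self._maps(w[1:]), ["N3"])
        assert np.allclose(both["N3"], (first["N3"] + second["N3"]) / 2)
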