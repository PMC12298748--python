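"""Published benchmark confusion matrices for this architecture.

These are the reported evaluation counts of the gated cross-channel
attention classifier on the two public Sleep-EDF benchmarks (20-subject
and 78-subject cohorts), under subject-wise cross-validation. Rows are
ground truth, columns predictions, stage order (W, N1, N2, N3, REM).
They serve as fixed inputs for verifying the metric stack: feeding them
through :func:`mcafnet.eval_metrics.metrics_from_confusion` must
reproduce the reported per-class precision/recall/F1 and the overall
accuracy / kappa / macro-F1 figures.
"""

import numpy as np

#: Sleep-EDF-20 benchmark counts. Reported overall: accuracy 88.3%,
#: Cohen's kappa 0.84, macro-F1 81.8%.
SLEEP_EDF20_CONFUSION = np.array([
    [8652,  224,    98,   15,  150],
    [454,  1096,   657,    5,  610],
    [106,   206, 16525,  411,  673],
    [17,      0,   646, 4768,    4],
    [91,    154,   512,    3, 6955],
], dtype=np.int64)

#: Reported per-class (precision, recall, F1) in percent, Sleep-EDF-20.
SLEEP_EDF20_PER_CLASS = {
    "W":   (92.8, 94.7, 93.7),
    "N1":  (65.2, 38.8, 48.7),
    "N2":  (89.6, 92.2, 90.9),
    "N3":  (91.7, 87.7, 89.6),
    "REM": (82.9, 90.1, 86.4),
}

#: Sleep-EDF-78 benchmark counts. Reported overall: accuracy 85.6%,
#: macro-F1 80.1%.
SLEEP_EDF78_CONFUSION = np.array([
    [57878,  2121,   346,    32,   370],
    [2902,   9061,  5713,    36,  1854],
    [412,    2682, 56410,  1265,  2078],
    [44,       11,  2326,  9457,    16],
    [343,    1312,  1805,     5, 20021],
], dtype=np.int64)

#: Reported per-class (precision, recall, F1) in percent, Sleep-EDF-78.
SLEEP_EDF78_PER_CLASS = {
    "W":   (94.0, 95.3, 94.6),
    "N1":  (59.7, 46.3, 52.1),
    "N2":  (84.7, 89.8, 87.2),
    "N3":  (87.6, 79.8, 83.5),
    "REM": (82.3, 85.2, 83.7),
}
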