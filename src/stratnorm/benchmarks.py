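"""Published SEED benchmark results for the multitaper + stratified
normalization pipeline.

These tables are the reported leave-one-participant-out results of this
method on the SEED corpus (62 channels, 15 participants, 3 sessions of
15 film-clip trials). SEED itself is access-restricted, so the tables
ship with the package as reference data: they let the summary arithmetic
(pooled accuracy, per-class recall/precision, cross-task correlation) be
recomputed and regression-tested without the corpus.

Per-participant accuracies are percentages, printed to one decimal.
Confusion-matrix rows are true labels, columns predicted, in display
order positive(/neutral)/negative.
"""

import numpy as np

__all__ = [
    "SEED_LOPO_BINARY_PCT",
    "SEED_LOPO_TERNARY_PCT",
    "SEED_CONFUSION_BINARY",
    "SEED_CONFUSION_TERNARY",
]

#: Per-participant LOPO accuracy (%), binary task (positive vs negative),
#: participants s01..s15.
SEED_LOPO_BINARY_PCT = np.array(
    [76.7, 80.0, 93.3, 86.7, 96.7, 90.0, 93.3, 100.0, 96.7, 96.7,
     100.0, 80.0, 93.3, 90.0, 100.0]
)

#: Per-participant LOPO accuracy (%), ternary task (positive/neutral/negative).
SEED_LOPO_TERNARY_PCT = np.array(
    [77.8, 57.8, 93.3, 82.2, 84.4, 80.0, 80.0, 91.1, 84.4, 71.1,
     75.6, 86.7, 62.2, 71.1, 95.6]
)

#: Pooled LOPO confusion matrix, binary; classes (positive, negative).
SEED_CONFUSION_BINARY = np.array(
    [[208, 17],
     [21, 204]]
)

#: Pooled LOPO confusion matrix, ternary; classes (positive, neutral, negative).
SEED_CONFUSION_TERNARY = np.array(
    [[204, 8, 13],
     [14, 170, 41],
     [23, 39, 163]]
)
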