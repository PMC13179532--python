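"""Recorded contingency counts from the original proof-of-concept study.

The study presented 10 lateralized sounds to each of 28 infants and 30
toddlers, clustered the 2-s post-onset facial features with a 3-component
Gaussian mixture per feature set, and reported the number of predictions per
predicted class (left / centre / right) and speaker side for the toddler
training split, the toddler validation split and the infant validation set.
These published counts are inputs from which the validation statistics
(specificity, exact binomial tests, averages) are recomputed; nothing here
is produced by this package's pipeline.
"""

from __future__ import annotations

import numpy as np

from .decisions import DirectionTable

SPLITS = ("training", "validation_toddler", "validation_infant")

# counts[feature_set][split] = rows (left, centre, right) x cols (left, right speaker)
_COUNTS = {
    "head_rot": {
        "training":           [[48, 4], [65, 72], [9, 28]],
        "validation_toddler": [[4, 1], [23, 27], [0, 1]],
        "validation_infant":  [[13, 11], [102, 100], [21, 31]],
    },
    "gaze_left": {
        "training":           [[39, 4], [78, 84], [5, 16]],
        "validation_toddler": [[4, 0], [23, 29], [0, 0]],
        "validation_infant":  [[7, 2], [127, 131], [2, 9]],
    },
    "gaze_angle": {
        "training":           [[43, 5], [67, 78], [12, 21]],
        "validation_toddler": [[5, 0], [22, 28], [0, 1]],
        "validation_infant":  [[14, 10], [116, 114], [6, 18]],
    },
    "pca2": {
        "training":           [[45, 4], [72, 82], [5, 18]],
        "validation_toddler": [[5, 0], [22, 28], [0, 1]],
        "validation_infant":  [[15, 10], [118, 122], [3, 10]],
    },
}


def reference_table(feature_set: str, split: str) -> DirectionTable:
    """The recorded 3x2 prediction table for one feature set and split."""
    return DirectionTable(counts=np.asarray(_COUNTS[feature_set][split]),
                          split=split, feature_set=feature_set)


def reference_tables(split: str) -> dict[str, DirectionTable]:
    return {fs: reference_table(fs, split) for fs in _COUNTS}
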