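"""End-to-end glue: raw sample -> preprocessing -> feature matrix.

These helpers bind the preprocessing and feature modules into the standard
workflow (motion correction, pulse detection from the photodetector trace,
cropping to the pulse-train window plus reference margin, feature
extraction) for in-memory sample streams; the command-line layer adds file
handling on top.
"""

from __future__ import annotations

import numpy as np

from .features import FeatureConfig, extract_features, feature_names
from .io import MScan, PulseTrace
from .preprocess import (PulseTrain, correct_axial_motion, crop_to_pulse_train,
                         detect_pulses, temporal_subset)

__all__ = ["preprocess_sample", "iter_preprocessed", "feature_matrix"]


def preprocess_sample(mscan: MScan, trace: PulseTrace, pre_margin: int,
                      duration_s: float = 0.3, correct_motion: bool = True,
                      reference_column: int = 0,
                      expected_n_pulses: int | None = None
                      ) -> tuple[MScan, PulseTrain]:
    """Motion-correct, detect pulses, and crop one acquisition."""
    if correct_motion:
        mscan, _ = correct_axial_motion(mscan, reference_column)
    pulses = detect_pulses(trace, mscan.ascan_rate, expected_n_pulses)
    return crop_to_pulse_train(mscan, pulses, duration_s=duration_s,
                               pre_margin=pre_margin)


def iter_preprocessed(samples, pre_margin: int, duration_s: float = 0.3,
                      correct_motion: bool = True):
    """Yield (cropped scan, pulses, label) for a stream of simulated samples."""
    for sample in samples:
        mscan, pulses = preprocess_sample(
            sample.mscan, sample.trace, pre_margin, duration_s, correct_motion)
        yield mscan, pulses, sample.label


def feature_matrix(samples, config: FeatureConfig, pre_margin: int | None = None,
                   duration_s: float = 0.3, correct_motion: bool = True,
                   time_window: str | None = None
                   ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Feature matrix for a stream of simulated samples.

    Returns (X, y, ids, feature_names).  Samples are processed one at a time
    so the stream can be a generator and rasters need not coexist in memory.
    ``time_window`` restricts extraction to one temporal segment of the
    pulse train ("start", "middle", "end" or "start+middle"); the descriptor
    length then scales with the pulses in the segment.
    """
    if pre_margin is None:
        pre_margin = config.block.block_len
    rows, labels, ids = [], [], []
    for sample in samples:
        mscan, pulses = preprocess_sample(
            sample.mscan, sample.trace, pre_margin, duration_s, correct_motion)
        if time_window is not None:
            mscan, pulses = temporal_subset(mscan, pulses, time_window,
                                            pre_margin=pre_margin)
        rows.append(extract_features(mscan, pulses, config).values)
        labels.append(sample.label)
        ids.append(sample.mscan.id)
    X = np.vstack(rows)
    n_blocks = (X.shape[1] - 3) // 2
    return X, np.asarray(labels), ids, feature_names(n_blocks)
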