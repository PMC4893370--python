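"""Dataset-level simulation studies of the classification pipeline.

These helpers reproduce the evaluation protocol on synthetic data:
simulate a labeled cohort mirroring the clinical class balance (119
successful / 34 unsuccessful scans by default), run the preprocessing and
feature extraction on every scan, and hand the feature matrix to repeated
random-split cross-validation, feature-family ablation, or
temporal-segment analysis.  Scans are processed one at a time so a whole
cohort never needs to sit in memory.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .classify import CVResult, cross_validate
from .features import extract_features
from .pipeline import feature_matrix, iter_preprocessed
from .preprocess import SEGMENTS, correct_axial_motion, detect_pulses, temporal_subset
from .presets import Preset, reduced_scale
from .synth import iter_dataset, simulate_mscan

__all__ = ["cohort_features", "cohort_cv", "temporal_cohort_features",
           "motion_recovery", "pulse_detection_accuracy"]


def _cohort(n_pos: int, n_neg: int, preset: Preset, seed: int,
            burst_amplitude: float | None, burst_pulses: int | None):
    sim = preset.simulation
    if burst_amplitude is not None:
        sim = dataclasses.replace(sim, burst_amplitude=burst_amplitude)
    if burst_pulses is not None:
        sim = dataclasses.replace(sim, burst_pulses=burst_pulses)
    if sim.burst_amplitude == 0:
        # a zero-effect cohort: all scans are statistically negative, but the
        # nominal labels keep the requested class balance so that chance-level
        # classification can be measured
        negatives = iter_dataset(0, n_pos + n_neg, sim, seed)
        for i, sample in enumerate(negatives):
            sample.label = 1 if i < n_pos else 0
            yield sample
    else:
        yield from iter_dataset(n_pos, n_neg, sim, seed)


def cohort_features(n_pos: int = 119, n_neg: int = 34,
                    preset: Preset | None = None, seed: int = 0,
                    burst_amplitude: float | None = None,
                    burst_pulses: int | None = None,
                    correct_motion: bool = False):
    """Feature matrix of a simulated cohort: (X, y, ids, feature_names).

    ``burst_amplitude`` overrides the preset's effect size (0 gives a null
    cohort whose labels are independent of the scans); ``burst_pulses``
    restricts bursts to the first pulses of the train.  Motion correction is
    skipped by default since the generator's default jitter is zero.
    """
    if preset is None:
        preset = reduced_scale()
    samples = _cohort(n_pos, n_neg, preset, seed, burst_amplitude, burst_pulses)
    return feature_matrix(samples, preset.feature, pre_margin=preset.pre_margin,
                          correct_motion=correct_motion)


def cohort_cv(X: np.ndarray, y: np.ndarray, preset: Preset | None = None,
              seed: int = 0) -> CVResult:
    """Repeated-split cross-validation with the preset's model settings."""
    if preset is None:
        preset = reduced_scale()
    return cross_validate(X, y, dataclasses.replace(preset.model, seed=seed))


def temporal_cohort_features(n_pos: int = 119, n_neg: int = 34,
                             preset: Preset | None = None, seed: int = 0,
                             burst_pulses: int | None = None,
                             segments: tuple[str, ...] = SEGMENTS
                             ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-segment feature matrices of one simulated cohort.

    Each scan is preprocessed once; features are then recomputed on every
    requested temporal segment (the descriptor length scales with the number
    of pulses in the segment).  Returns ({segment: X}, y).
    """
    if preset is None:
        preset = reduced_scale()
    samples = _cohort(n_pos, n_neg, preset, seed, None, burst_pulses)
    rows: dict[str, list[np.ndarray]] = {s: [] for s in segments}
    labels: list[int] = []
    for mscan, pulses, label in iter_preprocessed(
            samples, pre_margin=preset.pre_margin, correct_motion=False):
        labels.append(label)
        for seg in segments:
            sub, sub_pulses = temporal_subset(mscan, pulses, seg,
                                              pre_margin=preset.pre_margin)
            rows[seg].append(extract_features(sub, sub_pulses, preset.feature).values)
    return {s: np.vstack(r) for s, r in rows.items()}, np.asarray(labels)


def motion_recovery(n_scans: int = 5, jitter_px: int = 8,
                    preset: Preset | None = None, seed: int = 0) -> float:
    """Fraction of columns whose injected axial jitter is exactly inverted."""
    if preset is None:
        preset = reduced_scale()
    exact = total = 0
    seeds = np.random.SeedSequence(seed).generate_state(n_scans)
    for s in seeds:
        cfg = dataclasses.replace(preset.simulation, motion_jitter_px=jitter_px,
                                  seed=int(s % (2**31)))
        sample = simulate_mscan(cfg)
        _, shifts = correct_axial_motion(sample.mscan)
        exact += int(np.sum(shifts == -sample.jitter))
        total += shifts.size
    return exact / total


def pulse_detection_accuracy(preset: Preset | None = None, seed: int = 0) -> dict:
    """Detect the pulse train of one simulated scan against ground truth.

    Returns the detected count, the median spacing in ms, and the maximum
    onset error in trace samples.
    """
    if preset is None:
        preset = reduced_scale()
    cfg = dataclasses.replace(preset.simulation, seed=seed)
    sample = simulate_mscan(cfg)
    pt = detect_pulses(sample.trace, cfg.ascan_rate, cfg.n_pulses)
    truth = cfg.pulse_onset_times() * cfg.trace_sample_rate
    detected = pt.onsets_seconds * cfg.trace_sample_rate
    n = min(truth.size, detected.size)
    return {
        "n_detected": pt.n_pulses,
        "median_spacing_ms": float(np.median(np.diff(pt.onsets_seconds)) * 1e3),
        "max_onset_error_samples": float(np.abs(detected[:n] - truth[:n]).max()),
    }
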