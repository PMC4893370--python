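"""Evaluation protocol: accuracy against a reference labeling, feature-family
ablation, and temporal-segment analysis.

Accuracy is the fraction of scans on which a prediction agrees with a
reference label set (clinically: FFA leakage as assessed by the attending
ophthalmologist), reported as a percentage rounded half-away-from-zero to
one decimal — the convention under which 15/16 prints as 93.8 and 13/16 as
81.3.  The bundled ``table1_invivo.csv`` fixture carries the published
16-application clinical reference used as a regression anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .classify import CVResult, ModelConfig, cross_validate
from .features import FAMILIES, FeatureConfig, extract_features, segments_from_names
from .preprocess import temporal_subset

__all__ = ["EvaluationReport", "accuracy_vs_reference", "round_percentage",
           "load_invivo_reference", "ablation", "temporal_analysis"]


@dataclass
class EvaluationReport:
    """Agreement of one prediction column with a reference label set."""

    n: int
    agreements: int
    accuracy: float
    accuracy_pct: float
    true_pos: int
    true_neg: int
    false_pos: int
    false_neg: int

    def as_dict(self) -> dict:
        return dict(n=self.n, agreements=self.agreements, accuracy=self.accuracy,
                    accuracy_pct=self.accuracy_pct, true_pos=self.true_pos,
                    true_neg=self.true_neg, false_pos=self.false_pos,
                    false_neg=self.false_neg)


def round_percentage(fraction: float, decimals: int = 1) -> float:
    """Percentage rounded half away from zero (so 0.9375 -> 93.8)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def accuracy_vs_reference(pred, ref) -> EvaluationReport:
    """Fraction of positions where a binary prediction matches the reference.

    Equals 1 minus the normalized Hamming distance.  Confusion counts treat
    the reference as truth.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError(f"prediction and reference must be 1-D and equal "
                         f"length, got {pred.shape} vs {ref.shape}")
    for name, v in (("prediction", pred), ("reference", ref)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} vector must be binary")
    agree = int(np.count_nonzero(pred == ref))
    acc = agree / pred.size
    return EvaluationReport(
        n=int(pred.size), agreements=agree, accuracy=acc,
        accuracy_pct=round_percentage(acc),
        true_pos=int(np.count_nonzero((pred == 1) & (ref == 1))),
        true_neg=int(np.count_nonzero((pred == 0) & (ref == 0))),
        false_pos=int(np.count_nonzero((pred == 1) & (ref == 0))),
        false_neg=int(np.count_nonzero((pred == 0) & (ref == 1))),
    )


def load_invivo_reference() -> pd.DataFrame:
    """The bundled 16-application clinical evaluation table.

    Columns: ``energy_uJ`` (pulse energy), ``ffa`` (FFA leakage ground
    truth), ``oct`` (manual M-Scan label) and the classifier calls at the
    three clinical operating points (``c100spec``, ``c95spec``, ``c100sens``).
    """
    with resources.files("srtoct.data").joinpath("table1_invivo.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def ablation(features: np.ndarray, labels: np.ndarray, feature_names: list[str],
             subsets: list[tuple[str, ...]] | None = None,
             config: ModelConfig | None = None) -> dict[tuple[str, ...], CVResult]:
    """Cross-validated AUC using only selected feature families.

    ``subsets`` lists family combinations (subsets of {"bm", "bs", "sv",
    "sp"}); for each, the forest is retrained on just those columns with all
    other settings unchanged.  Defaults to each single family plus all
    families combined.
    """
    segs = segments_from_names(list(feature_names))
    if subsets is None:
        subsets = [(f,) for f in FAMILIES if f in segs] + [tuple(segs)]
    results: dict[tuple[str, ...], CVResult] = {}
    for subset in subsets:
        if not subset:
            raise ValueError("empty feature subset")
        unknown = [f for f in subset if f not in segs]
        if unknown:
            raise ValueError(f"unknown feature families {unknown}; "
                             f"available: {sorted(segs)}")
        cols = np.concatenate([segs[f] for f in subset])
        results[tuple(subset)] = cross_validate(features[:, cols], labels, config)
    return results


def temporal_analysis(samples, feature_config: FeatureConfig | None = None,
                      model_config: ModelConfig | None = None,
                      segments: tuple[str, ...] = ("start", "middle", "end", "start+middle"),
                      pre_margin: int | None = None
                      ) -> dict[str, CVResult]:
    """Cross-validated AUC when only part of the pulse train is observed.

    ``samples`` is a sequence of (cropped scan, pulse train, label) triples.
    For each temporal segment, features are recomputed identically on the
    reduced signal (the block count N, hence the feature length 2N+3, scales
    with the number of pulses in the segment) and cross-validated.
    """
    if feature_config is None:
        feature_config = FeatureConfig()
    if pre_margin is None:
        pre_margin = feature_config.block.block_len
    per_segment: dict[str, list[np.ndarray]] = {s: [] for s in segments}
    labels: list[int] = []
    for mscan, pulses, label in samples:
        labels.append(int(label))
        for seg in segments:
            sub, sub_pulses = temporal_subset(mscan, pulses, seg, pre_margin=pre_margin)
            per_segment[seg].append(
                extract_features(sub, sub_pulses, feature_config).values)
    y = np.asarray(labels)
    return {seg: cross_validate(np.vstack(rows), y, model_config)
            for seg, rows in per_segment.items()}
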