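"""Random-forest outcome classification with clinical operating points.

A 200-tree random forest maps the 2N+3 M-Scan descriptor to a treatment
success score in [0, 1].  Clinical use asks for hard decisions at specific
operating points of the ROC curve — maximal sensitivity at 100% or 95%
specificity (avoid calling unsuccessful treatments successful) or 100%
sensitivity (never miss a successful one).  Generalization is estimated by
repeated stratified random subsampling: 50 independent 2/3 train / 1/3 test
splits, AUC on each held-out third.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = ["ModelConfig", "TrainedModel", "ROCCurve", "OperatingPoint",
           "CVResult", "train", "predict_scores", "classify_at", "roc_curve",
           "select_operating_point", "cross_validate"]

logger = logging.getLogger(__name__)

CRITERIA = ("specificity_100", "specificity_95", "sensitivity_100")


@dataclass
class ModelConfig:
    """Random-forest and cross-validation settings.

    ``train_fraction`` defaults to 102/153, matching a 102-sample training /
    51-sample test split of a 153-scan dataset; ``cv_iterations`` repeated
    stratified random splits estimate held-out performance.
    """

    n_trees: int = 200
    max_depth: int | None = None
    class_weight: str | dict | None = None
    train_fraction: float = 102 / 153
    cv_iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_iterations < 1:
            raise ValueError("cv_iterations must be >= 1")


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed downstream.

    ``feature_names`` allows family-wise ablation and input validation;
    ``operating_points`` holds thresholds selected on the training scores.
    """

    forest: RandomForestClassifier
    feature_names: list[str]
    config: ModelConfig
    operating_points: dict[str, "OperatingPoint"] = field(default_factory=dict)


@dataclass
class ROCCurve:
    """A full ROC sweep with trapezoidal AUC.

    ``thresholds``, ``fpr`` and ``tpr`` trace the curve from (0, 0) to
    (1, 1); the raw scores and labels are retained so that operating points
    can be selected with the same strict-inequality decision rule used at
    prediction time.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scores: np.ndarray
    labels: np.ndarray


@dataclass
class OperatingPoint:
    """A score threshold with the sensitivity/specificity it achieves.

    A sample is called positive iff its score is strictly greater than
    ``threshold``.
    """

    criterion: str
    threshold: float
    achieved_sens: float
    achieved_spec: float


@dataclass
class CVResult:
    """Per-iteration held-out AUCs of repeated random-split cross-validation."""

    aucs: np.ndarray
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1))

    @property
    def pooled_auc(self) -> float:
        """AUC of all held-out scores pooled over iterations."""
        return roc_curve(self.pooled_scores, self.pooled_labels).auc


# ---------------------------------------------------------------------------


def train(features: np.ndarray, labels: np.ndarray,
          config: ModelConfig | None = None,
          feature_names: list[str] | None = None) -> TrainedModel:
    """Fit the random forest.  Deterministic given ``config.seed``."""
    if config is None:
        config = ModelConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training set contains a single class ({classes.tolist()}); "
                         "need both outcomes")
    if feature_names is None:
        feature_names = [f"f{i:03d}" for i in range(X.shape[1])]
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length must match feature count")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, max_depth=config.max_depth,
        class_weight=config.class_weight, random_state=config.seed)
    forest.fit(X, y)
    model = TrainedModel(forest=forest, feature_names=list(feature_names),
                         config=config)
    roc = roc_curve(predict_scores(model, X), y)
    for criterion in CRITERIA:
        try:
            model.operating_points[criterion] = select_operating_point(roc, criterion)
        except ValueError as exc:  # pragma: no cover - degenerate training sets
            logger.warning("operating point %s not selectable on training data: %s",
                           criterion, exc)
    return model


def predict_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Treatment-success scores in [0, 1] (fraction of trees voting 1)."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.feature_names):
        raise ValueError(f"feature length {X.shape[1]} does not match the "
                         f"model's {len(model.feature_names)}")
    pos = list(model.forest.classes_).index(1)
    return model.forest.predict_proba(X)[:, pos]


def classify_at(model: TrainedModel, features: np.ndarray,
                op: OperatingPoint) -> np.ndarray:
    """Hard labels at an operating point: 1 iff score > op.threshold."""
    return (predict_scores(model, features) > op.threshold).astype(np.int64)


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve and trapezoidal AUC of scores against binary labels.

    The trapezoidal area equals the Mann-Whitney pair statistic (ties counted
    as half).  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
                    scores=scores, labels=labels.astype(np.int64))


def _sens_spec(scores: np.ndarray, labels: np.ndarray, threshold: float
               ) -> tuple[float, float]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    return float(np.mean(pos > threshold)), float(np.mean(neg <= threshold))


def select_operating_point(roc: ROCCurve, criterion: str) -> OperatingPoint:
    """Choose a score threshold meeting a clinical constraint.

    Candidate thresholds are the midpoints between consecutive distinct
    scores (plus one below the minimum), evaluated with the strict
    score-greater-than-threshold decision rule.  For ``specificity_100`` /
    ``specificity_95`` the smallest threshold with specificity >= the bound
    is returned (maximizing sensitivity subject to the constraint); for
    ``sensitivity_100`` the largest threshold that still classifies every
    positive sample correctly.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    uniq = np.unique(roc.scores)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    stats = [(t, *_sens_spec(roc.scores, roc.labels, t)) for t in candidates]
    if criterion.startswith("specificity"):
        bound = {"specificity_100": 1.0, "specificity_95": 0.95}[criterion]
        feasible = [(t, sens, spec) for t, sens, spec in stats if spec >= bound]
        if not feasible:
            raise ValueError(f"no threshold achieves specificity >= {bound}")
        t, sens, spec = min(feasible, key=lambda x: x[0])
    else:
        feasible = [(t, sens, spec) for t, sens, spec in stats if sens == 1.0]
        if not feasible:
            raise ValueError("no threshold achieves sensitivity = 1")
        t, sens, spec = max(feasible, key=lambda x: x[0])
    return OperatingPoint(criterion=criterion, threshold=float(t),
                          achieved_sens=sens, achieved_spec=spec)


def cross_validate(features: np.ndarray, labels: np.ndarray,
                   config: ModelConfig | None = None) -> CVResult:
    """Repeated stratified random-split cross-validation.

    ``config.cv_iterations`` independent splits at ``config.train_fraction``
    (stratified by label to protect the minority class); a forest is trained
    per split and scored by trapezoidal AUC on its held-out samples.  Split
    sequence and forests are deterministic given ``config.seed``.
    """
    if config is None:
        config = ModelConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples to cross-validate")
    splitter = StratifiedShuffleSplit(
        n_splits=config.cv_iterations, train_size=config.train_fraction,
        random_state=config.seed % (2**31))
    seeds = np.random.SeedSequence(config.seed).generate_state(config.cv_iterations)
    aucs, pooled_s, pooled_y = [], [], []
    for i, (tr, te) in enumerate(splitter.split(X, y)):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            # stratification should prevent this; guard anyway
            logger.warning("split %d lost a class; skipping", i)
            continue
        cfg = ModelConfig(n_trees=config.n_trees, max_depth=config.max_depth,
                          class_weight=config.class_weight,
                          train_fraction=config.train_fraction,
                          cv_iterations=config.cv_iterations,
                          seed=int(seeds[i] % (2**31)))
        model = train(X[tr], y[tr], cfg)
        s = predict_scores(model, X[te])
        aucs.append(roc_curve(s, y[te]).auc)
        pooled_s.append(s)
        pooled_y.append(y[te])
    return CVResult(aucs=np.asarray(aucs),
                    pooled_scores=np.concatenate(pooled_s),
                    pooled_labels=np.concatenate(pooled_y))
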