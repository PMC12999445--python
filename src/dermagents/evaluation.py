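"""Evaluation protocol: confusion metrics, ROC/AUC, stratified CV,
one-way ANOVA with Tukey HSD, and decision-curve analysis.

The malignant class is the positive class throughout. Decision-curve net
benefit follows

    NB(thr) = sens * prev - (1 - spec) * (1 - prev) * thr / (1 - thr)

evaluated over screening thresholds 0.01-0.30 at an assumed prevalence of
20%, against treat-none (identically 0) and treat-all references.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ContractError, DomainError


# ---------------------------------------------------------------------------
# confusion matrix and scalar metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with malignant as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive: int = 1) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float


def _safe_ratio(num: float, den: float) -> float:
    """NaN marks an undefined metric (zero denominator) rather than raising."""
    return num / den if den > 0 else float("nan")


def confusion_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    if cm.total == 0:
        raise DomainError("empty confusion matrix")
    precision = _safe_ratio(cm.tp, cm.tp + cm.fp)
    recall = _safe_ratio(cm.tp, cm.tp + cm.fn)
    f1 = (
        2 * precision * recall / (precision + recall)
        if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0
        else float("nan")
    )
    return ClassificationMetrics(
        accuracy=(cm.tp + cm.tn) / cm.total,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=_safe_ratio(cm.tn, cm.tn + cm.fp),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC points (fpr, tpr) and trapezoidal AUC.

    With rank-average tie handling the AUC equals the concordance
    probability (1/2 credit for tied scores).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DomainError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# decision-curve analysis
# ---------------------------------------------------------------------------

def net_benefit(sens: float, spec: float, prevalence: float, threshold: float) -> float:
    """Clinical net benefit of acting on the model at one threshold."""
    if not 0 < threshold < 1:
        raise DomainError("threshold must lie strictly inside (0, 1)")
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise DomainError(f"{name} must lie in [0, 1]")
    return sens * prevalence - (1 - spec) * (1 - prevalence) * threshold / (1 - threshold)


@dataclass(frozen=True)
class DCACurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "net_benefit": self.net_benefit,
                "treat_all": self.treat_all,
                "treat_none": self.treat_none,
            }
        )


def dca_curve(
    sens: float,
    spec: float,
    prevalence: float = 0.20,
    thresholds: np.ndarray | None = None,
) -> DCACurve:
    """Net-benefit curve over the screening threshold grid (default 0.01-0.30)."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.301, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    nb = np.array([net_benefit(sens, spec, prevalence, t) for t in thresholds])
    ta = np.array([net_benefit(1.0, 0.0, prevalence, t) for t in thresholds])
    return DCACurve(
        thresholds=thresholds,
        net_benefit=nb,
        treat_all=ta,
        treat_none=np.zeros_like(thresholds),
        prevalence=prevalence,
    )


# ---------------------------------------------------------------------------
# cross-validation and statistics
# ---------------------------------------------------------------------------

def stratified_kfold(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint test folds preserving class proportions within 1 sample."""
    labels = np.asarray(labels)
    if k < 2:
        raise DomainError("k must be at least 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise DomainError("every class needs at least k members for k folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(len(labels)), labels)]


def one_way_anova(groups) -> tuple[float, float]:
    """Classic between/within mean-square F ratio with its p-value.

    Degenerate inputs (zero within-group variance everywhere) yield
    (nan, nan) rather than an exception.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DomainError("ANOVA needs >=2 groups with >=2 values each")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*groups)
    if not np.isfinite(f_stat):
        return float("nan"), float("nan")
    return float(f_stat), float(p)


def tukey_hsd(groups, alpha: float = 0.05) -> pd.DataFrame:
    """Studentized-range pairwise comparisons after ANOVA.

    Returns one row per unordered pair with the adjusted p-value and a
    significance flag at ``alpha``.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DomainError("Tukey HSD needs >=2 groups with >=2 values each")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group_a": i,
                    "group_b": j,
                    "p_adjusted": p,
                    "significant": bool(np.isfinite(p) and p < alpha),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end model evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    metrics: ClassificationMetrics
    roc_points: np.ndarray | None
    auc: float
    dca: DCACurve
    predictions: np.ndarray = field(repr=False, default=None)
    scores: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
            },
            "accuracy": self.metrics.accuracy,
            "precision": self.metrics.precision,
            "recall": self.metrics.recall,
            "f1": self.metrics.f1,
            "specificity": self.metrics.specificity,
            "auc": self.auc,
            "dca": {
                "prevalence": self.dca.prevalence,
                "thresholds": self.dca.thresholds.tolist(),
                "net_benefit": self.dca.net_benefit.tolist(),
                "treat_all": self.dca.treat_all.tolist(),
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_model(
    spatial,
    temporal,
    rule,
    samples,
    positive_class: int = 1,
    prevalence: float = 0.20,
    tau: float = 1.0,
    grid=None,
    t_max: int = 16,
    pos_frequencies: int = 2,
) -> EvaluationReport:
    """Greedy-rollout evaluation of a trained team on a labelled sample set.

    The positive-class softmax probability at the terminal step is the score
    used for ROC and DCA.
    """
    from .training import predict  # local import to avoid a cycle

    if not samples:
        raise ContractError("empty test set")
    y_true = np.array([s.label for s in samples])
    preds = np.empty(len(samples), dtype=int)
    scores = np.empty(len(samples), dtype=float)
    for i, sample in enumerate(samples):
        p = predict(
            sample, spatial, temporal, rule,
            grid=grid, t_max=t_max, pos_frequencies=pos_frequencies, tau=tau,
        )
        preds[i] = p.predicted_class
        scores[i] = p.probabilities[positive_class]
    cm = ConfusionMatrix.from_predictions(y_true, preds, positive=positive_class)
    metrics = confusion_metrics(cm)
    if len(np.unique(y_true)) > 1:
        roc_points, auc_value = roc_auc(scores, (y_true == positive_class).astype(int))
    else:
        roc_points, auc_value = None, float("nan")
    sens = metrics.recall if np.isfinite(metrics.recall) else 0.0
    spec = metrics.specificity if np.isfinite(metrics.specificity) else 0.0
    dca = dca_curve(sens, spec, prevalence=prevalence)
    return EvaluationReport(
        confusion=cm,
        metrics=metrics,
        roc_points=roc_points,
        auc=auc_value,
        dca=dca,
        predictions=preds,
        scores=scores,
    )
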