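"""Model evaluation: confusion metrics, ROC/AUC and validation protocols.

The amyloidogenic class is the positive class throughout.  Metrics are the
three standard confusion-table ratios

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

reported as percentages to one decimal, and the area under the ROC curve,
which is insensitive to the heavy class imbalance of the application.
Validation protocols mirror the study design: self-consistency,
leave-one-out CV, stratified k-fold CV, and repeated stratified 90/10
subsampling without replacement (per iteration) with mean +/- sd
aggregation.  The fixed decision threshold (default 0.15) is applied to
every split; the model is retrained per split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .part import (
    DEFAULT_THRESHOLD,
    RuleList,
    fit_rules,
    predict_proba_matrix,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(
    probabilities: Sequence[float],
    labels: Sequence[int],
    threshold: float = DEFAULT_THRESHOLD,
) -> ConfusionCounts:
    """Tally calls (P >= threshold is positive) against binary labels."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    calls = p >= threshold
    return ConfusionCounts(
        tp=int((calls & (y == 1)).sum()),
        tn=int((~calls & (y == 0)).sum()),
        fp=int((calls & (y == 0)).sum()),
        fn=int((~calls & (y == 1)).sum()),
    )


def confusion_metrics(
    counts: ConfusionCounts,
) -> tuple[float, Optional[float], Optional[float]]:
    """(accuracy, sensitivity, specificity) as fractions in [0, 1].

    An undefined ratio (empty class) is returned as None rather than 0.
    """
    if counts.n == 0:
        raise ValueError("cannot compute metrics of an empty evaluation")
    accuracy = (counts.tp + counts.tn) / counts.n
    sensitivity = (
        counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    )
    specificity = (
        counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    )
    return accuracy, sensitivity, specificity


def roc_auc(
    probabilities: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points from a full threshold sweep plus the trapezoidal AUC.

    The AUC equals the probability that a random positive outscores a random
    negative, counting ties as one half.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one instance of each class")
    order = np.argsort(-p, kind="mergesort")
    ps, ys = p[order], y[order]
    # group tied scores so the curve steps once per distinct threshold
    distinct = np.nonzero(np.diff(ps))[0]
    bounds = np.r_[distinct, len(ps) - 1]
    tp_cum = np.cumsum(ys)[bounds]
    fp_cum = bounds + 1 - tp_cum
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _pct(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(100.0 * x, 1)


@dataclass
class EvalReport:
    """Metrics for one protocol; percentages to one decimal, AUC in [0, 1]."""

    protocol: str
    counts: ConfusionCounts
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    auc: Optional[float]
    threshold: float
    seed: Optional[int] = None
    roc_points: list = field(default_factory=list, repr=False)
    per_iteration: Optional[pd.DataFrame] = field(default=None, repr=False)
    summary_sd: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "protocol": self.protocol,
            "threshold": self.threshold,
            "seed": self.seed,
            "counts": asdict(self.counts),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": None if self.auc is None else round(self.auc, 4),
        }
        if self.summary_sd is not None:
            out["sd"] = self.summary_sd
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def write_roc(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in self.roc_points:
                fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")


def _report(
    protocol: str,
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    seed: Optional[int] = None,
) -> EvalReport:
    counts = confusion_counts(probabilities, labels, threshold)
    accuracy, sensitivity, specificity = confusion_metrics(counts)
    roc_points, auc = roc_auc(probabilities, labels)
    return EvalReport(
        protocol=protocol,
        counts=counts,
        accuracy=_pct(accuracy),
        sensitivity=_pct(sensitivity),
        specificity=_pct(specificity),
        auc=auc,
        threshold=threshold,
        seed=seed,
        roc_points=roc_points,
    )


# ---------------------------------------------------------------------------
# Splitters (stratified, seeded, hand-rolled so splits are reproducible
# across library versions)
# ---------------------------------------------------------------------------

def _stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Indices of k folds with per-class proportional allocation."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        if len(idx) < k and len(idx) > 0:
            raise ValueError(
                f"class {cls} has {len(idx)} instances, fewer than k={k} folds"
            )
        idx = rng.permutation(idx)
        for i, chunk in enumerate(np.array_split(idx, k)):
            folds[i].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _stratified_subsample(
    y: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Training indices: ``frac`` of each class, sampled without replacement."""
    train: list[int] = []
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        n_take = int(round(frac * len(idx)))
        n_take = min(max(n_take, 1), len(idx) - 1)
        train.extend(rng.choice(idx, size=n_take, replace=False).tolist())
    return np.sort(np.array(train, dtype=int))


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def cross_validate(
    matrix: FeatureMatrix,
    protocol: str = "loocv",
    k: int = 10,
    n_iter: int = 5000,
    frac_train: float = 0.9,
    threshold: float = DEFAULT_THRESHOLD,
    min_leaf: int = 2,
    seed: int = 0,
) -> EvalReport:
    """Evaluate the rule learner under a validation protocol.

    ``self_consistency``
        train on everything, score the training data;
    ``loocv``
        each record scored by a model trained on the other n-1;
    ``kfold``
        stratified k folds, each scored by a model trained on the rest;
    ``resampling``
        ``n_iter`` stratified ``frac_train`` subsamples without replacement;
        metrics averaged over iterations (mean +/- sd), AUC likewise.

    The model is retrained per split; the decision threshold is fixed.
    """
    X, y = matrix.X, matrix.y
    names = matrix.feature_names
    n = len(y)
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("cross-validation needs both classes")
    rng = np.random.default_rng(seed)

    if protocol == "self_consistency":
        model = fit_rules(X, y, names, min_leaf=min_leaf, seed=seed)
        probs = predict_proba_matrix(model, X, names)
        return _report(protocol, probs, y, threshold, seed)

    if protocol == "loocv":
        probs = np.empty(n)
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            assert not keep[i], "held-out record leaked into its training split"
            model = fit_rules(X[keep], y[keep], names, min_leaf=min_leaf, seed=seed)
            probs[i] = predict_proba_matrix(model, X[i : i + 1], names)[0]
        return _report(protocol, probs, y, threshold, seed)

    if protocol == "kfold":
        probs = np.empty(n)
        for fold in _stratified_folds(y, k, rng):
            keep = np.ones(n, dtype=bool)
            keep[fold] = False
            if y[keep].sum() in (0, keep.sum()):
                raise ValueError("a training split lost one class; reduce k")
            model = fit_rules(X[keep], y[keep], names, min_leaf=min_leaf, seed=seed)
            probs[fold] = predict_proba_matrix(model, X[fold], names)
        return _report(protocol, probs, y, threshold, seed)

    if protocol == "resampling":
        rows = []
        pooled_counts = np.zeros(4, dtype=int)
        for _ in range(n_iter):
            train_idx = _stratified_subsample(y, frac_train, rng)
            test_mask = np.ones(n, dtype=bool)
            test_mask[train_idx] = False
            model = fit_rules(
                X[train_idx], y[train_idx], names, min_leaf=min_leaf, seed=seed
            )
            p_test = predict_proba_matrix(model, X[test_mask], names)
            y_test = y[test_mask]
            counts = confusion_counts(p_test, y_test, threshold)
            accuracy, sensitivity, specificity = confusion_metrics(counts)
            try:
                _, auc = roc_auc(p_test, y_test)
            except ValueError:
                auc = math.nan
            rows.append(
                {
                    "accuracy": accuracy,
                    "sensitivity": sensitivity,
                    "specificity": specificity,
                    "auc": auc,
                }
            )
            pooled_counts += np.array([counts.tp, counts.tn, counts.fp, counts.fn])
        per_iter = pd.DataFrame(rows)
        mean = per_iter.mean(skipna=True)
        sd = per_iter.std(skipna=True, ddof=1)
        counts = ConfusionCounts(*(int(v) for v in pooled_counts))
        report = EvalReport(
            protocol=protocol,
            counts=counts,
            accuracy=_pct(mean["accuracy"]),
            sensitivity=_pct(mean["sensitivity"]),
            specificity=_pct(mean["specificity"]),
            auc=float(mean["auc"]),
            threshold=threshold,
            seed=seed,
            per_iteration=per_iter,
            summary_sd={
                "accuracy": _pct(sd["accuracy"]),
                "sensitivity": _pct(sd["sensitivity"]),
                "specificity": _pct(sd["specificity"]),
                "auc": round(float(sd["auc"]), 4),
            },
        )
        return report

    raise ValueError(f"unknown protocol {protocol!r}")


def holdout_test(
    train_matrix: FeatureMatrix,
    test_matrix: FeatureMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    min_leaf: int = 2,
    seed: int = 0,
) -> EvalReport:
    """Train on one labeled matrix, report metrics on a held-out one."""
    model = fit_rules(
        train_matrix.X, train_matrix.y, train_matrix.feature_names,
        min_leaf=min_leaf, seed=seed,
    )
    probs = predict_proba_matrix(model, test_matrix.X, train_matrix.feature_names)
    return _report("test", probs, test_matrix.y, threshold, seed)


def feature_ablation(
    matrix: FeatureMatrix,
    protocol: str = "kfold",
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    **protocol_kwargs,
) -> pd.DataFrame:
    """Per-feature importance: AUC with the feature removed, and alone.

    Retrains under the same protocol and seed for every variant; rows are
    indexed by feature name with columns ``auc_without`` and ``auc_only``.
    """
    names = matrix.feature_names
    if len(names) < 2:
        raise ValueError("ablation needs at least two features")
    rows = {}
    for name in names:
        without = FeatureMatrix(matrix.features.drop(columns=[name]), matrix.labels)
        only = FeatureMatrix(matrix.features[[name]], matrix.labels)
        rows[name] = {
            "auc_without": cross_validate(
                without, protocol=protocol, threshold=threshold, seed=seed,
                **protocol_kwargs,
            ).auc,
            "auc_only": cross_validate(
                only, protocol=protocol, threshold=threshold, seed=seed,
                **protocol_kwargs,
            ).auc,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
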