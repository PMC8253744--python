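"""Separate-and-conquer rule induction over partial C4.5-style trees.

The learner repeats: grow a partial decision tree on the instances not yet
covered, turn the first terminal leaf into an ordered rule, discard the
instances it covers, and start over — until nothing remains (the classic
PART scheme).  Trees use binary numeric splits at midpoints between
consecutive distinct sorted values; the split is chosen by information gain
ratio among the candidates passing the C4.5 average-gain admissibility
screen.  Nodes are expanded best-first by class entropy and expansion stops
at purity, at fewer than ``min_leaf`` instances, or when no admissible
split exists.  No pruning is applied (the model is trained unpruned).

Class probabilities are Laplace-smoothed leaf frequencies,
``P(positive) = (n_pos + 1) / (n_covered + 2)``, and the final call applies
a fixed decision threshold (default 0.15, chosen low to counter the heavy
negative-class imbalance of the application: a sequence is called
amyloidogenic whenever P >= t).

Everything here is deterministic given the training data and recorded
parameters; models serialize to human-readable JSON and round-trip exactly.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features import FeatureMatrix

POSITIVE = "amyloid"
NEGATIVE = "non_amyloid"
DEFAULT_THRESHOLD = 0.15

_EPS = 1e-12


@dataclass(frozen=True)
class Rule:
    """Conjunction of numeric conditions with leaf class counts."""

    conditions: tuple[tuple[str, str, float], ...]  # (feature, "<=" or ">", thr)
    n_pos: int
    n_neg: int

    @property
    def n_covered(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def probability(self) -> float:
        """Laplace-smoothed positive fraction."""
        return (self.n_pos + 1) / (self.n_covered + 2)

    def matches(self, row: Mapping[str, float]) -> bool:
        for feature, op, thr in self.conditions:
            value = row[feature]
            if op == "<=":
                if not value <= thr:
                    return False
            elif not value > thr:
                return False
        return True

    def __str__(self) -> str:
        if not self.conditions:
            cond = "TRUE"
        else:
            cond = " AND ".join(f"{f} {op} {t:g}" for f, op, t in self.conditions)
        return f"IF {cond} THEN ({self.n_pos} pos / {self.n_neg} neg)"


@dataclass(frozen=True)
class RuleList:
    """An ordered rule model: first matching rule wins, else the default."""

    rules: tuple[Rule, ...]
    default_counts: tuple[int, int]  # (n_pos, n_neg) for instances matching no rule
    feature_names: tuple[str, ...]
    training_meta: dict = field(default_factory=dict)

    @property
    def default_probability(self) -> float:
        n_pos, n_neg = self.default_counts
        return (n_pos + 1) / (n_pos + n_neg + 2)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "model": "part_rule_list",
            "feature_names": list(self.feature_names),
            "rules": [
                {
                    "conditions": [
                        {"feature": f, "op": op, "threshold": thr}
                        for f, op, thr in rule.conditions
                    ],
                    "n_pos": rule.n_pos,
                    "n_neg": rule.n_neg,
                }
                for rule in self.rules
            ],
            "default_counts": list(self.default_counts),
            "training_meta": self.training_meta,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RuleList":
        payload = json.loads(text)
        rules = tuple(
            Rule(
                conditions=tuple(
                    (c["feature"], c["op"], float(c["threshold"]))
                    for c in r["conditions"]
                ),
                n_pos=int(r["n_pos"]),
                n_neg=int(r["n_neg"]),
            )
            for r in payload["rules"]
        )
        return cls(
            rules=rules,
            default_counts=tuple(int(v) for v in payload["default_counts"]),
            feature_names=tuple(payload["feature_names"]),
            training_meta=payload["training_meta"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RuleList":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------

def _binary_entropy(p: np.ndarray) -> np.ndarray:
    """Entropy (bits) of a Bernoulli(p), vectorized, with 0*log0 = 0."""
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        mask = q > 0
        out[mask] -= q[mask] * np.log2(q[mask])
    return out


def _node_entropy(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    return float(_binary_entropy(np.array([y.mean()]))[0])


def best_split(
    X: np.ndarray, y: np.ndarray
) -> tuple[int, float] | None:
    """Best admissible (feature, threshold) split by C4.5 gain ratio.

    Candidates are midpoints between consecutive distinct sorted values of
    each feature.  Candidates whose information gain falls below the mean
    gain over all candidates are screened out; among the rest the highest
    gain ratio wins, ties broken toward the lower feature index and then the
    lower threshold.  Returns None when no feature has two distinct values.
    """
    n = len(y)
    parent = _node_entropy(y)
    feats: list[np.ndarray] = []
    thrs: list[np.ndarray] = []
    gains: list[np.ndarray] = []
    ratios: list[np.ndarray] = []
    for j in range(X.shape[1]):
        x = X[:, j]
        order = np.argsort(x, kind="mergesort")
        xs, ys = x[order], y[order]
        cut = np.nonzero(xs[1:] > xs[:-1])[0]  # split after index i
        if cut.size == 0:
            continue
        thr = (xs[cut] + xs[cut + 1]) / 2.0
        # guard against midpoints rounding up onto the right value
        bad = thr >= xs[cut + 1]
        thr[bad] = xs[cut][bad]
        left_n = cut + 1
        right_n = n - left_n
        pos_cum = np.cumsum(ys)
        left_pos = pos_cum[cut]
        right_pos = pos_cum[-1] - left_pos
        h_left = _binary_entropy(left_pos / left_n)
        h_right = _binary_entropy(right_pos / right_n)
        gain = parent - (left_n * h_left + right_n * h_right) / n
        split_info = _binary_entropy(left_n / n)
        ratio = np.where(split_info > 0, gain / np.maximum(split_info, _EPS), 0.0)
        feats.append(np.full(cut.size, j))
        thrs.append(thr)
        gains.append(gain)
        ratios.append(ratio)
    if not feats:
        return None
    gain_all = np.concatenate(gains)
    ratio_all = np.concatenate(ratios)
    feat_all = np.concatenate(feats)
    thr_all = np.concatenate(thrs)
    admissible = gain_all >= gain_all.mean() - _EPS
    idx = np.nonzero(admissible)[0]
    # max gain ratio; ties -> lower feature index, then lower threshold.
    # candidates are already ordered by (feature, threshold ascending).
    best = None
    best_ratio = -np.inf
    for i in idx:
        if ratio_all[i] > best_ratio + _EPS:
            best_ratio = ratio_all[i]
            best = i
    if best is None or gain_all[best] <= _EPS:
        return None
    return int(feat_all[best]), float(thr_all[best])


# ---------------------------------------------------------------------------
# Partial tree growth and the separate-and-conquer loop
# ---------------------------------------------------------------------------

def _merge_condition(
    conditions: tuple[tuple[int, str, float], ...], feature: int, op: str, thr: float
) -> tuple[tuple[int, str, float], ...]:
    """Append a condition, tightening any existing bound on the same feature."""
    out = []
    replaced = False
    for f, o, t in conditions:
        if f == feature and o == op:
            if op == "<=":
                t = min(t, thr)
            else:
                t = max(t, thr)
            replaced = True
        out.append((f, o, t))
    if not replaced:
        out.append((feature, op, thr))
    return tuple(out)


def _grow_rule(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[tuple[tuple[int, str, float], ...], int, int]:
    """Grow one partial tree; return the first terminal leaf reached.

    The frontier is expanded best-first by node class entropy (ties by
    creation order).  A node is terminal when pure, smaller than
    ``min_leaf`` or unsplittable; the first terminal node popped becomes
    the extracted rule (conditions, n_pos, n_neg).
    """
    counter = 0
    all_idx = np.arange(len(y))
    heap: list[tuple[float, int, np.ndarray, tuple]] = []
    heapq.heappush(heap, (_node_entropy(y), counter, all_idx, ()))
    while heap:
        _, _, idx, conditions = heapq.heappop(heap)
        ysub = y[idx]
        n_pos = int(ysub.sum())
        n_neg = int(len(ysub) - n_pos)
        terminal = n_pos == 0 or n_neg == 0 or len(idx) < min_leaf
        split = None if terminal else best_split(X[idx], ysub)
        if terminal or split is None:
            return conditions, n_pos, n_neg
        feature, thr = split
        mask = X[idx, feature] <= thr
        for child_idx, op in ((idx[mask], "<="), (idx[~mask], ">")):
            counter += 1
            heapq.heappush(
                heap,
                (
                    _node_entropy(y[child_idx]),
                    counter,
                    child_idx,
                    _merge_condition(conditions, feature, op, thr),
                ),
            )
    raise AssertionError("partial tree expansion exhausted without a terminal leaf")


def fit_rules(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    min_leaf: int = 2,
    unpruned: bool = True,
    seed: int = 0,
) -> RuleList:
    """Train a rule list on a numeric matrix with binary labels (1 = positive)."""
    if not unpruned:
        raise ValueError("only unpruned training is supported")
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains missing or non-finite values")
    feature_names = tuple(feature_names)
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length must match number of columns")

    remaining = np.arange(len(y))
    rules: list[Rule] = []
    default_counts = (0, 0)
    while remaining.size:
        conditions, n_pos, n_neg = _grow_rule(X[remaining], y[remaining], min_leaf)
        if not conditions:
            # catch-all leaf: the rest of the data becomes the default
            default_counts = (n_pos, n_neg)
            break
        rule = Rule(
            conditions=tuple(
                (feature_names[f], op, thr) for f, op, thr in conditions
            ),
            n_pos=n_pos,
            n_neg=n_neg,
        )
        rules.append(rule)
        covered = _match_matrix(rule, X[remaining], feature_names)
        assert covered.sum() == rule.n_covered, "rule coverage mismatch"
        remaining = remaining[~covered]
    return RuleList(
        rules=tuple(rules),
        default_counts=default_counts,
        feature_names=feature_names,
        training_meta={
            "algorithm": "part_separate_and_conquer",
            "min_leaf": min_leaf,
            "unpruned": True,
            "seed": seed,
            "n_train": int(len(y)),
            "n_pos": int(y.sum()),
        },
    )


def train(
    matrix: FeatureMatrix,
    min_leaf: int = 2,
    unpruned: bool = True,
    seed: int = 0,
) -> RuleList:
    """Train on a labeled :class:`~vlamy.features.FeatureMatrix`."""
    return fit_rules(
        matrix.X, matrix.y, matrix.feature_names, min_leaf=min_leaf,
        unpruned=unpruned, seed=seed,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _match_matrix(
    rule: Rule, X: np.ndarray, feature_names: Sequence[str]
) -> np.ndarray:
    col = {name: i for i, name in enumerate(feature_names)}
    mask = np.ones(len(X), dtype=bool)
    for feature, op, thr in rule.conditions:
        values = X[:, col[feature]]
        mask &= values <= thr if op == "<=" else values > thr
    return mask


def predict_proba(model: RuleList, row: Mapping[str, float]) -> float:
    """P(amyloid) for one feature row: first matching rule's Laplace estimate."""
    missing = [f for f in model.feature_names if f not in row]
    if missing:
        raise KeyError(f"row is missing model features: {missing}")
    for rule in model.rules:
        if rule.matches(row):
            return rule.probability
    return model.default_probability


def predict_proba_matrix(
    model: RuleList, X: np.ndarray, feature_names: Sequence[str] | None = None
) -> np.ndarray:
    """Vectorized :func:`predict_proba` over a numeric matrix."""
    if feature_names is None:
        feature_names = model.feature_names
    X = np.asarray(X, dtype=float)
    out = np.full(len(X), model.default_probability)
    unassigned = np.ones(len(X), dtype=bool)
    for rule in model.rules:
        hit = unassigned & _match_matrix(rule, X, feature_names)
        out[hit] = rule.probability
        unassigned &= ~hit
    return out


def classify(
    model: RuleList, row: Mapping[str, float], threshold: float = DEFAULT_THRESHOLD
) -> str:
    """Call a sequence amyloidogenic iff P(amyloid) >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return POSITIVE if predict_proba(model, row) >= threshold else NEGATIVE


def select_threshold(
    probabilities: Sequence[float],
    labels: Sequence[int],
    criterion: str = "fixed",
) -> float:
    """Pick the decision threshold.

    ``fixed`` returns the package default (0.15).  The data-driven criteria
    sweep every distinct predicted probability as a candidate threshold
    (calls use the >= convention) and return the maximizer of balanced
    accuracy (``max_balanced_accuracy``) or the Youden J statistic
    (``max_youden``); ties go to the smaller threshold, favoring
    sensitivity under class imbalance.
    """
    if criterion == "fixed":
        return DEFAULT_THRESHOLD
    if criterion not in ("max_balanced_accuracy", "max_youden"):
        raise ValueError(f"unknown criterion {criterion!r}")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("data-driven threshold selection needs both classes")
    best_t, best_score = None, -np.inf
    for t in np.unique(p):
        calls = p >= t
        sens = (calls & (y == 1)).sum() / n_pos
        spec = (~calls & (y == 0)).sum() / n_neg
        score = (sens + spec) / 2 if criterion == "max_balanced_accuracy" else sens + spec - 1
        if score > best_score + _EPS:
            best_score, best_t = score, float(t)
    return best_t
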