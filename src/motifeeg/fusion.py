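"""Fusing benchmark and motif feature groups.

Three strategies:

* **feature fusion** -- concatenate the groups' feature tables before
  selection;
* **score-level fusion** -- combine per-group class probabilities with
  weights ``alpha_i`` and development-performance factors
  ``t_i = F_i / sum_j alpha_j F_j`` (F_i = training F1 of group i), so the
  fused probability ``p0 = sum_i alpha_i p_i t_i`` sums to one per trial by
  construction; the weight simplex is searched on a 0.1 grid;
* **output-associative fusion (OAF)** -- a second-stage classifier per
  affect dimension consuming the stage-1 class probabilities of every
  group for *both* dimensions, exploiting valence/arousal correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.preprocessing import StandardScaler

from .classification import DIMENSIONS, make_classifier
from .extraction import FeatureTable

__all__ = ["GroupPrediction", "feature_fusion", "score_fusion",
           "search_weights", "simplex_grid", "oaf_fuse"]


@dataclass(frozen=True)
class GroupPrediction:
    """Per-trial class probabilities of one feature group's classifier."""

    group_id: str
    proba: np.ndarray  # (n_trials, 2), rows sum to 1
    f1_train: float

    def __post_init__(self) -> None:
        p = np.asarray(self.proba, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("proba must be (n_trials, 2)")
        if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0):
            raise ValueError("rows of proba must be distributions")
        if not 0.0 <= self.f1_train <= 1.0:
            raise ValueError("f1_train must be in [0, 1]")
        object.__setattr__(self, "proba", p)


def feature_fusion(tables: list[FeatureTable]) -> FeatureTable:
    """Column-concatenate feature tables over identical trials."""
    tables = [t for t in tables if t.data.shape[1] > 0]
    if not tables:
        raise ValueError("nothing to fuse")
    first = tables[0]
    names: list[str] = []
    for t in tables:
        if len(t.data) != len(first.data):
            raise ValueError("trial-count mismatch between groups")
        if not t.labels.equals(first.labels):
            raise ValueError("label mismatch between groups")
        names.extend(t.feature_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names across groups")
    groups: dict[str, tuple[str, str]] = {}
    for t in tables:
        groups.update(t.groups)
    return FeatureTable(
        data=pd.concat([t.data.reset_index(drop=True) for t in tables],
                       axis=1),
        labels=first.labels.reset_index(drop=True),
        groups=groups, subjects=first.subjects)


def score_fusion(preds: list[GroupPrediction],
                 weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted score-level fusion of per-group class probabilities.

    Returns ``(fused_proba, decisions)``; fused rows sum to one because
    ``sum_i alpha_i t_i = 1`` algebraically.
    """
    alphas = np.asarray(weights, dtype=float)
    if alphas.size != len(preds):
        raise ValueError("one weight per group required")
    if np.any(alphas < 0) or not np.isclose(alphas.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    n = len(preds[0].proba)
    if any(len(p.proba) != n for p in preds):
        raise ValueError("groups cover different trial counts")
    F = np.array([p.f1_train for p in preds])
    denom = float((alphas * F).sum())
    if denom == 0:
        raise ValueError("all weighted development F1 scores are zero")
    t = F / denom
    fused = sum(a * ti * p.proba for a, ti, p in zip(alphas, t, preds))
    return fused, fused.argmax(axis=1)


def simplex_grid(n_groups: int, step: float = 0.1):
    """All weight vectors on the simplex with the given grid resolution."""
    k = int(round(1.0 / step))
    if not np.isclose(k * step, 1.0):
        raise ValueError("grid step must divide 1")
    for comb in itertools.combinations_with_replacement(range(n_groups), k):
        counts = np.bincount(comb, minlength=n_groups)
        yield counts / k


def search_weights(preds: list[GroupPrediction], dev_labels: np.ndarray,
                   step: float = 0.1) -> np.ndarray:
    """Exhaustive simplex search maximizing development BACC.

    Ties break toward the most uniform weight vector (then lexicographic),
    so identical groups fuse with equal weights.
    """
    y = np.asarray(dev_labels, dtype=int)
    uniform = np.full(len(preds), 1.0 / len(preds))
    best = None
    for alphas in simplex_grid(len(preds), step):
        _, dec = score_fusion(preds, alphas)
        bacc = balanced_accuracy_score(y, dec)
        key = (-bacc, float(np.abs(alphas - uniform).sum()),
               tuple(alphas))
        if best is None or key < best[0]:
            best = (key, alphas)
    return best[1]


def _stage1_matrix(preds_by_dim: dict[str, list[GroupPrediction]]
                   ) -> np.ndarray:
    """Concatenate stage-1 probabilities of all groups for both dimensions."""
    missing = [d for d in DIMENSIONS if d not in preds_by_dim]
    if missing:
        raise ValueError(f"missing stage-1 predictions for {missing}")
    cols = []
    for dim in DIMENSIONS:
        for p in preds_by_dim[dim]:
            cols.append(p.proba[:, 1])  # class-1 probability carries it all
    return np.column_stack(cols)


def oaf_fuse(train_preds: dict[str, list[GroupPrediction]],
             test_preds: dict[str, list[GroupPrediction]],
             train_labels: dict[str, np.ndarray],
             seed: int = 0) -> dict[str, np.ndarray]:
    """Output-associative fusion: per-dimension second-stage classifier.

    For each dimension, the reference RBF-SVM is trained on the stage-1
    class probabilities of all groups for *both* dimensions and predicts
    the final label, letting correlated dimensions inform each other.
    """
    X_tr = _stage1_matrix(train_preds)
    X_te = _stage1_matrix(test_preds)
    out = {}
    for dim in DIMENSIONS:
        if dim not in train_labels:
            raise ValueError(f"missing labels for {dim}")
        scaler = StandardScaler().fit(X_tr)
        clf = make_classifier(seed=seed).fit(scaler.transform(X_tr),
                                             np.asarray(train_labels[dim]))
        out[dim] = clf.predict(scaler.transform(X_te))
    return out
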