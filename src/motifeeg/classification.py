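"""Label binarization, RBF-SVM evaluation protocol and chance testing.

Ratings on the 9-point SAM scale are binarized with a per-subject
("individualized") threshold chosen to balance the high/low split, which
compensates subjective rating bias.  Classification uses a radial-kernel
SVM with fixed hyperparameters (C = 1, gamma = 0.01; no hyperparameter
search by design) evaluated over repeated random 90/10 train/test splits;
the figure of merit is balanced accuracy, BACC = (sensitivity +
specificity) / 2, whose chance level is 0.5 at any class prevalence.
Significance against chance is a one-sample t-test of the per-split BACC
values against the empirical mean of a random-voting classifier run on the
same splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st
from sklearn.metrics import balanced_accuracy_score, f1_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "DIMENSIONS",
    "LabelingResult",
    "EvalResult",
    "individualized_threshold",
    "balanced_accuracy",
    "make_classifier",
    "train_eval",
    "random_voting_eval",
    "chance_test",
]

DIMENSIONS = ("valence", "arousal")

#: Fixed SVM hyperparameters (no optimization by design).
SVM_C = 1.0
SVM_GAMMA = 0.01


@dataclass(frozen=True)
class LabelingResult:
    """Chosen per-subject threshold and the resulting binary labels."""

    threshold: float
    labels: np.ndarray  # 1 = "high" (rating > threshold)


@dataclass
class EvalResult:
    """Balanced-accuracy summary over repeated random splits."""

    bacc_mean: float
    bacc_std: float
    baccs: np.ndarray
    f1_train: float = float("nan")
    p_vs_chance: float = float("nan")


def individualized_threshold(ratings: np.ndarray,
                             integer_only: bool = False) -> LabelingResult:
    """Per-subject rating threshold giving the most balanced high/low split.

    Candidates are midpoints between consecutive distinct observed ratings
    plus the integers 1..9 (``integer_only=True`` restricts to integers).
    ``high`` means rating strictly above the threshold.  Ties in balance are
    broken toward the candidate closest to the scale midpoint 5, then the
    smaller value.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size < 2:
        raise ValueError("need at least 2 trials")
    distinct = np.unique(ratings)
    if distinct.size == 1:
        warnings.warn("all ratings identical; one class is empty",
                      stacklevel=2)
        return LabelingResult(5.0, (ratings > 5.0).astype(int))
    candidates = list(np.arange(1.0, 10.0))
    if not integer_only:
        candidates += list((distinct[:-1] + distinct[1:]) / 2.0)
    best = None
    for thr in candidates:
        hi = int((ratings > thr).sum())
        lo = ratings.size - hi
        key = (abs(hi - lo), abs(thr - 5.0), thr)
        if best is None or key < best[0]:
            best = (key, thr)
    thr = float(best[1])
    return LabelingResult(thr, (ratings > thr).astype(int))


def balanced_accuracy(tp: int, fn: int, tn: int, fp: int) -> float:
    """BACC = (TP/P + TN/N) / 2 with P = TP+FN, N = TN+FP."""
    P, N = tp + fn, tn + fp
    if P == 0 or N == 0:
        raise ValueError("both classes must be present")
    return (tp / P + tn / N) / 2.0


def make_classifier(seed: int | None = 0, probability: bool = False) -> SVC:
    """The reference RBF-SVM (C=1, gamma=0.01), optionally calibrated
    to class-membership probabilities via Platt scaling / pairwise
    coupling."""
    kwargs = {"probability": True} if probability else {}
    return SVC(C=SVM_C, kernel="rbf", gamma=SVM_GAMMA, random_state=seed,
               **kwargs)


def _splits(n: int, y: np.ndarray, n_iter: int, seed: int,
            test_size: float = 0.1):
    """Random 90/10 splits derived from a master seed by iteration index.

    A split whose test half misses a class is resampled (BACC undefined
    otherwise)."""
    idx = np.arange(n)
    for i in range(n_iter):
        sub_seed = seed + i
        for _ in range(100):
            tr, te = train_test_split(idx, test_size=test_size,
                                      random_state=sub_seed % (2 ** 31))
            if len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2:
                break
            sub_seed += n_iter
        yield tr, te


def train_eval(X: np.ndarray, y: np.ndarray, n_iter: int = 100,
               seed: int = 0, test_size: float = 0.1) -> EvalResult:
    """Repeated-split evaluation of the reference SVM.

    Per iteration: fresh random 90/10 split, standardization with training
    statistics only, fit, test BACC.  Also reports the F1 score on the
    training data of the last split (the development-performance weight
    used by score-level fusion).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_trials, n_features) matching y")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    baccs = []
    f1_train = float("nan")
    for tr, te in _splits(len(y), y, n_iter, seed, test_size):
        scaler = StandardScaler().fit(X[tr])
        clf = make_classifier().fit(scaler.transform(X[tr]), y[tr])
        pred = clf.predict(scaler.transform(X[te]))
        baccs.append(balanced_accuracy_score(y[te], pred))
        f1_train = f1_score(y[tr], clf.predict(scaler.transform(X[tr])))
    baccs = np.asarray(baccs)
    return EvalResult(float(baccs.mean()), float(baccs.std()), baccs,
                      f1_train=float(f1_train))


def random_voting_eval(y: np.ndarray, n_iter: int = 100,
                       seed: int = 0, test_size: float = 0.1) -> EvalResult:
    """Uniform random predictions evaluated under the same split protocol.

    Defines the empirical chance level for :func:`chance_test`; its mean
    BACC is 0.5 up to Monte-Carlo error at any prevalence.
    """
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    baccs = []
    for _, te in _splits(len(y), y, n_iter, seed, test_size):
        pred = rng.integers(0, 2, size=len(te))
        baccs.append(balanced_accuracy_score(y[te], pred))
    baccs = np.asarray(baccs)
    return EvalResult(float(baccs.mean()), float(baccs.std()), baccs)


def chance_test(bacc_samples: np.ndarray,
                chance_mean: float = 0.5) -> float:
    """One-sample t-test p-value of BACC samples against the chance mean.

    ``chance_mean`` is typically the empirical mean of
    :func:`random_voting_eval` on the same splits.  A zero-variance sample
    degenerates to an exact comparison of means (p = 1 if equal, else 0).
    """
    s = np.asarray(bacc_samples, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    if np.allclose(s.std(), 0.0):
        return 1.0 if np.isclose(s.mean(), chance_mean) else 0.0
    return float(_st.ttest_1samp(s, chance_mean).pvalue)
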