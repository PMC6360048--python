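"""Feature ranking and selection: ANOVA, mRMR and RFE, with grid search.

All selectors operate on a development partition only (90% of trials,
split with a fixed seed); the held-out 10% never influences ranking.  The
grid search crosses selector x number-of-features and scores each cell
with the repeated-split SVM protocol restricted to the development data,
returning the best combination with deterministic tie-breaking (fewer
features first, then selector order anova < mrmr < rfe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE, f_classif
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .classification import train_eval
from .extraction import FeatureTable

__all__ = ["SelectionResult", "anova_rank", "mrmr_select", "rfe_select",
           "grid_search", "dev_holdout_split"]

ALGORITHMS = ("anova", "mrmr", "rfe")


@dataclass
class SelectionResult:
    """Winning selector, its ranked features and development score."""

    algorithm: str
    ranked_features: list[str]
    nof: int
    score: float
    per_cell: pd.DataFrame | None = None

    @property
    def selected(self) -> list[str]:
        return self.ranked_features[: self.nof]


def _xy(ft: FeatureTable, dimension: str,
        idx: np.ndarray | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    X = ft.data if idx is None else ft.data.iloc[idx]
    y = ft.labels[dimension].to_numpy()
    if idx is not None:
        y = y[idx]
    return X, y


def anova_rank(ft: FeatureTable, dimension: str,
               idx: np.ndarray | None = None) -> pd.DataFrame:
    """One-way F-test of class-mean differences, per feature.

    Returns a frame with columns ``feature, F, p`` sorted by ascending p
    (ties broken by feature name).  Zero-variance features get p = 1.
    """
    X, y = _xy(ft, dimension, idx)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        F, p = f_classif(X.to_numpy(), y)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance feature(s) "
                      "assigned p = 1", stacklevel=2)
        p = np.where(degenerate, 1.0, p)
        F = np.where(np.isfinite(F), F, 0.0)
    out = pd.DataFrame({"feature": X.columns, "F": F, "p": p})
    return out.sort_values(["p", "feature"], kind="stable",
                           ignore_index=True)


def _discretize(col: np.ndarray, bins: int = 5) -> np.ndarray:
    """Equal-frequency binning for mutual-information estimation."""
    edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, col)


def mrmr_select(ft: FeatureTable, dimension: str, nof: int,
                idx: np.ndarray | None = None,
                bins: int = 5) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance forward selection.

    Mutual information is estimated on equal-frequency discretized
    features (5 bins).  The first pick maximizes MI(feature; label); each
    subsequent pick maximizes MI(f; label) minus the mean MI(f; chosen)
    (the difference criterion).  Ties break by feature name.
    """
    X, y = _xy(ft, dimension, idx)
    names = list(X.columns)
    if not 1 <= nof <= len(names):
        raise ValueError(f"nof must be in [1, {len(names)}]")
    binned = {n: _discretize(X[n].to_numpy(), bins) for n in names}
    relevance = {n: mutual_info_score(binned[n], y) for n in names}
    chosen: list[str] = []
    remaining = sorted(names)
    pair_mi: dict[tuple[str, str], float] = {}

    def redundancy(cand: str) -> float:
        if not chosen:
            return 0.0
        total = 0.0
        for c in chosen:
            key = (cand, c)
            if key not in pair_mi:
                pair_mi[key] = mutual_info_score(binned[cand], binned[c])
            total += pair_mi[key]
        return total / len(chosen)

    while len(chosen) < nof:
        scores = [(relevance[n] - redundancy(n), n) for n in remaining]
        best = max(scores, key=lambda s: (s[0], [-ord(ch) for ch in s[1]]))
        chosen.append(best[1])
        remaining.remove(best[1])
    return chosen


def rfe_select(ft: FeatureTable, dimension: str, nof: int,
               idx: np.ndarray | None = None) -> list[str]:
    """Recursive feature elimination with a linear maximum-margin ranker.

    Features are standardized, a linear-kernel SVM is refit each round and
    the feature with the smallest squared coefficient is dropped, one per
    round, until ``nof`` remain.  (The evaluation classifier's radial
    kernel has no per-feature weights, so the linear margin is the
    importance proxy.)  Returned order: surviving features in column
    order, then eliminated ones in reverse elimination order.
    """
    X, y = _xy(ft, dimension, idx)
    names = list(X.columns)
    if not 1 <= nof <= len(names):
        raise ValueError(f"nof must be in [1, {len(names)}]")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Xs = StandardScaler().fit_transform(X.to_numpy())
    rfe = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=nof,
              step=1).fit(Xs, y)
    order = np.argsort(rfe.ranking_, kind="stable")
    return [names[i] for i in order]


def dev_holdout_split(n: int, dev_fraction: float = 0.9,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """The fixed development/holdout partition (default 90/10, seed 0)."""
    dev, hold = train_test_split(np.arange(n), train_size=dev_fraction,
                                 random_state=seed)
    return np.sort(dev), np.sort(hold)


_SELECTORS = {
    "anova": lambda ft, dim, nof, idx: list(
        anova_rank(ft, dim, idx)["feature"][:nof]),
    "mrmr": mrmr_select,
    "rfe": rfe_select,
}


def grid_search(ft: FeatureTable, dimension: str,
                nof_grid: list[int] | None = None,
                algorithms: tuple[str, ...] = ALGORITHMS,
                dev_fraction: float = 0.9, split_seed: int = 0,
                n_iter: int = 10, eval_seed: int = 0) -> SelectionResult:
    """Cross selector x nof on the development split, score each cell.

    Each cell selects features on the development partition and scores them
    with the repeated-split SVM protocol (``n_iter`` splits) run inside the
    development data.  Ties break toward fewer features, then selector
    order.
    """
    if nof_grid is None:
        nof_grid = list(range(1, min(50, len(ft.feature_names)) + 1))
    if not nof_grid or not algorithms:
        raise ValueError("empty grid")
    dev, _ = dev_holdout_split(len(ft.data), dev_fraction, split_seed)
    X_dev = ft.data.iloc[dev]
    y_dev = ft.labels[dimension].to_numpy()[dev]
    cells = []
    best = None
    for alg_rank, alg in enumerate(algorithms):
        if alg not in _SELECTORS:
            raise ValueError(f"unknown algorithm {alg!r}")
        max_nof = min(max(nof_grid), len(ft.feature_names))
        if alg == "rfe":
            # rank to a single survivor: prefixes then equal RFE-to-nof runs
            ranked_full = rfe_select(ft, dimension, 1, dev)
        else:
            ranked_full = _SELECTORS[alg](ft, dimension, max_nof, dev)
        for nof in nof_grid:
            selected = ranked_full[:nof]
            res = train_eval(X_dev[selected].to_numpy(), y_dev,
                             n_iter=n_iter, seed=eval_seed)
            cells.append({"algorithm": alg, "nof": nof,
                          "bacc": res.bacc_mean})
            key = (-res.bacc_mean, nof, alg_rank)
            if best is None or key < best[0]:
                best = (key, SelectionResult(alg, ranked_full, nof,
                                             res.bacc_mean))
    result = best[1]
    result.per_cell = pd.DataFrame(cells)
    return result
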