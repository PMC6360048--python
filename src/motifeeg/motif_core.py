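"""Ordinal-pattern (motif) encoding, permutation entropy and dissimilarity.

A motif of degree ``n = 3`` is the rank ordering of three samples
``x(i), x(i+lag), x(i+2*lag)``.  There are ``3! = 6`` orderings, coded 1-6:

====  =======================
code  ordering
====  =======================
1     x1 < x2 < x3  (ascending)
2     x1 < x3 < x2
3     x2 < x1 < x3
4     x3 < x1 < x2
5     x3 < x2 < x1  (descending)
6     x2 < x3 < x1
====  =======================

The code depends only on the shape of the series, never on its amplitude,
which is what makes motif statistics robust to amplitude artefacts.  Ties
are resolved deterministically by treating the earlier-indexed sample as
the smaller one; exact ties are measure-zero for continuous EEG.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "N_MOTIFS",
    "encode_motifs",
    "motif_distribution",
    "permutation_entropy",
    "ordinal_dissimilarity",
]

#: Number of motifs for degree 3.
N_MOTIFS = 6


def encode_motifs(x: np.ndarray, lag: int = 1) -> np.ndarray:
    """Convert a 1-D series (or each row of a 2-D array) to motif codes.

    Returns an integer array of codes in ``{1..6}`` of length
    ``len(x) - 2*lag`` (per row).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[-1]
    if n < 2 * lag + 1:
        raise ValueError(
            f"series of length {n} too short for lag {lag} (need "
            f">= {2 * lag + 1})")
    a = x[..., : n - 2 * lag]
    b = x[..., lag: n - lag]
    c = x[..., 2 * lag:]
    # ties: earlier index counts as smaller, hence <= along increasing index
    ab = a <= b
    bc = b <= c
    ac = a <= c
    codes = np.empty(a.shape, dtype=np.int8)
    codes[ab & bc] = 1
    codes[ab & ~bc & ac] = 2
    codes[~ab & bc & ac] = 3
    codes[ab & ~bc & ~ac] = 4
    codes[~ab & ~bc] = 5
    codes[~ab & bc & ~ac] = 6
    return codes[0] if squeeze else codes


def motif_distribution(codes: np.ndarray) -> np.ndarray:
    """Relative frequency of each of the 6 motif codes.

    Accepts a 1-D code series (returns shape ``(6,)``) or a 2-D array of
    per-row series (returns ``(n_rows, 6)``).
    """
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("empty motif series")
    if codes.ndim == 1:
        counts = np.bincount(codes, minlength=N_MOTIFS + 1)[1:]
        return counts / codes.size
    return np.stack([motif_distribution(row) for row in codes])


def permutation_entropy(p: np.ndarray) -> float:
    """Shannon entropy (natural log) of a motif distribution.

    ``0 * log 0`` is taken as 0; the range is ``[0, ln 6]`` with the maximum
    at the uniform distribution (a fully irregular series).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size != N_MOTIFS:
        raise ValueError("expected a length-6 distribution")
    if np.any(p < -1e-12) or not np.isclose(p.sum(), 1.0):
        raise ValueError("not a probability distribution")
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())


def ordinal_dissimilarity(px: np.ndarray, py: np.ndarray,
                          root: bool = False) -> float:
    """Ordinal-distance dissimilarity between two motif distributions.

    ``D_m = n!/(n!-1) * sum_j (px_j - py_j)^2`` with ``n = 3``, i.e. a
    ``6/5``-scaled squared Euclidean distance between the two length-6
    distributions: 0 iff identical, maximal (2.4) for distributions
    concentrated on different motifs.  ``root=True`` returns the square
    root of the scaled sum instead (a metric variant; same ranking).
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    if px.shape != (N_MOTIFS,) or py.shape != (N_MOTIFS,):
        raise ValueError("expected length-6 distributions")
    d = N_MOTIFS / (N_MOTIFS - 1) * float(((px - py) ** 2).sum())
    return float(np.sqrt(d)) if root else d
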