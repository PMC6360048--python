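"""Network-level graph metrics on motif-synchronization brain graphs.

Electrodes are nodes; the synchronization degree matrix Q gives edge
weights.  An unweighted graph is obtained by thresholding at the mean
off-diagonal weight (edges strictly above the mean survive).  From the
weighted and unweighted graphs the module computes, per band:

* mean degree ``k`` / weighted degree ``kw``,
* mean clustering coefficient ``C`` / ``Cw`` (geometric-mean triangle
  intensity for the weighted variant),
* transitivity ``Tr`` / ``Trw`` (triangles over connected triplets),
* characteristic path length ``L`` / ``Lw`` and global efficiency
  ``G`` / ``Gw`` (weighted edge length = 1/weight),
* small-world ratios ``Ls = L/L_rand``, ``Cs = C/C_rand`` and
  small-worldness ``S = Cs/Ls`` against a degree-preserving rewired null
  ensemble,
* direction of flow ``DoF``: the half-matrix sum of the direction
  indicators q (positive when the network tends to transmit along the
  channel ordering).

Together with permutation entropy (electrode-averaged, 4) and ordinal
dissimilarity over the 12 interhemispheric pairs (48), the motif feature
group has 20 weighted + 20 unweighted + 12 small-world + 4 DoF + 4 PE +
48 Dm = 108 named features.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .motif_connectivity import SyncConfig, SyncResult, _sync_matrices
from .motif_core import (encode_motifs, motif_distribution,
                         ordinal_dissimilarity, permutation_entropy)
from .signal_io import (BandDefinition, DEFAULT_BANDS, Montage,
                        band_decompose)

__all__ = [
    "threshold_graph",
    "degree_features",
    "clustering_features",
    "transitivity",
    "path_features",
    "small_world_features",
    "direction_of_flow",
    "band_graph_features",
    "motif_feature_names",
    "extract_motif_features",
]


def _check_square_symmetric(m: np.ndarray, name: str = "matrix") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    return m


def threshold_graph(weights: np.ndarray) -> np.ndarray:
    """Binary adjacency: keep edges strictly above the mean off-diag weight."""
    w = _check_square_symmetric(weights, "weights")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    iu = np.triu_indices_from(w, k=1)
    thr = w[iu].mean()
    # strictly above the mean; the epsilon absorbs summation round-off so
    # a constant-weight graph thresholds to the empty graph
    adj = (w - thr > 1e-12 * max(1.0, thr)).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


def degree_features(adjacency: np.ndarray,
                    weights: np.ndarray) -> tuple[float, float]:
    """Mean binary degree and mean weighted degree (strength)."""
    a = _check_square_symmetric(adjacency, "adjacency")
    w = _check_square_symmetric(weights, "weights")
    return float(a.sum(axis=1).mean()), float(w.sum(axis=1).mean())


def _local_clustering(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1)
    # e_i = edges among neighbours of i = diag(A^3)/2
    e = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * e / denom, 0.0)
    return c


def _weighted_local_clustering(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    m = np.cbrt(w)
    # t_i = geometric-mean triangle intensity around i = diag(M^3)/2
    t = np.diag(m @ m @ m) / 2.0
    kw = w.sum(axis=1)
    n_neighbors = (w > 0).sum(axis=1)
    denom = kw * (kw - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where((n_neighbors >= 2) & (denom > 0), 2.0 * t / denom, 0.0)
    return c


def clustering_features(adjacency: np.ndarray,
                        weights: np.ndarray) -> tuple[float, float]:
    """Mean clustering coefficient, binary and weighted.

    Nodes with fewer than two neighbours (or weighted degree <= 1, whose
    normalization would be non-positive) contribute zero.
    """
    a = _check_square_symmetric(adjacency, "adjacency")
    w = _check_square_symmetric(weights, "weights")
    return (float(_local_clustering(a).mean()),
            float(_weighted_local_clustering(w).mean()))


def transitivity(graph: np.ndarray, weighted: bool = False) -> float:
    """Triangles-to-triplets ratio of the whole network.

    Binary: ``sum_i 2 e_i / sum_i k_i (k_i - 1)``; weighted: triangle
    intensities ``t_i`` over ``sum_i kw_i (kw_i - 1)``, mirroring the
    weighted-clustering construction.  0 when there are no triplets.
    """
    g = _check_square_symmetric(graph, "graph")
    if weighted:
        m = np.cbrt(g)
        tri = np.diag(m @ m @ m).sum()  # = sum_i 2 t_i
        kw = g.sum(axis=1)
        denom = (kw * (kw - 1)).sum()
    else:
        tri = np.diag(g @ g @ g).sum()  # = sum_i 2 e_i
        k = g.sum(axis=1)
        denom = (k * (k - 1)).sum()
    return float(tri / denom) if denom > 0 else 0.0


def path_features(graph: np.ndarray,
                  weighted: bool = False) -> tuple[float, float]:
    """Characteristic path length L and global efficiency G.

    Unweighted distance is hop count; weighted distance sums ``1/w`` along
    the path (higher synchronization = shorter edge).  L averages shortest
    distances over connected ordered pairs only; disconnected pairs
    contribute 0 to G via ``1/inf``.
    """
    g = _check_square_symmetric(graph, "graph")
    n = g.shape[0]
    if n < 2:
        return 0.0, 0.0
    if weighted:
        with np.errstate(divide="ignore"):
            lengths = np.where(g > 0, 1.0 / np.where(g > 0, g, 1.0), 0.0)
        d = shortest_path(lengths, method="D", directed=False, unweighted=False)
    else:
        d = shortest_path(g, method="D", directed=False, unweighted=True)
    off = ~np.eye(n, dtype=bool)
    dd = d[off]
    finite = np.isfinite(dd)
    L = float(dd[finite].mean()) if finite.any() else 0.0
    with np.errstate(divide="ignore"):
        inv = np.where(finite & (dd > 0), 1.0 / np.where(dd > 0, dd, 1.0), 0.0)
    G = float(inv.mean())
    return L, G


def _rewired_null(adjacency: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving (double-edge-swap) rewired copy of a binary graph.

    Performs ``10 m`` successful swaps (m = edge count): edges (a, b) and
    (c, d) are replaced by (a, d) and (c, b) when that creates neither a
    self-loop nor a multi-edge, which preserves every node degree exactly.
    Falls back to a density-matched random graph when the graph is too
    sparse to rewire.
    """
    import random as _random

    a = np.asarray(adjacency)
    n = a.shape[0]
    ii, jj = np.nonzero(np.triu(a, 1))
    edges = list(zip(ii.tolist(), jj.tolist()))
    m = len(edges)
    if m < 2:
        warnings.warn("graph too sparse to rewire; using density-matched "
                      "random null", stacklevel=2)
        return nx.to_numpy_array(
            nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31))))
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for u, v in edges:
        neighbors[u].add(v)
        neighbors[v].add(u)
    py_rng = _random.Random(int(rng.integers(2 ** 31)))
    randrange = py_rng.randrange
    target, done, tries, max_tries = 10 * m, 0, 0, 1000 * m
    while done < target and tries < max_tries:
        tries += 1
        i = randrange(m)
        j = randrange(m)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if randrange(2):  # swap orientation of the second edge
            x, y = y, x
        if u == y or v == x or u == x or v == y:
            continue
        if y in neighbors[u] or v in neighbors[x]:
            continue
        neighbors[u].remove(v); neighbors[v].remove(u)
        neighbors[x].remove(y); neighbors[y].remove(x)
        neighbors[u].add(y); neighbors[y].add(u)
        neighbors[x].add(v); neighbors[v].add(x)
        edges[i] = (u, y)
        edges[j] = (x, v)
        done += 1
    if done < target:
        warnings.warn("rewiring stalled before the target swap count; "
                      "null graph only partially randomized", stacklevel=2)
    out = np.zeros((n, n))
    for u, v in edges:
        out[u, v] = out[v, u] = 1.0
    return out


def small_world_features(adjacency: np.ndarray, n_null: int = 10,
                         seed: int = 0) -> tuple[float, float, float]:
    """Small-world ratios Ls = L/L_rand, Cs = C/C_rand and S = Cs/Ls.

    The null ensemble is ``n_null`` degree-preserving rewirings of the
    thresholded binary graph; C_rand and L_rand are ensemble means.  A ratio
    with zero null mean is reported as 0 (degenerate graph).
    """
    a = _check_square_symmetric(adjacency, "adjacency")
    if a.sum() == 0:
        raise ValueError("adjacency is empty")
    C = float(_local_clustering(a).mean())
    L, _ = path_features(a, weighted=False)
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    for _ in range(n_null):
        nm = _rewired_null(a, rng)
        c_null.append(float(_local_clustering(nm).mean()))
        l_null.append(path_features(nm, weighted=False)[0])
    c_rand = float(np.mean(c_null))
    l_rand = float(np.mean(l_null))
    Cs = C / c_rand if c_rand > 0 else 0.0
    Ls = L / l_rand if l_rand > 0 else 0.0
    S = Cs / Ls if Ls > 0 else 0.0
    return Ls, Cs, S


def direction_of_flow(q: np.ndarray) -> float:
    """Half-matrix sum of direction indicators: DoF = sum_{i<j} q_ij.

    The full ordered-pair sum of an antisymmetric matrix is identically
    zero, so the upper triangle carries the information.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("q must be square")
    if not np.allclose(q, -q.T):
        raise ValueError("q must be antisymmetric")
    iu = np.triu_indices_from(q, k=1)
    return float(q[iu].sum())


#: Per-band graph-family feature keys in output order.
_GRAPH_KEYS = ("k", "kw", "C", "Cw", "Tr", "Trw", "L", "Lw", "G", "Gw",
               "Ls", "Cs", "S", "DoF")

#: Subgroup tags used by selection/fusion bookkeeping.
GRAPH_SUBGROUPS = {
    "k": "unweighted_graph", "C": "unweighted_graph",
    "Tr": "unweighted_graph", "L": "unweighted_graph",
    "G": "unweighted_graph",
    "kw": "weighted_graph", "Cw": "weighted_graph", "Trw": "weighted_graph",
    "Lw": "weighted_graph", "Gw": "weighted_graph",
    "Ls": "small_world", "Cs": "small_world", "S": "small_world",
    "DoF": "dof",
}


def band_graph_features(sync: SyncResult, n_null: int = 10,
                        seed: int = 0) -> dict[str, float]:
    """The 14 network-level features for one band's connectivity matrices."""
    W = sync.Q
    A = threshold_graph(W)
    k, kw = degree_features(A, W)
    C, Cw = clustering_features(A, W)
    Tr = transitivity(A, weighted=False)
    Trw = transitivity(W, weighted=True)
    L, G = path_features(A, weighted=False)
    Lw, Gw = path_features(W, weighted=True)
    if A.sum() > 0:
        Ls, Cs, S = small_world_features(A, n_null=n_null, seed=seed)
    else:
        Ls, Cs, S = 0.0, 0.0, 0.0
    dof = direction_of_flow(sync.q)
    vals = (k, kw, C, Cw, Tr, Trw, L, Lw, G, Gw, Ls, Cs, S, dof)
    return dict(zip(_GRAPH_KEYS, vals))


def motif_feature_names(
        montage: Montage,
        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> list[str]:
    """The 108 motif feature names in extraction order."""
    names = [f"{key}({band.name})" for band in bands for key in _GRAPH_KEYS]
    names += [f"PE({band.name})" for band in bands]
    names += [f"Dm({a},{b})({band.name})"
              for a, b in montage.pair_list for band in bands]
    return names


def extract_motif_features(
        trial: np.ndarray, fs: float, montage: Montage,
        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
        sync_cfg: SyncConfig = SyncConfig(), lag: int = 1,
        n_null: int = 10, seed: int = 0,
        band_epochs=None) -> pd.Series:
    """All 108 motif-based features for one trial, in stable order.

    Orchestrates motif encoding, permutation entropy, ordinal dissimilarity
    over the montage pairs, motif-synchronization connectivity and the
    network metrics, per band.  ``seed`` controls the small-world null
    ensemble only; everything else is deterministic.
    """
    if band_epochs is None:
        band_epochs = band_decompose(trial, fs, bands)
    values: dict[str, float] = {}
    ss = np.random.SeedSequence(seed)
    band_seeds = ss.generate_state(len(band_epochs))
    pe_vals: dict[str, float] = {}
    dm_vals: dict[str, float] = {}
    for be, bseed in zip(band_epochs, band_seeds):
        codes = encode_motifs(be.data, lag=lag)
        dists = motif_distribution(codes)
        pe_vals[f"PE({be.band.name})"] = float(
            np.mean([permutation_entropy(p) for p in dists]))
        for a, b in montage.pair_list:
            ia, ib = montage.index(a), montage.index(b)
            dm_vals[f"Dm({a},{b})({be.band.name})"] = ordinal_dissimilarity(
                dists[ia], dists[ib])
        Q, q = _sync_matrices(codes, sync_cfg)
        sync = SyncResult(Q=Q, q=q, band=be.band)
        gf = band_graph_features(sync, n_null=n_null, seed=int(bseed) % (2**31))
        values.update({f"{key}({be.band.name})": val
                       for key, val in gf.items()})
    values.update(pe_vals)
    values.update(dm_vals)
    out = pd.Series(values)
    return out.reindex(motif_feature_names(montage, bands))
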