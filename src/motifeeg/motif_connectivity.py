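"""Motif synchronization: delayed-coincidence connectivity between channels.

Two channels are synchronized when the same motif appears in one shortly
after it appeared in the other.  For motif series ``Xm`` and ``Ym`` the
coincidence count

``c(Xm; Ym) = max_tau  #{ i in window : Xm(i) = Ym(i + tau) }``,

with the delay ``tau`` scanned from 0 to ``tau_max``, measures how often
``Ym`` echoes ``Xm``.  The degree of synchronization and its direction are

``Q_xy = max(c_XY, c_YX) / l_m``  (in [0, 1]) and
``q_xy = sign(c_XY - c_YX)``  (+1: flow X->Y, -1: Y->X, 0: no preference),

evaluated on consecutive non-overlapping windows of length ``l_m`` and
aggregated over windows (mean for Q, sign of the summed count difference
for q).  Reference parameters: ``tau_max = 5`` samples, ``l_m = 256``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif_core import N_MOTIFS, encode_motifs
from .signal_io import BandDefinition, BandEpoch

__all__ = ["SyncConfig", "SyncResult", "delayed_coincidence", "pair_sync",
           "build_sync_graph"]


@dataclass(frozen=True)
class SyncConfig:
    """Parameters of the delayed-coincidence scan.

    ``aggregate`` selects how windows are combined into one trial-level Q:
    ``"mean"`` averages window-level Q values (default), ``"pooled"`` sums
    coincidence counts over windows before the max-over-delay.
    """

    tau_max: int = 5
    window: int = 256
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.tau_max < 0:
            raise ValueError("tau_max must be >= 0")
        if self.window <= self.tau_max:
            raise ValueError("window must exceed tau_max")
        if self.aggregate not in ("mean", "pooled"):
            raise ValueError("aggregate must be 'mean' or 'pooled'")


@dataclass(frozen=True)
class SyncResult:
    """Per-band synchronization degree and direction matrices.

    ``Q`` is symmetric with entries in [0, 1] and zero diagonal (self-edges
    are excluded from every downstream graph metric); ``q`` is antisymmetric
    with entries in {-1, 0, 1}.
    """

    Q: np.ndarray
    q: np.ndarray
    band: BandDefinition | None = None


def delayed_coincidence(xm: np.ndarray, ym: np.ndarray, tau: int,
                        start: int = 0, length: int | None = None) -> int:
    """Count positions i in a window with ``xm(i) == ym(i + tau)``.

    The sum runs over the ``length - tau`` positions whose delayed partner
    stays inside the same window.
    """
    xm = np.asarray(xm)
    ym = np.asarray(ym)
    if length is None:
        length = min(xm.size, ym.size) - start
    if tau < 0 or tau >= length:
        raise ValueError("need 0 <= tau < window length")
    if start < 0 or start + length > xm.size or start + length > ym.size:
        raise ValueError("window out of range")
    stop = start + length - tau
    return int(np.count_nonzero(xm[start:stop] == ym[start + tau:start + length]))


def _coincidence_tensor(codes: np.ndarray, start: int, lm: int,
                        tau_max: int) -> np.ndarray:
    """All-pairs coincidence counts for one window.

    ``codes`` is ``(n_ch, T)`` int; returns ``K`` of shape
    ``(tau_max + 1, n_ch, n_ch)`` with
    ``K[tau, i, j] = #{ t < lm - tau : codes[i, start+t] == codes[j, start+t+tau] }``.

    Implemented as one-hot matrix products: coincidences of code ``c`` at
    delay ``tau`` are an inner product of the two indicator series.
    """
    w = codes[:, start:start + lm]
    onehot = np.stack([(w == c) for c in range(1, N_MOTIFS + 1)])  # (6,n,lm)
    onehot = onehot.astype(np.float32)
    n_ch = codes.shape[0]
    K = np.empty((tau_max + 1, n_ch, n_ch), dtype=np.int64)
    for tau in range(tau_max + 1):
        acc = np.zeros((n_ch, n_ch), dtype=np.float32)
        for c in range(N_MOTIFS):
            a = onehot[c, :, : lm - tau]
            b = onehot[c, :, tau:lm]
            acc += a @ b.T
        K[tau] = np.rint(acc).astype(np.int64)
    return K


def _sync_matrices(codes: np.ndarray, cfg: SyncConfig
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Trial-level (Q, q) matrices from per-channel motif code series."""
    n_ch, T = codes.shape
    lm = cfg.window
    n_win = T // lm
    if n_win < 1:
        raise ValueError(
            f"motif series of length {T} shorter than one window ({lm})")
    q_sum = np.zeros((n_ch, n_ch), dtype=np.int64)
    if cfg.aggregate == "pooled":
        pooled = np.zeros((cfg.tau_max + 1, n_ch, n_ch), dtype=np.int64)
        for w in range(n_win):
            pooled += _coincidence_tensor(codes, w * lm, lm, cfg.tau_max)
        c_xy = pooled.max(axis=0)
        q_sum = c_xy - c_xy.T
        Q = np.maximum(c_xy, c_xy.T) / (lm * n_win)
    else:
        Q = np.zeros((n_ch, n_ch))
        for w in range(n_win):
            K = _coincidence_tensor(codes, w * lm, lm, cfg.tau_max)
            c_xy = K.max(axis=0)
            Q += np.maximum(c_xy, c_xy.T) / lm
            q_sum += c_xy - c_xy.T
        Q /= n_win
    q = np.sign(q_sum).astype(np.int8)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(q, 0)
    return Q, q


def pair_sync(xm: np.ndarray, ym: np.ndarray,
              cfg: SyncConfig = SyncConfig()) -> tuple[float, int]:
    """Synchronization degree Q and direction q for one channel pair.

    ``q = +1`` means the motifs of ``x`` tend to reappear in ``y`` (flow
    x -> y), ``-1`` the reverse, ``0`` no net preference.
    """
    xm = np.asarray(xm)
    ym = np.asarray(ym)
    if xm.size != ym.size:
        raise ValueError("motif series must have equal length")
    Q, q = _sync_matrices(np.stack([xm, ym]), cfg)
    return float(Q[0, 1]), int(q[0, 1])


def build_sync_graph(band_epoch: BandEpoch | np.ndarray,
                     cfg: SyncConfig = SyncConfig(),
                     lag: int = 1) -> SyncResult:
    """Motif-synchronization connectivity over all channel pairs.

    Each channel of the band-filtered trial is motif-encoded, then every
    unordered channel pair is scanned for delayed coincidences, giving the
    symmetric degree matrix Q and the antisymmetric direction matrix q.
    """
    if isinstance(band_epoch, BandEpoch):
        data, band = band_epoch.data, band_epoch.band
    else:
        data, band = np.atleast_2d(np.asarray(band_epoch, float)), None
    if data.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    codes = encode_motifs(data, lag=lag)
    Q, q = _sync_matrices(codes, cfg)
    return SyncResult(Q=Q, q=q, band=band)
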