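"""EEG epoch containers, montage definition, band decomposition and file I/O.

The unit of analysis is an :class:`EpochSet`: one subject's collection of
fixed-length multichannel trials together with 9-point valence/arousal
ratings.  Channel labels follow the international 10-20 system and are
normalized to upper case.  Band decomposition uses a zero-phase (forward-
backward) Butterworth filter so that the shape of the waveform -- which the
ordinal-pattern analysis downstream is sensitive to -- is not lag-distorted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as _sps

__all__ = [
    "BandDefinition",
    "BandEpoch",
    "EpochSet",
    "Montage",
    "MontageError",
    "DEFAULT_BANDS",
    "REFERENCE_CHANNELS",
    "REFERENCE_PAIRS",
    "reference_montage",
    "band_decompose",
    "subtract_baseline",
    "load_epochset",
    "save_epochset",
]


class MontageError(ValueError):
    """Channel labels inconsistent with the requested montage."""


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with bounds in Hz."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: need lo < hi, got "
                             f"({self.lo_hz}, {self.hi_hz})")


#: Canonical theta/alpha/beta/gamma bands used throughout.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

#: 32-channel 10-20 layout (Biosemi ordering), upper-cased.
REFERENCE_CHANNELS: tuple[str, ...] = (
    "FP1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "OZ", "PZ",
    "FP2", "AF4", "FZ", "F4", "F8", "FC6", "FC2", "CZ",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: The 12 interhemispheric electrode pairs used for asymmetry-type features.
REFERENCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("FP2", "FP1"), ("F3", "F4"), ("F7", "F8"), ("FC1", "FC2"),
    ("FC5", "FC6"), ("C3", "C4"), ("T7", "T8"), ("CP1", "CP2"),
    ("CP5", "CP6"), ("P3", "P4"), ("P7", "P8"), ("O1", "O2"),
)


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus the list of left/right electrode pairs."""

    channel_names: tuple[str, ...]
    pair_list: tuple[tuple[str, str], ...] = REFERENCE_PAIRS

    def __post_init__(self) -> None:
        names = tuple(n.upper() for n in self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pairs = tuple((a.upper(), b.upper()) for a, b in self.pair_list)
        object.__setattr__(self, "pair_list", pairs)
        if len(set(names)) != len(names):
            raise MontageError("duplicate channel labels")
        known = set(names)
        for a, b in pairs:
            if a not in known or b not in known:
                raise MontageError(f"pair ({a},{b}) not in channel list")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, label: str) -> int:
        try:
            return self.channel_names.index(label.upper())
        except ValueError:
            raise MontageError(f"unknown channel label {label!r}") from None


def reference_montage() -> Montage:
    """The 32-channel montage with the 12 interhemispheric pairs."""
    return Montage(REFERENCE_CHANNELS, REFERENCE_PAIRS)


@dataclass(frozen=True)
class BandEpoch:
    """One trial band-filtered into a single frequency band."""

    band: BandDefinition
    data: np.ndarray  # (channels, samples)


@dataclass
class EpochSet:
    """Per-subject trials, sampling rate and 9-point ratings.

    Parameters
    ----------
    subject_id
        Free-form subject identifier.
    trials
        List of ``(channels, samples)`` float arrays, all of the same shape.
    fs
        Sampling rate in Hz.
    ratings
        ``(n_trials, 2)`` array of valence/arousal ratings on the 9-point
        SAM scale (values in ``[1, 9]``; may be non-integer).
    channel_names
        Ordered 10-20 labels; normalized to upper case.
    baselines
        Optional per-trial prestimulus ``(channels, samples)`` matrices.
    classes
        Optional ``(n_trials, 2)`` hidden binary state per dimension; only
        populated by the synthetic generator (ground truth for recovery
        tests), never read from disk formats by default.
    """

    subject_id: str
    trials: list[np.ndarray]
    fs: float
    ratings: np.ndarray
    channel_names: tuple[str, ...]
    baselines: list[np.ndarray] | None = None
    classes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel_names = tuple(str(n).upper() for n in self.channel_names)
        if not self.trials:
            raise ValueError("EpochSet needs at least one trial")
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        shape = self.trials[0].shape
        for i, t in enumerate(self.trials):
            if t.ndim != 2:
                raise ValueError(f"trial {i} is not a 2-D matrix")
            if t.shape != shape:
                raise ValueError(
                    f"ragged trials: trial {i} has shape {t.shape}, "
                    f"expected {shape}")
        if shape[0] != len(self.channel_names):
            raise MontageError(
                f"{shape[0]} rows but {len(self.channel_names)} channel names")
        if shape[1] < 3:
            raise ValueError("trials need at least 3 samples")
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.ratings.shape != (len(self.trials), 2):
            raise ValueError("ratings must be (n_trials, 2)")
        if np.any(self.ratings < 1) or np.any(self.ratings > 9):
            raise ValueError("ratings must lie in [1, 9]")
        if self.baselines is not None:
            self.baselines = [np.asarray(b, dtype=float)
                              for b in self.baselines]
            for b in self.baselines:
                if b.shape[0] != shape[0]:
                    raise ValueError("baseline channel count mismatch")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0]


def subtract_baseline(trial: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Remove the per-channel mean of the prestimulus baseline from a trial."""
    trial = np.asarray(trial, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if trial.shape[0] != baseline.shape[0]:
        raise ValueError(
            f"channel mismatch: trial has {trial.shape[0]} channels, "
            f"baseline has {baseline.shape[0]}")
    return trial - baseline.mean(axis=1, keepdims=True)


def band_decompose(trial: np.ndarray, fs: float,
                   bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                   order: int = 4) -> list[BandEpoch]:
    """Zero-phase Butterworth band-pass decomposition of one trial.

    Each band is filtered forward-backward (``sosfiltfilt``) with odd
    reflection padding so startup transients do not corrupt the ordinal
    patterns at trial edges.  Output shapes equal the input shape.
    """
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    out = []
    for band in bands:
        if fs <= 2 * band.hi_hz:
            raise ValueError(
                f"band {band.name} upper edge {band.hi_hz} Hz exceeds "
                f"Nyquist for fs={fs}")
        sos = _sps.butter(order, [band.lo_hz, band.hi_hz],
                          btype="bandpass", fs=fs, output="sos")
        filtered = _sps.sosfiltfilt(sos, trial, axis=-1)
        out.append(BandEpoch(band=band, data=np.ascontiguousarray(filtered)))
    return out


# ---------------------------------------------------------------------------
# File formats.  Two plain dialects are supported: a single HDF5 container
# and a directory of per-trial CSV matrices with a JSON sidecar.  DEAP's own
# container is not parsed (convert externally).
# ---------------------------------------------------------------------------

def save_epochset(es: EpochSet, path: str | Path,
                  format_tag: str = "hdf5") -> Path:
    """Write an :class:`EpochSet`; round-trips float64 bit-exactly."""
    path = Path(path)
    if format_tag == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=np.stack(es.trials))
            f.create_dataset("ratings", data=es.ratings)
            if es.baselines is not None:
                f.create_dataset("baseline", data=np.stack(es.baselines))
            if es.classes is not None:
                f.create_dataset("classes", data=np.asarray(es.classes))
            f.attrs["fs"] = es.fs
            f.attrs["subject_id"] = es.subject_id
            f.attrs["channel_names"] = list(es.channel_names)
        return path
    if format_tag == "csvdir":
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "subject_id": es.subject_id,
            "fs": es.fs,
            "channel_names": list(es.channel_names),
            "ratings": es.ratings.tolist(),
            "n_trials": es.n_trials,
        }
        (path / "epochset.json").write_text(json.dumps(meta, indent=1))
        for i, t in enumerate(es.trials):
            np.savetxt(path / f"trial_{i:03d}.csv", t, delimiter=",",
                       fmt="%.17g")
        return path
    raise ValueError(f"unknown format {format_tag!r}")


def load_epochset(path: str | Path, format_tag: str | None = None,
                  montage: Montage | None = None) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`save_epochset`.

    ``format_tag`` is inferred from the path when omitted (directory ->
    ``csvdir``, file -> ``hdf5``).  If a montage is given, the stored channel
    labels must match it exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_tag is None:
        format_tag = "csvdir" if path.is_dir() else "hdf5"
    if format_tag == "hdf5":
        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"])
            ratings = np.asarray(f["ratings"])
            baselines = ([b for b in np.asarray(f["baseline"])]
                         if "baseline" in f else None)
            classes = np.asarray(f["classes"]) if "classes" in f else None
            fs = float(f.attrs["fs"])
            subject = str(f.attrs["subject_id"])
            names = tuple(str(n) for n in f.attrs["channel_names"])
    elif format_tag == "csvdir":
        meta = json.loads((path / "epochset.json").read_text())
        names = tuple(meta["channel_names"])
        fs = float(meta["fs"])
        subject = str(meta["subject_id"])
        ratings = np.asarray(meta["ratings"], dtype=float)
        data = np.stack([
            np.loadtxt(path / f"trial_{i:03d}.csv", delimiter=",", ndmin=2)
            for i in range(int(meta["n_trials"]))])
        baselines = None
        classes = None
    else:
        raise ValueError(f"unknown format {format_tag!r}")
    es = EpochSet(subject_id=subject, trials=list(data), fs=fs,
                  ratings=ratings, channel_names=names,
                  baselines=baselines, classes=classes)
    if montage is not None and es.channel_names != montage.channel_names:
        raise MontageError(
            "stored channel labels do not match the requested montage")
    return es
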