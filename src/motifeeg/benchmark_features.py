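"""Spectrum-based benchmark features: band powers, ratios, entropy, asymmetry.

The benchmark set has exactly 58 features per trial:

* 4 spectral band powers (theta/alpha/beta/gamma, averaged over electrodes),
* 5 band-power ratios (gamma/beta, beta/theta, alpha/theta,
  (alpha+beta)/gamma, (gamma+beta)/theta; computed per electrode, then
  averaged),
* 1 Shannon entropy of the normalized band-power distribution,
* 48 asymmetry indices (12 interhemispheric electrode pairs x 4 bands),
  AI = (P_a - P_b) / (P_a + P_b) in [-1, 1].

Band power is the time-domain mean square of the band-filtered signal; the
band-pass decomposition already isolates the band, so this estimator is
parameter-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signal_io import (BandDefinition, BandEpoch, DEFAULT_BANDS, Montage,
                        band_decompose)

__all__ = [
    "band_power",
    "band_power_table",
    "band_ratios",
    "shannon_entropy",
    "asymmetry_index",
    "benchmark_feature_names",
    "extract_benchmark_features",
    "RATIO_NAMES",
]

#: The five ratios, as (name, numerator bands, denominator bands).
RATIO_DEFS: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("gamma/beta", ("gamma",), ("beta",)),
    ("beta/theta", ("beta",), ("theta",)),
    ("alpha/theta", ("alpha",), ("theta",)),
    ("(alpha+beta)/gamma", ("alpha", "beta"), ("gamma",)),
    ("(gamma+beta)/theta", ("gamma", "beta"), ("theta",)),
)
RATIO_NAMES = tuple(name for name, _, _ in RATIO_DEFS)


def band_power(band_epoch: BandEpoch | np.ndarray) -> np.ndarray:
    """Per-channel power = mean of squared samples of the filtered signal."""
    data = band_epoch.data if isinstance(band_epoch, BandEpoch) else band_epoch
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[-1] == 0:
        raise ValueError("empty signal")
    return (data ** 2).mean(axis=-1)


def band_power_table(band_epochs: list[BandEpoch],
                     channel_names: tuple[str, ...]) -> pd.DataFrame:
    """Channels x bands table of nonnegative band powers."""
    cols = {be.band.name: band_power(be) for be in band_epochs}
    return pd.DataFrame(cols, index=list(channel_names))


def band_ratios(powers: pd.DataFrame) -> pd.Series:
    """The five band-power ratios, per electrode then averaged."""
    if (powers <= 0).any().any():
        bad = powers.stack().idxmin()
        raise ValueError(f"nonpositive band power at (channel, band)={bad}")
    out = {}
    for name, num, den in RATIO_DEFS:
        per_electrode = (powers[list(num)].sum(axis=1)
                         / powers[list(den)].sum(axis=1))
        out[name] = float(per_electrode.mean())
    return pd.Series(out)


def shannon_entropy(powers: pd.DataFrame) -> float:
    """Entropy (natural log) of the electrode-averaged band-power fractions.

    The four electrode-averaged band powers are normalized to sum to one;
    ``0 * log 0 := 0``.  Range [0, ln 4], maximal for equal band powers.
    """
    mean_p = np.asarray(powers.mean(axis=0), dtype=float)
    total = mean_p.sum()
    if total <= 0:
        raise ValueError("all band powers are zero")
    p = mean_p / total
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())


def asymmetry_index(powers: pd.DataFrame, montage: Montage) -> pd.Series:
    """48 asymmetry indices: AI = (P_a - P_b)/(P_a + P_b) per pair and band.

    Output order is deterministic: pairs in montage order (outer), bands in
    table column order (inner).
    """
    out = {}
    for a, b in montage.pair_list:
        for band in powers.columns:
            pa = float(powers.at[a, band])
            pb = float(powers.at[b, band])
            if pa + pb == 0:
                raise ValueError(
                    f"zero total power for pair ({a},{b}) band {band}")
            out[f"AI({a},{b})({band})"] = (pa - pb) / (pa + pb)
    return pd.Series(out)


def benchmark_feature_names(
        montage: Montage,
        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> list[str]:
    """The 58 benchmark feature names in extraction order."""
    names = [f"power({b.name})" for b in bands]
    names += [f"ratio({r})" for r in RATIO_NAMES]
    names.append("SE")
    names += [f"AI({a},{b})({band.name})"
              for a, b in montage.pair_list for band in bands]
    return names


def extract_benchmark_features(
        trial: np.ndarray, fs: float, montage: Montage,
        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
        band_epochs: list[BandEpoch] | None = None) -> pd.Series:
    """All 58 benchmark features for one trial, in stable order.

    ``band_epochs`` may be passed to reuse an existing decomposition.
    """
    if band_epochs is None:
        band_epochs = band_decompose(trial, fs, bands)
    powers = band_power_table(band_epochs, montage.channel_names)
    values = {f"power({b})": float(powers[b].mean()) for b in powers.columns}
    ratios = band_ratios(powers)
    values.update({f"ratio({k})": v for k, v in ratios.items()})
    values["SE"] = shannon_entropy(powers)
    ai = asymmetry_index(powers, montage)
    values.update(ai.to_dict())
    out = pd.Series(values)
    return out.reindex(benchmark_feature_names(montage, bands))
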