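"""Synthetic multichannel EEG with planted affect-dependent structure.

The generator emulates the layout of a preprocessed affective-EEG study:
32 named 10-20 channels at 128 Hz, 40 trials per subject, 9-point
valence/arousal ratings with per-subject bias.  Signals are superpositions
of band-limited Gaussian-noise carriers in the theta/alpha/beta/gamma
bands (filtered noise, not pure tones, so ordinal-pattern distributions
stay non-degenerate).  Three class-dependent effects can be planted, each
targeting one family of features:

* ``asym_shift`` -- an interhemispheric alpha desynchronization on the 12
  montage pairs: the suppressed (right) side's alpha carrier is attenuated
  (targets the asymmetry index) and broadened from its 9-11 Hz rhythm to
  the full analysis band, while the gamma carrier's peak frequency
  lateralizes (lower sub-band left, upper right; targets ordinal
  dissimilarity, which is amplitude-invariant and can only respond to
  shape changes),
* ``ratio_shift`` -- a multiplicative beta-band gain (targets band-power
  ratios involving beta),
* ``coupling`` -- unidirectional lagged alpha-band coupling
  ``y(t) = g * x(t - d) + noise`` on designated channel pairs (targets
  motif-synchronization degree Q and direction q).

Each trial carries a hidden binary class per dimension; ratings are drawn
from class-shifted distributions plus a per-subject bias offset, so
individualized rating thresholds differ across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _sps

from .signal_io import (DEFAULT_BANDS, EpochSet, Montage, reference_montage)

__all__ = ["SimConfig", "simulate_epochset", "simulate_null_epochset"]


@dataclass(frozen=True)
class SimConfig:
    """Study-layout and effect-size parameters for the generator.

    Defaults give 4 subjects x 40 trials of 12 s at 128 Hz with moderate
    planted effects; set ``duration_s=60`` and ``n_subjects=32`` for a
    full-scale layout.
    """

    n_subjects: int = 4
    n_trials: int = 40
    fs: float = 128.0
    duration_s: float = 12.0
    seed: int = 0
    #: interhemispheric alpha log-power shift (high class), in log units
    asym_shift: float = 0.5
    #: multiplicative beta gain for the high class
    ratio_shift: float = 1.5
    #: lagged-coupling gain (0 disables) and delay in samples
    coupling_gain: float = 0.8
    coupling_delay: int = 2
    #: channel pairs carrying the lagged coupling (source, target)
    coupling_pairs: tuple[tuple[str, str], ...] = (("F3", "F4"),
                                                   ("P3", "P4"))
    #: spread of the per-subject rating bias (9-point units)
    rating_bias_sd: float = 1.0
    #: baseline prestimulus length in seconds (0 disables)
    baseline_s: float = 3.0

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


#: relative carrier amplitudes per band (alpha-dominant resting-like mix)
_BAND_GAINS = {"theta": 1.0, "alpha": 1.3, "beta": 0.7, "gamma": 0.4}
#: broadband measurement noise relative to carrier scale
_NOISE_SD = 0.3


def _band_noise(rng: np.random.Generator, n_ch: int, n_s: int,
                lo: float, hi: float, fs: float) -> np.ndarray:
    """Band-limited Gaussian noise, unit variance per channel."""
    pad = int(fs)  # discard filter startup
    white = rng.standard_normal((n_ch, n_s + 2 * pad))
    sos = _sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = _sps.sosfilt(sos, white, axis=-1)[:, pad:pad + n_s]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _trial_signal(rng: np.random.Generator, cfg: SimConfig, montage: Montage,
                  cls: int, n_s: int) -> np.ndarray:
    n_ch = montage.n_channels
    left = [montage.index(a) for a, _ in montage.pair_list]
    right = [montage.index(b) for _, b in montage.pair_list]
    data = np.zeros((n_ch, n_s))
    for band in DEFAULT_BANDS:
        if band.name == "alpha":
            # rhythmic alpha is narrowband (9-11 Hz) within the 8-13 Hz
            # analysis band; desynchronized alpha (below) is broadband
            carrier = _band_noise(rng, n_ch, n_s, 9.0, 11.0, cfg.fs)
        else:
            carrier = _band_noise(rng, n_ch, n_s, band.lo_hz, band.hi_hz,
                                  cfg.fs)
        gain = np.full(n_ch, _BAND_GAINS[band.name])
        if band.name == "beta" and cls == 1:
            gain *= cfg.ratio_shift
        if band.name == "alpha" and cls == 1 and cfg.asym_shift != 0:
            # event-related desynchronization on the right-hemisphere pair
            # members: alpha gets weaker (power asymmetry) AND less
            # rhythmic (ordinal asymmetry) on the suppressed side
            gain[left] *= np.exp(cfg.asym_shift / 2)
            gain[right] *= np.exp(-cfg.asym_shift / 2)
            mix = min(1.0, cfg.asym_shift)
            broad = _band_noise(rng, len(right), n_s, band.lo_hz,
                                band.hi_hz, cfg.fs)
            carrier[right] = (np.sqrt(1.0 - mix) * carrier[right]
                              + np.sqrt(mix) * broad)
        if band.name == "gamma" and cls == 1 and cfg.asym_shift != 0:
            # hemispheric gamma peak-frequency lateralization: the gamma
            # carrier concentrates in the lower sub-band on the left and
            # the upper sub-band on the right.  Power within 30-45 Hz is
            # unchanged, but the lag-1 ordinal-pattern distributions of
            # the two hemispheres separate (targets the D_m features)
            mix = min(1.0, cfg.asym_shift)
            lo_g = _band_noise(rng, len(left), n_s, 30.0, 36.0, cfg.fs)
            hi_g = _band_noise(rng, len(right), n_s, 39.0, 45.0, cfg.fs)
            carrier[left] = (np.sqrt(1.0 - mix) * carrier[left]
                             + np.sqrt(mix) * lo_g)
            carrier[right] = (np.sqrt(1.0 - mix) * carrier[right]
                              + np.sqrt(mix) * hi_g)
        if band.name == "alpha" and cls == 1 and cfg.coupling_gain > 0:
            d = cfg.coupling_delay
            for src_lbl, dst_lbl in cfg.coupling_pairs:
                src, dst = montage.index(src_lbl), montage.index(dst_lbl)
                lagged = np.roll(carrier[src], d)
                lagged[:d] = carrier[dst][:d]
                carrier[dst] = (cfg.coupling_gain * lagged
                                + np.sqrt(max(0.0, 1 - cfg.coupling_gain ** 2))
                                * carrier[dst])
        data += gain[:, None] * carrier
    data += _NOISE_SD * rng.standard_normal((n_ch, n_s))
    return data


def _ratings(rng: np.random.Generator, classes: np.ndarray,
             bias: float) -> np.ndarray:
    """Class-shifted 9-point ratings: low ~ N(3.5, 1), high ~ N(6.5, 1)."""
    mu = np.where(classes == 1, 6.5, 3.5) + bias
    return np.clip(mu + rng.standard_normal(classes.shape), 1.0, 9.0)


def simulate_epochset(cfg: SimConfig = SimConfig(),
                      montage: Montage | None = None) -> list[EpochSet]:
    """Generate one labeled :class:`EpochSet` per subject.

    The hidden binary class per trial drives both dimensions: the planted
    signal effects follow the valence class; the arousal class is drawn
    independently (its ratings are class-shifted but its signal carries no
    planted effect), so arousal behaves as a harder dimension.
    The result is byte-reproducible from ``cfg.seed``.
    """
    montage = montage or reference_montage()
    ss = np.random.SeedSequence(cfg.seed)
    out = []
    for subj, sseed in enumerate(ss.spawn(cfg.n_subjects)):
        rng = np.random.default_rng(sseed)
        bias = rng.normal(0.0, cfg.rating_bias_sd)
        classes = np.column_stack([
            rng.permutation(np.arange(cfg.n_trials) % 2),   # valence
            rng.permutation(np.arange(cfg.n_trials) % 2)])  # arousal
        trials, baselines = [], []
        n_base = int(round(cfg.fs * cfg.baseline_s))
        for t in range(cfg.n_trials):
            trials.append(_trial_signal(rng, cfg, montage,
                                        int(classes[t, 0]), cfg.n_samples))
            if n_base >= 3:
                baselines.append(_trial_signal(rng, cfg, montage, 0, n_base))
        ratings = np.column_stack([
            _ratings(rng, classes[:, 0], bias),
            _ratings(rng, classes[:, 1], bias)])
        out.append(EpochSet(
            subject_id=f"sim{subj:02d}", trials=trials, fs=cfg.fs,
            ratings=ratings, channel_names=montage.channel_names,
            baselines=baselines or None, classes=classes))
    return out


def simulate_null_epochset(cfg: SimConfig = SimConfig(),
                           montage: Montage | None = None) -> list[EpochSet]:
    """Signals without planted effects; labels independent of content.

    Rating classes are still drawn (with per-subject bias, so thresholds
    vary across subjects) but every trial's signal is generated from the
    null (class 0) condition.
    """
    null_cfg = replace(cfg, asym_shift=0.0, ratio_shift=1.0,
                       coupling_gain=0.0)
    return simulate_epochset(null_cfg, montage=montage)
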