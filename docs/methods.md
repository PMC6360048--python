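# Methods

This note documents the models and procedures implemented by `motifeeg`,
the parameter choices that matter, the design decisions taken where the
problem was genuinely open, and what the synthetic-data tests do and do
not demonstrate.

## Signal model and preprocessing

The unit of analysis is a per-subject `EpochSet`: fixed-length
multichannel trials (channels × samples) at a common sampling rate, with
9-point valence/arousal ratings per trial and an optional prestimulus
baseline whose per-channel mean is subtracted before feature extraction.
The reference layout is 32 channels of the international 10–20 system at
128 Hz, matching widely used preprocessed affective-EEG corpora; artifact
removal, re-referencing and downsampling are assumed done upstream.

Band decomposition into θ (4–8), α (8–13), β (13–30) and γ (30–45 Hz)
uses a 4th-order Butterworth band-pass applied forward–backward
(`scipy.signal.sosfiltfilt`, odd reflection padding). Zero-phase
filtering is deliberate: the downstream ordinal encoding is
shape-sensitive, and a causal filter's frequency-dependent group delay
would distort motif statistics. Band edges above Nyquist are rejected.

## Ordinal (motif) statistics

**Encoding.** Degree `n = 3`, lag `λ = 1` (both frozen as reference
parameters; `λ` is exposed as a knob). Each triple maps to one of six
codes via three pairwise comparisons. Ties are resolved by treating the
earlier-indexed sample as smaller, which makes the map total and
deterministic; exact ties have measure zero in continuous EEG. The
encoder is verified against an independent rank-ordering oracle on all
six orderings and 10⁴ random triples.

**Permutation entropy** is the natural-log Shannon entropy of the
six-bin motif distribution, with `0·log 0 := 0`; range `[0, ln 6]`. It is
computed per channel over the full epoch (no sub-windowing — the
minimal-assumption reading) and averaged over electrodes into one feature
per band, mirroring how the spectral power features are aggregated.

**Ordinal dissimilarity** between two channels is
`D_m = (n!/(n!−1))·Σ_j (p_x(j) − p_y(j))²`, i.e. a 6/5-scaled squared
Euclidean distance with range `[0, 2.4]`. The squared (no square root)
form is the reference form; a `root=True` switch exposes the metric
variant, which changes only the scale, never the ranking. `D_m` is
computed for the 12 interhemispheric pairs per band.

Note an identifiability point that matters for interpretation: ordinal
statistics are invariant to any strictly monotone amplitude transform.
Within a band-filtered signal they respond only to the *in-band spectral
shape*, never to gain. A pure interhemispheric power asymmetry therefore
cannot move `D_m`; only accompanying changes in rhythmicity or peak
frequency can (see the generator section below).

## Motif synchronization and brain graphs

For each channel pair, coincidences `x_m(i) = y_m(i+τ)` are counted for
delays `τ = 0..τ_max` inside consecutive non-overlapping windows of
`l_m` samples (`τ_max = 5`, `l_m = 256` reference; for delay τ the count
runs over the `l_m − τ` positions whose partner stays in the window,
while the normalization stays `l_m`). Per window,
`Q = max(c_XY, c_YX)/l_m`; the trial-level `Q` is the arithmetic mean
over windows (a pooled-counts aggregation is available as a config
option), and the direction `q = sign(Σ_w (c_XY − c_YX))` pools the count
differences over windows — majority evidence, avoiding ties that
per-window sign voting would produce. A trailing partial window is
discarded. `Q ∈ [0,1]` elementwise and `q` is exactly antisymmetric; the
implementation is vectorized over all pairs (one-hot inner products) and
checked against a naive per-pair reimplementation.

Electrodes are nodes; `Q` is the weighted adjacency. The unweighted graph
keeps edges strictly above the mean off-diagonal weight (with a relative
epsilon absorbing summation round-off so constant-weight graphs threshold
to the empty graph). Per band, 14 network-level features:

- mean degree `k` and strength `kw`;
- mean clustering `C` (binary, `2e_i/(k_i(k_i−1))`, zero for `k_i < 2`)
  and `Cw` (geometric-mean triangle intensity
  `t_i = ½Σ_{j,h}(w_ij w_jh w_hi)^{1/3}`, normalized by
  `kw_i(kw_i−1)`, zero when that normalization is non-positive or the
  node has fewer than two neighbours). The factor-2 normalization is the
  standard convention under which complete graphs have clustering 1 and
  the weighted variant reduces to the binary one at unit weights;
- transitivity `Tr = Σ_i 2e_i / Σ_i k_i(k_i−1)` and its weighted mirror
  with triangle intensities and strengths (0 when no connected triplets);
- characteristic path length `L` and global efficiency `G`, unweighted
  (hop counts) and weighted with edge length `1/w` — the standard
  similarity-to-distance map for synchronization weights. `L` averages
  over connected ordered pairs only; disconnected pairs contribute 0 to
  `G` via `1/∞`, keeping both finite;
- small-world ratios `L_s = L/L_rand`, `C_s = C/C_rand`,
  `S = C_s/L_s`, computed on the thresholded binary graph against
  `n_null = 10` Maslov–Sneppen degree-preserving rewirings (10·m
  successful double-edge swaps per null, seeded deterministically per
  trial and band from the master seed). Graphs too sparse to rewire fall
  back to a density-matched random null with a warning; a ratio whose
  null mean is zero is reported as 0;
- direction of flow `DoF = Σ_{i<j} q_ij` over the upper triangle — the
  full ordered-pair sum of an antisymmetric matrix is identically zero,
  so the half-matrix sum is the only non-degenerate reading.

Feature count: (5 weighted + 5 unweighted + 3 small-world + 1 DoF) × 4
bands = 56, plus 4 PE and 48 `D_m`, giving the 108-feature motif group.

## Benchmark spectrum features (58)

Band power is the time-domain mean square of the band-filtered signal —
parameter-free given the decomposition; equivalence with a PSD-integral
estimate on stationary signals is a test property, not a requirement.
The five ratios (γ/β, β/θ, α/θ, (α+β)/γ, (γ+β)/θ) are computed per
electrode and averaged over electrodes (the per-electrode ratios are
scale-invariant, so averaging them preserves that invariance). Shannon
entropy uses the electrode-averaged band powers normalized to sum to one
(natural log, range `[0, ln 4]`). The asymmetry index is the normalized
difference `AI = (P_a − P_b)/(P_a + P_b)` — bounded in `[−1, 1]` and
antisymmetric under pair swap; difference and log-ratio forms are common
alternatives but unbounded or scale-dependent.

## Labels, selection, classification, fusion

**Individualized thresholds.** Per subject and dimension, candidate
cutoffs are the integers 1..9 plus midpoints between consecutive distinct
observed ratings (midpoints matter because SAM ratings can be
continuous; an integer-only mode is available). The cutoff minimizing
`|#high − #low|` wins; ties break toward the scale midpoint 5, then the
smaller value. "High" means rating strictly above the cutoff.

**Selection.** ANOVA ranking (one-way F-test, ascending p, name-ordered
ties, zero-variance features demoted to p = 1 with a warning); mRMR
greedy forward selection with the difference criterion, mutual
information estimated on 5-bin equal-frequency discretizations; RFE with
a linear-kernel SVM refit each round on standardized features, dropping
the smallest squared coefficient (the evaluation classifier's radial
kernel has no per-feature weights, so the linear margin is the standard
importance proxy). All selectors operate on a fixed 90 % development
split (seed 0); the grid search crosses selector × number-of-features,
scores each cell with the repeated-split protocol inside the development
data, and breaks ties toward fewer features, then selector order.
Inside the grid, RFE is run once down to a single survivor; because
elimination is one feature per round, prefixes of that ordering equal
separate RFE-to-`nof` runs.

**Classification.** RBF-SVM with `C = 1`, `γ = 0.01`, deliberately
without hyperparameter optimization. Evaluation: 100 random 90/10
splits derived from a master seed by iteration index; standardization
uses training statistics only; splits whose test half misses a class are
resampled. Balanced accuracy is the figure of merit (chance 0.5 at any
prevalence). Significance versus chance is a one-sample t-test of the
per-split BACC values against the empirical mean of a random-voting
classifier; that chance mean should be estimated with several hundred
voting iterations — a noisy chance estimate inflates the type-I error
(the calibration test covers this). Class probabilities for fusion come
from Platt-scaled SVM scores.

**Fusion.** Feature fusion concatenates the groups' tables before
selection. Score fusion implements
`p₀ = Σ_i α_i p_i t_i` with `t_i = F_i/Σ_j α_j F_j` (F_i = development
F1 of group i), which self-normalizes: fused probabilities sum to one
for any valid weights. The weight simplex is searched exhaustively in
steps of 0.1, maximizing development BACC (development, not holdout, to
avoid test leakage), ties breaking toward uniform weights.
Output-associative fusion trains a second-stage classifier of the same
family per dimension on the stage-1 class probabilities of all groups
for *both* dimensions (probabilities, not hard decisions — they carry
confidence), letting correlated valence/arousal labels inform each
other.

## Synthetic-data generator

The generator emulates the *layout and statistical structure* of a
preprocessed affective-EEG study, not its physiology: no dipole/forward
modeling, no 1/f spectrum, no artifacts. Carriers are band-limited
Gaussian noise (filtered white noise, unit variance per channel) rather
than pure tones — pure tones make ordinal patterns periodic and
uninformative. Relative carrier amplitudes θ:α:β:γ = 1.0:1.3:0.7:0.4
give an α-dominant resting-like mix; broadband white measurement noise
(SD 0.3) is added.

Defaults: 4 subjects × 40 trials of 12 s at 128 Hz (full-scale layouts —
32 subjects, 60 s — are config options; the shorter default keeps the
planted-recovery tests at desk scale). Each trial carries a hidden
binary class per dimension; ratings are drawn from class-shifted normals
(3.5 vs 6.5, SD 1) plus a per-subject bias (SD 1.0), clipped to [1, 9],
so individualized thresholds genuinely differ across subjects.

Planted effects (high class), each targeting one feature family:

- **Interhemispheric asymmetry** (`asym_shift = 0.5` log units): the
  alpha carrier is attenuated by `e^(−shift/2)` on the right member of
  each of the 12 pairs and amplified on the left (targets AI), and the
  suppressed side's 9–11 Hz alpha rhythm is partially broadened to the
  full 8–13 Hz band — emulating event-related desynchronization, where
  suppressed alpha is weaker *and* less rhythmic. Because ordinal
  features are amplitude-invariant (see above), the generator also
  lateralizes the gamma carrier's peak frequency (lower 30–36 Hz
  sub-band left, upper 39–45 Hz right, power-neutral within the band);
  this is the component the `D_m` features detect, and it is the reason
  the gamma band at 128 Hz is where ordinal asymmetry is visible at all:
  lag-1 triples span ~16 ms and cannot resolve within-band shape
  differences of a ~10 Hz rhythm, but they resolve a 3–4-sample gamma
  cycle easily.
- **Band-ratio shift** (`ratio_shift = 1.5`): multiplicative β gain,
  targeting the β-involving power ratios.
- **Lagged coupling** (gain 0.8, delay 2 samples ≤ τ_max, pairs
  F3→F4 and P3→P4): the target's alpha carrier becomes
  `g·x(t−d) + √(1−g²)·noise`, planting a directed synchronization that
  `Q` and `q` recover.

The null generator zeroes all three effects, so labels (still drawn with
subject bias) are independent of signal content.

**What passing tests show — and don't.** Recovery tests demonstrate that
each feature family detects the statistical structure it is designed
for, at realistic effect sizes, and that the evaluation protocol is
calibrated (random voting at BACC 0.50; type-I error ≈ 5 %). They do not
certify performance on real EEG, where effect sizes are smaller,
non-stationary and confounded; published accuracies on license-restricted
corpora are explicitly out of scope.

## Numerical choices and degenerate inputs

- Thresholding uses a relative epsilon (`1e−12`) so equal weights give
  an empty graph under the strict-inequality rule.
- Motif-series length must cover at least one synchronization window;
  shorter inputs raise shape errors rather than returning NaN.
- All-identical ratings yield threshold 5 with a warning (one class
  empty); zero-variance BACC samples degenerate the t-test to an exact
  mean comparison.
- All randomness (splits, null ensembles, simulations) flows from
  explicit seeds; per-trial and per-band seeds are derived via
  `numpy.random.SeedSequence` so stages are independently reproducible.

## Problem sizes used by the shipped checks

Planted-recovery checks run at 4 subjects × 40 trials × 12 s (the
generator default); the chance-calibration and type-I checks use
label-level simulation (200 repetitions × 20 reduced splits against a
400-iteration chance estimate); oracle equivalences use ≤10-node graphs
and 10⁴ random triples. These sizes were chosen to make the statistical
assertions stable at fixed seeds while staying desk-scale.

## Known limitations

- The gamma-band lateralization is the only planted effect ordinal
  dissimilarity can see; this is a property of ordinal statistics at
  `λ = 1`/128 Hz, not of the implementation.
- The grid search re-uses the single fixed development split rather than
  nesting selection inside every evaluation split; this mirrors the
  reference protocol but carries the usual mild optimism. The
  planted-recovery tests use fully nested per-split selection instead.
- Weighted clustering normalized by strength can exceed 1 on small
  dense graphs with sub-unit weights; it is a relative, not absolute,
  measure.
- `simulate_epochset` returns one `EpochSet` per subject (a list); the
  multi-subject study is the natural unit for the labeling and
  evaluation protocol.
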