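# Methods

This note documents what each stage of `whistlechain` computes, every tunable
parameter (units, default, rationale), what the synthetic generator does and
does not emulate, the numerical choices that matter, and known limitations.

## 1. Input representation

A whistle is a pair of uniformly sampled tracks: pitch (semitones,
`st = 12·log2(f / 100 Hz)`; NaN where unvoiced) and intensity (dB-like,
arbitrary scale). Track CSVs carry `time_s,value` rows; the sample rate is
inferred from the time step (tolerance 1e-6 s) and non-uniform steps are
rejected with the offending row named. Praat short-format PitchTier files
are supported via `read_pitchtier` (Hz → semitones on read). A dataset is a
`manifest.csv` mapping `(chain_id, generation, whistle_id)` to track files;
generations within a chain must be strictly increasing and whistle ids
unique. The slide whistles' physical range (450–2500 Hz) is recorded as
constants and used by the generator, not enforced on input data.

## 2. Segmentation and pitch targets

`SegmentationConfig`:

| parameter | unit | default | why |
|---|---|---|---|
| `silence_threshold` | intensity | None → 10 % of track max | separates whistle sound from breath pauses without per-recording calibration |
| `min_gap` | s | 0.02 | gaps shorter than a glottal flutter are closed, not treated as boundaries |
| `min_segment` | s | 0.05 | discards clicks too short to carry a pitch movement |
| `max_pitch_gap` | samples | 5 | unvoiced runs up to 10 ms are interpolated; longer ones split the segment |
| `smooth_window` | samples | 5 | centred moving average before target detection; suppresses tracker jitter |
| `min_prominence` | st | 0.5 | turning points must rise/fall at least this much on both sides to count as targets |

Segments are maximal intensity runs above threshold (half-open sample
intervals). Targets are the segment's first and last samples plus
prominence-filtered interior extrema of the smoothed contour
(plateau-aware; peaks and valleys always alternate). The 0.5-st prominence
is half the 1-st "slide threshold" used for contours, so targets are
detected more liberally than contour direction changes.

## 3. The seven measures

- **Discreteness (MU1)**. All target values of a (chain, generation) set are
  pooled. (a) Chi-square against a uniform histogram over the occupied range
  with `bin_width` = 1 st (one equal-tempered semitone; fine enough to
  resolve scale steps, coarse enough that bins are populated). (b) A
  one-dimensional Gaussian mixture with free means/variances is fitted for
  k = 1..`k_max` (default 10, above the 7-element universal so the check can
  fail); the BIC-minimal k is recorded and averaged over `n_runs` = 100
  random restarts. Restarts are seeded k-means++ initializations: still
  random, but a bad draw cannot strand EM in a degenerate optimum that would
  let an overfitted k win the BIC comparison (with naive random-from-data
  initialization the selected count exceeded the true k in up to a third of
  runs on well-separated planted data).
- **Few elements (MU2)**. `round(mean component count) ≤ 7`.
- **Contours (MU3)**. Target-to-target moves with |Δ| < `slide_threshold`
  (1 st) are level; the pruned sign sequence maps to horizontal, ascending,
  descending, arched, U-shaped, or undulating (≥ 2 direction changes).
  Reported as per-set label proportions.
- **Intervals (MU4)**. Onset-to-onset intervals are differences between
  consecutive segment onset pitches within a whistle (st). Reported per
  interval, as the set-level proportion ≤ 7.5 st (750 cents), and as the
  interval compression ratio: mean |interval| under `n_shuffles` = 100
  uniform random reorderings of the whistle's onsets divided by the actual
  mean |interval|. Whistles with < 3 segments have ratio 1 by construction;
  identical onsets are flagged degenerate (0/0).
- **Building blocks (MU5)**. Pairwise DDTW over a set's segments, then
  average-linkage agglomerative clustering, merging while the linkage height
  is strictly below `block_threshold` = 0.08 (threshold 0 therefore leaves
  every segment its own block). Entropy of block frequencies in bits
  (`entropy_base` = 2).
- **Chunk strength (MU6)**. All bigram and trigram tokens of the per-whistle
  block sequences (tokens never cross whistle boundaries) are pooled; the
  measure is the mean, over tokens, of each token's type frequency in the
  set. Duplicating a set's sequences doubles it; it is invariant to block
  relabeling.
- **Phrases (MU7)**. Per whistle: segment count, total duration (first
  segment start to last segment end, s), and mean segment duration.

### DDTW numerical choices

Both sequences are linearly resampled to `resample_len` = 25 points
(removes duration as a similarity cue and bounds cost at 25×25 DP tables),
derivatives are estimated with the Keogh–Pazzani stencil
`d_i = ((q_i − q_{i−1}) + (q_{i+1} − q_{i−1})/2)/2` (boundary values copy
their neighbours), local cost is the squared derivative difference, and the
accumulated cost is divided by the optimal path length (ties broken
diagonal → vertical → horizontal). Before resampling, clustering applies a
centred moving average of `ddtw_smooth_window` = 25 track samples (50 ms at
500 Hz) so sample noise does not dominate derivatives. With these choices,
same-shape segments under realistic jitter/noise sit at distances ≲ 0.02
and different shapes ≳ 0.5, so the 0.08 merge threshold separates them with
a wide margin. The DP inner loop is numba-compiled; a pure-Python oracle in
the test suite certifies it to 1e-9.

## 4. Trend model

Each measure is modelled as `value ~ generation + (1 | chain)` fitted by
REML. The implementation profiles the likelihood over λ = τ²/σ² (grid scan
plus bounded scalar minimization, with an explicit λ = 0 boundary check)
using Woodbury identities per group, so it is exact for the
random-intercept structure. Fixed effects get t-tests with Satterthwaite
degrees of freedom, df = 2f²/(gᵀAg), where f is the coefficient's variance,
g its numeric gradient in (σ², τ²), and A the inverse numeric Hessian of
the REML criterion; at the τ² = 0 boundary df falls back to n − p.
Single-chain tables fall back to OLS (flagged `method="ols"`); zero-variance
responses return a degenerate fit. `mean_onset_interval` rows carry a binary
`dataset` column (actual vs. shuffled orderings) and are fitted with the
full `generation * dataset` interaction model. Measures observed in fewer
than `min_generations` = 3 generations are skipped with a warning. The
fitter matches statsmodels `MixedLM` (β, SE, σ², τ²) and R `lmerTest`
(including fractional df and p-values) on fixture data in the test suite.

## 5. Synthetic generator

`GeneratorParams` plants known structure per whistle set:

| parameter | unit | default | meaning |
|---|---|---|---|
| `n_whistles` | — | 12 | whistles per (chain, generation) set |
| `n_pitch_levels` | — | 3 | planted scale size; 0 = continuous pitch (no scale) |
| `level_jitter_sd` | st | 0.5 | per-target deviation from its scale level |
| `n_block_types` | — | 5 | size of the building-block vocabulary |
| `block_reuse_concentration` | — | 1.0 | block type i is drawn ∝ exp(−c·i); 0 = uniform, larger = heavier reuse (lower entropy, higher chunk strength) |
| `contour_mixture` | prob. | mixed | shape distribution of block templates |
| `mean_segment_duration_s` / `mean_gap_duration_s` | s | 0.5 / 0.2 | gamma(shape 4) durations, clamped |
| `segments_per_whistle_mean` | — | 4.0 | 1 + Poisson(mean − 1) segments |
| `onset_interval_scale_st` | st | 4.0 | exponential step scale of the onset random walk (reflected at the feasible range, snapped to scale levels when a scale exists) |
| `pitch_noise_sd` | st | 0.2 | per-sample tracker noise |

Scale levels are equally spaced in the instrument's semitone range minus a
safety margin of `1 + 3·(jitter + noise)` st so no sample can leave the
physical range; parameter validation rejects scales whose spacing is below
3× the jitter (levels would smear together). Block templates are piecewise-
linear realizations of the six contour shapes with excursions of roughly a
whole scale span (discrete mode) or U(8, 14) st (continuous mode) — large
enough that different shapes stay far apart in DDTW space. A `ChainPlan`
interpolates every parameter linearly from a start to an end
parameterization across generations (integers rounded, the contour mixture
blended and renormalized); the `drifting` preset moves 2 → 5 scale levels,
concentration 0.3 → 2.2, and complex → simple contour mixtures, the
qualitative pattern the measures are built to detect. Each (chain,
generation) set receives an independent child seed from
`numpy.random.SeedSequence(seed).spawn`, so everything is reproducible from
one master seed and chains are statistically independent.

**What the generator emulates**: planted pitch scales with jitter, a reusable
block vocabulary with tunable reuse skew, the six contour families, small-
step onset walks, realistic segment/gap durations, tracker noise, and smooth
parameter drift across generations. **What it does not emulate**: human
learning (generations are independent draws from drifting parameters, not
reproductions of the previous generation's output), production constraints
such as breath groups or articulation slides between segments, pitch drift
within a segment beyond its template, amplitude dynamics (intensity is a
flat level per segment), or perceptual asymmetries between participants.
It is a measurement-validation instrument, not a model of cultural
transmission.

## 6. Pipeline and determinism

`measure_dataset` emits a tidy long-format table (one row per set-level
measure, per whistle, per segment, or per interval; columns `chain_id,
generation, whistle_id, item, dataset, measure, unit, value, degenerate`).
Output CSVs carry `# version / # config_hash / # seed` header comments.
Per-set measurement seeds are spawned from the master seed and all derived
integer seeds are taken modulo 2³¹ − 1. Two runs of
simulate → measure → trends with the same master seed are byte-identical
(covered by a test).

## 7. Limitations

- The 0.08 DDTW threshold is meaningful only under this package's exact
  normalization (25-point resampling, squared cost, path-length division,
  50 ms pre-smoothing). Distances from other DTW implementations are not
  comparable.
- The chi-square discreteness statistic depends on bin placement and range;
  it is reported with its df but treated as descriptive, not inferential.
- Chunk strength grows with set size (more whistles → higher type
  frequencies); compare it only across sets of equal design, as the
  transmission-chain layout guarantees.
- The mixed model assumes a single random intercept per chain; random
  slopes and residual autocorrelation across generations are not modelled.
- GMM component counts on few targets are unstable; `k_max` is lowered
  automatically (with a warning) when a set has fewer targets than
  `k_max + 1`.
- Phrase measures take intensity silences as phrase boundaries; if a
  recording concatenates multiple phrases without silence they are measured
  as one.
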