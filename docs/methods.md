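# Methods

This note documents the models implemented in `driftlab`, the parameter
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that matter for
reproducibility.

## Coordinate conventions

Positions are screen pixels, origin top-left, y growing downward. Text
lines are indexed 0-based, top to bottom. A line's position (`line_ys`)
is the **vertical center** of the words on that line — the resting
position of an accurately recorded fixation — not the AOI's top edge.
This choice makes the offset-tolerance of nearest-line snapping symmetric
(attach is exact for any |Δy| < half the line spacing) and matches the
line-midline convention of the classic drift-correction algorithm suites.
Durations are milliseconds, carried as floats.

## Synthetic trial generator

The generator walks the word AOIs in reading order and emits one fixation
per visited word:

- **Landing position**: x = AOI.x + width/3 (slightly left of center, the
  optimal viewing position), y = line center; both axes receive Gaussian
  jitter with SD `jitter_sd_x` = `jitter_sd_y` = 2 px by default. The
  jitter magnitude is deliberately small relative to the default 50 px
  line spacing so that undistorted trials are perfectly recoverable —
  which is exactly what makes them a usable ground truth.
- **Duration**: 100 + (width/15)·40 ms, i.e. proportional to word width.
  With 60 px words this gives 260 ms, a typical reading fixation.
- **Skipping**: a word of c characters is skipped with probability
  clamp(`skip_base` − `skip_decay`·(c−1), 0, `skip_base`), defaults 0.5
  and 0.08 per character: two-character function words are skipped 42% of
  the time, words of seven or more characters never. Character counts
  come from the AOI token when present, otherwise width/`est_char_width`
  (10 px/char). The first word of every line is never skipped, so each
  line receives at least one fixation (several correctors assume
  non-empty lines). The linear-decay form is the package's own
  quantification of the qualitative rule that short words are skipped
  more often.
- **Regressions**: each walk index > 2 independently becomes a regression
  index with probability `regression_probability`; if none is chosen and
  the probability is positive, one eligible index is added. At a
  regression index the walk draws a uniformly random prior index, up to
  10 retries, accepting only targets on a *different* line (between-line
  variant) or the *same* line (within-line variant); on success the walk
  jumps back and re-reads forward. Regression indexes fire once, so
  re-reads do not trigger nested regressions and the walk terminates. In
  the within-line variant a failed draw simply continues the walk; in the
  between-line variant, if a whole walk ends with no executed regression
  while one is possible, the generator re-walks once with a forced
  regression at a uniformly chosen index that has a valid different-line
  prior (target drawn uniformly among valid priors). This guarantees the
  trial actually contains the behavior its condition is named after.

What the generator does *not* emulate: saccade trajectories, blinks,
microsaccades, refixations within a word, duration dependence on
frequency/predictability, or horizontal calibration error. Passing tests
on this data therefore demonstrate correctness of the algorithms'
geometry and contracts, not their ranking on real reading records, where
drift co-occurs with richer behavior.

## Drift distortions

- **noise**: y += N(0, `ynoise`), seeded; applied to all fixations by
  default (an optional boolean mask restricts it to a subset).
- **slope**: y += (x − x₀)/100 · `slope_factor`, x₀ the first fixation's
  x. The divisor 100 (pixels of x per unit factor) is part of the model
  definition.
- **shift**: y += |y − line_ys[0]| / (line_ys[1] − line_ys[0]) ·
  `y_shift_factor`; the distance term uses the input y (not applied
  iteratively). Requires at least two lines.
- **offset**: (x, y) += (`x_offset`, `y_offset`).

All preserve count, order and durations; only offset touches x.

### Suite magnitudes

The 18-trial suite is 6 conditions × 3 levels. Magnitudes are expressed
as fractions of the line spacing L, chosen once to span "clearly
recoverable" through "genuinely ambiguous": noise SD ∈ {0.1, 0.25, 0.4}·L;
slope and shift factors set so the maximum displacement (far edge / last
line) is {0.25, 0.5, 0.75}·L; vertical offset ∈ {0.3, 0.6, 0.9}·L with no
horizontal component. The two regression conditions use regression
probabilities {0.1, 0.2, 0.3} and no distortion; distortion and
regression conditions are disjoint trials. Magnitudes are configurable.

## Correction algorithms

All nine receive the fixation sequence plus the line positions (Warp
receives the full word layout), change only y, and emit y-values that are
members of `line_ys` plus the matching line index.

- **attach**: nearest line per fixation via binary search with a final
  neighbor comparison; exact ties go to the lower line index (a
  deterministic rule matching a stable linear scan, which is also the
  test oracle).
- **chain** (`x_thresh` = 192 px, `y_thresh` = 32 px): consecutive
  fixations chain while |Δx| ≤ x_thresh and |Δy| ≤ y_thresh; each chain
  snaps by its mean y. The threshold defaults follow the established
  Chain lineage and are exposed everywhere.
- **cluster**: k-means (k = number of lines) on y-values, 10 restarts,
  fixed seed; clusters sorted by center and matched to lines in order.
- **merge** (`gradient_thresh` = 0.1, `error_thresh` = 20 px): initial
  split at x-backtracks beyond −192 px or |Δy| > 32 px (reusing the chain
  thresholds); then best-first pair merging — the candidate union's
  least-squares line must satisfy the phase's constraints, and the pair
  with the lowest rms residual merges first — over four phases: both
  constraints, gradient only, error only, unconstrained, stopping at one
  sequence per line. Unions with fewer than two distinct x-positions get
  gradient 0 and rms spread around the mean. If the initial split already
  yields fewer sequences than lines, each snaps to the line nearest its
  mean y; otherwise sequences map to lines in vertical order.
- **regress** (slope ∈ (−0.1, 0.1), offset ∈ ±0.5·L, sd ∈ (1, 20) px):
  lines predict y = line + slope·x + offset with Gaussian spread sd; the
  parameters minimize the negative log-likelihood of each fixation's best
  line. The likelihood is multimodal in the offset (each whole-line shift
  of the assignment is a mode), so the bounded L-BFGS-B refinement runs
  from seven starts on an offset grid and keeps the best optimum;
  deterministic. Fixations then take their most probable line.
- **segment**: the m−1 *most negative* x-displacements are taken as
  return sweeps; line indices increment at each, so assignments are
  non-decreasing. Because "largest saccade" readings differ, the
  alternative (largest |Δx|) is available behind `convention="largest"`;
  most-negative is the default since return sweeps are long leftward
  jumps.
- **split**: 2-means on the x-displacements (fixed seed, 10 restarts);
  the lower-mean cluster marks boundaries; segments snap by mean y.
  Degenerates (all displacements equal) raise.
- **stretch** (scale ∈ (0.9, 1.1), offset ∈ ±0.5·L): minimizes
  Σ|s·yᵢ + o − nearest_line(s·yᵢ + o)| with bounded Powell search from
  (1, 0) — the objective is piecewise-linear with flat regions, so a
  derivative-free method is used. The returned cost is never worse than
  the identity transform's.
- **warp**: exact DTW (cost-matrix recursion, unit steps, ties prefer the
  diagonal predecessor) over Euclidean fixation-to-word-center distances;
  each fixation takes the modal line of its matched words, ties to the
  topmost line.

Defaults involving L are resolved against the layout at call time
(half-spacing = 25 px for the default 50 px spacing).

## Metrics

Accuracy compares line *indices*, not pixel y, so algorithms are not
penalized for the numeric representation of a line's position. Agreement
is the modal-count fraction per fixation (not pairwise agreement),
matching the three-of-four = 75% definition; fixations with fewer than
two ratings are excluded with a warning. ICC(3,1) is the single-rater
consistency form from the two-way ANOVA without interaction, with
listwise deletion of incomplete fixations; line labels are treated as
interval-scaled values (the standard ICC assumption). A matrix with zero
total variance has no defined ICC and raises; zero residual variance with
subject variance returns ICC 1 with F = ∞. The group comparison is
scipy's tie-corrected two-sided Mann-Whitney U plus pooled-SD Cohen's d
(NaN with a warning for constant groups).

## Benchmark and reproducibility

`run_benchmark` derives every per-trial and per-algorithm seed from the
master seed via `SeedSequence` (labels hashed with CRC32, which is stable
across processes), so two runs with the same seed produce byte-identical
summary CSVs (floats written at six decimals) and manifests. The
manifest records seeds, magnitudes, generator parameters and the
distortion spec of every trial.

`magnitude_sweep` uses a paired design for the degradation analysis: per
replicate seed one base trial per condition, the three magnitudes applied
to the same walk, and a single noise seed shared across levels (common
random numbers). This isolates the magnitude effect from trial
variation; 20 replicates over a 4-line × 6-word layout keep the full
sweep under a minute while leaving mean accuracies stable to well under
the 2-percentage-point comparison tolerance.

Default problem sizes throughout the tests and examples (3–10 lines,
4–6 words per line, 12–60 fixations per trial) were chosen as typical of
single-paragraph reading stimuli.

## Known limitations

- The suite's distortion magnitudes and layout geometry are configurable
  stand-ins for those of any particular human-correction study; absolute
  accuracy numbers depend on them, and only relative/structural claims
  (orderings, monotone degradation, exactness properties) are asserted.
- All nine algorithms correct y only; horizontal drift is out of scope.
- ICC on categorical line labels inherits the interval-scale assumption;
  with very few lines the approximation coarsens.
- `merge` is O(k²) in the number of initial sequences per merge step;
  fine for paragraph-scale trials, slow for thousands of fixations.
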