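# Methods

`gazecontrast` implements the complete analysis chain for a face-recognition
eye-tracking experiment contrasting own- and other-race face viewing, together
with a synthetic-data generator that stands in for raw data.  This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic data can and cannot establish.

## The experimental design being emulated

Thirty observers study 48 frontal face photographs (16 each of three races,
scaled so the forehead subtends about 10° of visual angle) in self-paced
trials, then perform an old/new recognition test on 96 faces shown for 1 s
each.  Before every trial, gaze is held at one of four start positions
(left/right/above/below the internal features), computed per face so each is
equidistant from the centers of its nearest feature AOIs: the lateral points
are circumcenters of the (eye, half-nose, half-mouth) center triangle, and the
vertical points sit on the perpendicular bisector of the two eye (or two
mouth-half) centers at the mean of the two lateral equidistances.  Seven
rectangular AOIs (left eye, bridge, right eye, and bisected nose and mouth)
are drawn on every face; all geometry lives in degrees of visual angle with
the origin at the image's top-left corner and y increasing downward.
Rectangles are half-open (`x0 <= x < x1`), so bisection edges assign a point
to exactly one half.

## Synthetic data generator

The generator is a mixture-over-features model — the minimal structure the
downstream analyses assume, with directly interpretable effect-size knobs:

* **Face layouts.** A hand-drawn template with eyes in the upper third, nose
  central, and mouth in the lower third.  Each face jitters its three feature
  rows by a shared configural offset plus independent per-row offsets whose
  variances sum to `layout_jitter_sd²` (default 0.3°), so every AOI center is
  marginally Gaussian around the template while rows rarely collide; a face
  is redrawn on overlap.  A random half of the faces is mirrored about the
  vertical midline (AOI names follow image sides, so "left eye" is always the
  eye on the image left).
* **Fixations.** Fixation 1 lands near the face center, displaced toward the
  start side by `start_pull` (default 0.35).  Every later fixation first draws
  an AOI-group label from a race-specific probability vector over {left eye,
  bridge, right eye, nose, mouth, other}, then a location: Gaussian scatter
  (`scatter_sd`, default 0.4°) around the feature center, or uniform over the
  non-feature part of the frame for "other".  Early fixations tilt the label
  distribution toward start-side groups with geometrically decaying strength
  (`start_pull · 0.5^(ordinal−2)`).  The tilt multiplies the same groups by
  the same factor for every race, so race and start position act on disjoint
  parameters.  Study trials draw 5–9 fixations; durations are lognormal with
  a 250 ms median.
* **Default feature weights** inject the target effect structure: own-race
  (Caucasian) eye bias of +0.013 per eye and other-race nose/mouth surpluses
  of 0.6–1.6 percentage points against the Chinese and African conditions.
  After scatter leakage these produce paired Hedges' g values around 0.2 for
  the eye contrasts at n = 30 — subtle by design, because the scientific
  point under test is how analysis choice determines whether effects of this
  size are detected.  The calibration is asserted by test, not hard-coded.
* **Behavior.** Old/new judgments are Bernoulli per trial with per-race hit
  and false-alarm probabilities (defaults 0.72/0.18 Caucasian, 0.75/0.22
  African, 0.70/0.30 Chinese).  With 16 old and 16 new faces per race, the
  binomial sampling noise alone makes the paired d′ contrast between
  Caucasian and Chinese faces land near g ≈ 0.9, and the criterion ordering
  Caucasian > African > Chinese holds in group means.  RTs are lognormal
  (median 900 ms) with a 2% rate of 3–6× outliers to exercise the RT filter.

What the generator does **not** emulate: image content and saliency,
inter-participant strategy differences (all participants share the mixture),
saccade kinematics, blinks, drift, or any race × start-position interaction.
Passing tests therefore show that the analyses behave correctly on data with
the assumed statistical structure — not that real data have that structure.

## Analysis windows

Study-phase analyses use fixations 2–5: the first fixation is excluded
(reliably shorter, dominated by the start position) and later fixations are
dropped to equate data across trials.  An `include_first` switch restores the
1–5 window.  Test-phase analyses keep every fixation whose onset (cumulative
duration of its predecessors) falls inside the 1 s display.

## AOI analysis

Relative frequency divides each group's fixation count by the number of
*possible* fixations.  For the study phase this denominator is fixed by
design — trials × 4 (e.g. 16 × 4 = 64) — and trials with fewer than five
fixations still count fully, so denominators never depend on where or whether
fixations occurred.  For the test phase the 1 s cap makes possible counts
data-dependent; the realized per-trial in-window count is the default
denominator, with a fixed-window option.  Planned contrasts are paired
t-tests with declared tails (own > other for each eye; other > own for nose
and mouth), reported with bias-corrected Hedges' g using the d_av
standardizer: g = J(n−1) · mean(a−b) / s with s the average of the two
condition standard deviations and J(df) = 1 − 3/(4·df − 1).  The d_av
convention avoids the inflation a difference-score standardizer suffers under
correlated pairs.  Identical conditions return t = 0 and one-tailed p = 0.5
rather than the 0/0 a t-test would produce.

## Signal-detection metrics

d′ = z(hit) − z(fa) and c = −[z(hit) + z(fa)]/2 with z the inverse standard
normal.  Extreme rates are corrected before the transform: the default clamp
maps 0 → 1/(2n) and 1 → 1 − 1/(2n); a log-linear rule ((k+0.5)/(n+1)) is
selectable.  RTs of correct trials are filtered per participant × condition
by the rule "exclude values more extreme than 2.5 standard deviations from
the median", taken literally: the spread is the sample SD of the unfiltered
cell, centered on the median.  A consequence worth knowing: in very small
cells a single enormous outlier can inflate the SD enough to shield itself;
the filter evaluates the stated rule rather than second-guessing it.
Singleton and zero-variance cells are kept whole.

## Density maps

Each analyzed fixation contributes a unit-mass isotropic Gaussian with
σ = 0.3° (duration weighting is available but off by default).  Before
rendering, each face's fixations are translated by the closed-form minimizer
of the summed squared distance between its AOI centers and the population
mean centers — t = mean over AOIs of (reference − center); translations only,
no scaling or rotation.  Pixel values are exact cell integrals (products of
CDF differences along each axis), so the quadrature oracle in the tests is
exact and interior fixations conserve mass to float precision.  Out-of-grid
mass is lost, not renormalized, and reported via `mass_in_grid`; out-of-frame
fixations stay in every analysis.  The grid is explicit configuration
everywhere (`GridSpec`); the default working grid is 64 × 64 at 0.25°/pixel
over a 16° × 16° field, which samples σ = 0.3° adequately while keeping
permutation studies cheap, and a finer 256 × 256 grid at 0.0625°/pixel is a
one-line change.  Group maps average per-trial maps within participant and
then across participants; contrasts subtract per participant before
averaging.  Profiles are marginal sums (mass-preserving); the vertical
profile reads fixation density over facial features from forehead to chin.

## Permutation inference

The null hypothesis is that fixation locations of each ordinal rank are
identically distributed in the two contrasted conditions.  Exchangeability
holds only within a (participant × ordinal) cell; each iteration reassigns
the (location, face-alignment-offset) tokens of every cell between the
condition slots uniformly at random, preserving per-condition counts (so
trial-count imbalance is allowed), rebuilds both per-participant maps,
subtracts, and averages across participants.  Tokens carry their original
face's alignment offset, because the locations being exchanged live in the
aligned reference frame.

Because a token's pixel map never changes, the resampler precomputes one map
per token and forms each resampled group difference as a weighted sum.  Two
backends exist: `matmul` (one BLAS product per chunk of iterations; the
default) and `sum` (strictly sequential accumulation in token order, which is
bit-identical to naively re-rendering each condition and serves as the
reference the fast path is tested against; the two agree to 1e-12).  Each
cell's assignments come from a generator seeded by (master seed, cell index),
so results are independent of chunk size and processing order.

Pixel p-values are sign-dependent: a positive observed pixel is ranked
against the upper tail of the resampled values, a negative one against the
lower tail, with the (count+1)/(n_iter+1) convention so Monte Carlo p-values
are valid and never zero; exactly-zero observed pixels get p = 1.  Ties are
counted as extreme.  With the matmul backend, tail counts compare against the
matmul-path observed values (so an iteration that redraws the identity
assignment ties exactly) while signs and exact zeros come from the canonical
map.  Profile p-values collapse the *same* resampled maps along one axis —
reuse, not regeneration.  Uncorrected maps threshold at per-tail p < 0.01
(two-tailed 0.02); profiles at per-tail p < 0.025 (two-tailed 0.05).  FDR
correction is Benjamini–Hochberg step-up at q < 0.05, restricted to an
analysis mask for spatial maps (default: the union of aligned face frames,
standing in for a non-face-region mask) and over all pixels for profiles.

An exact-enumeration oracle exhausts every admissible reassignment on tiny
instances (capped at 10⁶), computing raw unsmoothed tail proportions through
the identical arithmetic path; the Monte Carlo test matches it within
binomial error.  The reference iteration count for production maps is
104,000; tests and replicate studies use 1,000–2,000 iterations, which bounds
attainable p-values at ~5·10⁻⁴ and is the reason FDR maps of subtle effects
are expected to be empty at these scales.

## Replicate studies and problem sizes

The test suite runs two replicate studies chosen to finish in minutes on one
CPU while keeping their statistical questions well-posed: a null calibration
(200 datasets, 10 participants, 8 trials/condition, equal feature weights,
2,000 iterations on the 64 × 64 grid) verifying that the fixed-pixel
rejection rate sits in the 99% binomial band around 0.02, that FDR maps are
almost always empty, and that the AOI contrast rejects at its nominal 5%;
and a sensitivity study (100 datasets at the default injected eye bias,
n = 30, 1,000 iterations) verifying the ordering that motivates the package:
the pooled AOI eye contrast rejects in strictly more replicates than the
FDR-corrected map shows any significant eye-region pixel.
`scripts/acceptance.py` reruns smaller versions of both (60 and 40 datasets)
plus the full default-design analysis.

## Known limitations

* The generator's effect sizes are calibration targets, not measurements of
  any real population; only orderings and calibration properties transfer.
* d′ heterogeneity across participants is purely binomial; real observers
  add true individual differences, which would enlarge the denominator of
  paired effect sizes.
* The exact-enumeration oracle is limited to instances whose reassignment
  count fits in 10⁶; larger oracles would need importance sampling.
* The non-face analysis mask is a rectangle union, not a face-shaped alpha
  mask; any boolean mask can be supplied where a tighter one exists.
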