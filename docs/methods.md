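# Methods

## The analysis in brief

`viewdecode` measures whether a population of trial-based spiking neurons
carries object-identity information that survives rotation of the object
in depth.  A linear classifier is trained to separate one object from
three similar distractors using population response vectors at one viewing
angle, and is tested on held-out response vectors at viewing angles 0–90°
away.  Decoding performance is tracked through time in sliding windows, so
both the strength and the latency of view-tolerant information can be read
off, and is referenced against a random-labeling permutation null.

## Preprocessing

* **Rates.** Spike counts in boxcar windows of `window_ms` (default
  100 ms) sliding in `step_ms` (default 20 ms) steps; a bin labeled *t*
  covers [*t* − w/2, *t* + w/2).  The default label grid −450…950 ms
  contains exactly 71 bins (closed form: ⌊(end − start)/step⌋ + 1).  The
  recorded trial window must cover every window; the simulator therefore
  records (−500, 1000) ms by default.
* **Baseline.** Each trial's mean rate over [−500, 0) ms is subtracted
  from that trial's bins (per-trial rather than per-cell: slow drifts in
  excitability then cancel; configurable).  Negative values are
  meaningful (suppression).
* **Normalization.** Each cell is z-scored against the mean and sample
  standard deviation (ddof = 1) of *all* its pooled (trial, bin) entries
  in the analysis range.  Zero-variance cells cannot be normalized and are
  excluded with a warning.  Normalization is idempotent to ≤ 1e−9.
* **Screening.** Per (cell, image), a two-sided Wilcoxon signed-rank test
  pairs the evoked rate (default window [0, 600) ms; the presentation
  epoch is configurable) with the same trial's spontaneous rate.
  Bonferroni correction uses m = number of images in the set (16 for a
  full set).  The exact null distribution is used for ≤ 25 tie-free
  pairs, otherwise a normal approximation with tie and continuity
  corrections.  Note that with m = 16 the smallest attainable two-sided
  exact p (2·2⁻ⁿ) only clears 0.05/16 from n = 10 trials upward; the
  screen warns below `min_trials` (default 6, the hard floor).

## Pseudo-population decoding

* **Assembly.** Cells were (or are simulated as) recorded in separate
  sessions, so pseudo-trial *j* of an image concatenates each cell's
  response on its own trial π_c(j), with an independent random permutation
  π_c per (cell, image).  The roster fixes component order.  Default 20
  pseudo-trials per image (must exceed the fold count and keep the
  TP/FP proportions reasonably grained).
* **Splits.** 5 folds × 5 repeats of a shuffled partition of pseudo-trial
  indices (shared across images, so every image's trials are spread evenly
  over folds) give the 25 d′ estimates per bin.
* **Classifier.** Linear soft-margin SVM, C = 1, no class reweighting
  despite the 1:3 imbalance (reweighting is exposed as a parameter).
  Implemented as a one-vs-rest hinge-loss liblinear problem whose four
  hyperplanes are fitted in a single call; a dual-coordinate-descent
  iteration cap (`max_iter` = 250, tol 1e−3) bounds runtime on
  unstructured data without measurably changing decisions, and the
  intercept is effectively unregularized (intercept scaling 10).  The
  maximum-margin geometry is verified against a direct QP oracle in the
  tests.  Training uses one anchor angle at a time; a `train_scope=
  "pooled"` switch trains jointly on all four same-angle vector sets
  instead (the choice the original procedure left ambiguous).  Training
  and testing always use the same time bin.
* **d′.** tp and fp are the proportions of target/non-target held-out
  vectors with positive decision value, clipped to [1/(2n), 1 − 1/(2n)]
  (n = the relevant side's test count) before the inverse-normal
  transform; d′ = z(tp) − z(fp).  One estimate per (bin, repeat, fold) is
  the average of d′ over the 4 target objects, the angle pairs of the
  tested angular difference (both rotation directions pooled: 6/4/2
  ordered pairs at 30/60/90°, 4 identity pairs at 0°) and the object
  sets of the condition; a `pool_confusions` variant pools the counts
  into one confusion table first.

  A consequence of the clipping rule worth knowing: with small, unequal
  test counts (e.g. 4 target vs 12 non-target vectors per pair) an
  everything-labeled-0 classifier yields d′ = z(1/8) − z(1/24) ≈ +0.58,
  not 0.  The permutation null carries the identical bias, so the
  real-vs-null comparison stays calibrated, but raw d′ values near chance
  should not be read as exactly zero-centered.
* **Null.** Object labels are permuted independently within every
  (set, angle) stratum, freshly per repeat; the pipeline is otherwise
  identical, giving a matched 71 × 25 null matrix.  At Δ = 0 a
  per-angle relabeling is consistent between train and test and is *not*
  a null — the same-angle baseline is reported without one.

## Inference

* Per bin, the 25 real vs 25 null estimates enter a two-sided
  Mann-Whitney U test (exact distribution when tie-free, which holds for
  continuous d′ values; tie-corrected normal approximation otherwise,
  with the continuity correction clipped at the distribution center so
  identical samples give exactly p = 1).
* A time course is significant only where p stays **strictly below**
  0.001 for ≥ 5 consecutive bins; no further correction is applied across
  the bins (or across the 852 condition × bin combinations of a full
  run) beyond this run-length rule.
* Neuron-dropping curves rerun the decoder on a single wide 100–600 ms
  window for 5 random draws of each roster size; reported as mean ±
  SE (SD/√5).

## The synthetic generator

Cells are inhomogeneous-Poisson units:

    rate(t) = baseline                                   t < latency
              baseline + phase_gain(t) · g(image)        latency ≤ t < 600 ms
              baseline + late_gain · g(image) · e^(−(t−600)/τ)   t ≥ 600 ms

with per-cell latency ~ U(70, 110) ms, an early/late phase boundary at
300 ms (early gain 1.0, late 0.7) and decay τ = 150 ms.  The evoked gain
of an image is

    g = amplitude · [α·u(object) + (1 − α)·v(object, view)]

where `amplitude` is log-normal (median 10 spikes/s, log-sd 0.5; baseline
median 5 spikes/s, log-sd 0.4), and u, v are unit-mean log-normal
selectivity factors (log-sd `tuning_sigma` = 1).  u is shared across the
four views of an object (view-invariant object preference); v is
view-specific.  The association strength α is drawn per cell from a Beta
distribution with the group's mean:

| group            | mean α | rationale                                   |
|------------------|--------|---------------------------------------------|
| TE, object task  | 0.75   | view-association experience, anterior IT    |
| TE, across-set   | 0.30   | exposure only; partial invariance           |
| TEO, object/across | 0.10 | posterior IT: predominantly view-specific   |

The view-specific component is angularly *correlated*: the latent Gaussian
behind v has correlation exp(−(Δ/λ)²) between views Δ apart, λ =
`view_corr_length_deg` = 31° (≈ 0.39 at 30°, ≈ 0.02 at 60°).  This is the
generator's expression of the graded ~30° viewing-angle tolerance of
view-tuned IT cells; λ = 0 recovers fully independent per-view gains (the
limit in which the α = 0 independence property is tested).  With these
defaults the cross-view signal correlation is ≈ 0.9 at all Δ for the
TE-like group and ≈ 0.4 / 0.03 / 0.02 at 30/60/90° for the TEO-like group
— which is what makes the TE-like population decodable at all three
rotations and the TEO-like population at 30° only.

Trials are i.i.d. single presentations (the analysis the package mirrors
used only first presentations).  What the generator does **not** emulate:
noise correlations between simultaneously recorded cells (cells are
assembled as pseudo-populations anyway), firing-rate adaptation across
trials, non-Poisson spiking statistics, latency differences between
stimuli, and any behavioral/attentional modulation.  Passing tests on this
generator therefore validate the *analysis chain* — its bookkeeping,
statistics and qualitative sensitivity to association strength — not any
claim about real tissue.

## Presets and problem sizes

* `paper_roster_config`: four groups with roster sizes 60/49/40/65
  (109 TE + 105 TEO cells), two object sets, 20 trials per image.
* `contrast_config`: TE-like (ᾱ = 0.75) vs TEO-like (ᾱ = 0.10,
  concentration 30) populations, 64 cells each, one set, 20 trials.  The
  package's qualitative-contrast checks run this preset through the full
  71-bin chain with nulls at Δ = 30/60/90°.
* `zero_signal_config`: tuning gain scale 0 (pure baseline Poisson
  trains), 24 cells, 10 trials — the type-I-error configuration, decoded
  at Δ = 90° with screening disabled (screening would empty the roster,
  which controls false positives trivially rather than by the statistics).
  Twenty seeded runs of the full chain are expected to produce at most one
  run with a significant interval.

These sizes are the package's chosen desk-scale study conditions; they are
deliberately small enough that the complete test suite and the acceptance
script each finish in minutes while leaving the decoding problem
statistically non-trivial.

## Numerical and degenerate-input conventions

* Bin labels are window centers; windows are half-open [lo, hi).
* Zero-variance cells: excluded from normalization with a warning, never
  silently passed.
* Single-class training sets raise; identical training vectors with mixed
  labels warn and fall back to a constant decision.
* Proportion clipping makes every d′ finite; d′(p, p) = 0 exactly.
* p-values exactly at the 0.001 threshold do not count toward runs
  ("below" is strict).
* Every stochastic step (population draw, spike draw, trial permutation,
  fold shuffling, label permutation, cell subsampling) takes a named seed;
  identical configurations reproduce byte-identical outputs.

## Known limitations

* The d′ chance-level bias under clipping (above) makes absolute d′
  magnitudes depend on test-set size; comparisons should stay within one
  split geometry.
* The exact Mann-Whitney branch assumes tie-free d′ values; massively
  discretized inputs would silently shift to the corrected normal branch.
* The angular-correlation model of view tuning is phenomenological; λ is
  not fitted to any recording.
* The TE/TEO qualitative contrast is a stochastic property of a finite
  population: with 64 cells the realized across-cell correlation between
  tuning at two views fluctuates around its expectation with an SE of
  roughly 1/√(n_cells·n_objects) ≈ 0.06, so an association-poor
  population can, at some population seeds, cross the significance
  threshold at 60° or 90° (or dip below it at 30°).  The documented
  preset reproduces the 30°-only pattern at its reference seed; across
  arbitrary seeds the pattern holds in most but not all draws.
* Cross-bin (temporal-generalization) decoding and nonlinear kernels are
  out of scope.
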