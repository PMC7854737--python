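# Methods

## The model

Recursive dynamic functional connectivity (rdFC) quantifies how the
coupling between neurophysiological signals is itself coupled across
temporal scales.  Given three signals (an electrode *triplet*), a
1-second window slides sample-by-sample along the data, and the Pearson
correlation of each of the C(3,2) = 3 channel pairings is computed per
window.  This yields the order-1 dynamic connectivity time series —
three signals of windowed correlations.  The same sliding-window
operation is applied to that trivariate series to give order 2, and so
on recursively; by default the recursion runs four times, producing
orders 1–4 of dynamic series.  Each trivariate series (the raw signals
plus four dynamic series) is summarized by three full-length Pearson
coefficients, giving five *static* connectivity triples.  Each triple
is a point (x, y, z) ∈ [−1, 1]³, assigned by the fixed pairing
convention x ← corr(e₁,e₂), y ← corr(e₁,e₃), z ← corr(e₂,e₃) for the
ordered channel sequence (e₁,e₂,e₃).  The five points joined by four
segments form the rdFC pattern.

Because Pearson correlation is invariant to per-channel positive affine
transforms, the pattern depends only on the signals' joint fluctuation
structure, not their amplitudes.  An unordered triplet admits
P(3,3) = 6 ordered sequences; permuting the sequence permutes each
point's coordinates by the induced pair permutation, iterated across
orders (`pattern_coordinate_permutations`).  The six sequence patterns
therefore represent a single underlying correlation structure in six
coordinate frames, and fall into three classes of two according to
which axis carries the lowest first-order coefficient.

With k starting nodes the recursion generates C(k,2) measures at order
1 and c_{n+1} = C(c_n, 2) at each later order: three nodes are the
fixed point (3 per order, 15 in total for five orders), while four
nodes already require 14,908,656 static measures by order five —
the combinatorial reason the method uses triplets.

## Matching

Two patterns are compared by shape alone.  Each polyline's four
segments are normalized to unit directions, and the match score is the
sum of the four dot products of corresponding directions: range −4 to
+4, +4 for identical shape, invariant to positive scaling and
translation of either pattern.  A sample is matched against a
*reference set* of three patterns related by coordinate permutations;
the highest of the three scores is its match score, and the match is
*exclusive* when exactly one reference crosses the significance
threshold.  Zero-length segments (possible in random pseudo-patterns)
carry a flagged null direction contributing 0, so degenerate patterns
score low rather than erroring.  Ties in the best-reference argmax
break toward the lowest reference index.

The matching reference can also be *predicted* from the first-order
point alone: the axis holding the lowest first-order coefficient maps
to a reference (default x→3, y→2, z→1, fixed by the reference-set
construction).  The gap between the two lowest first-order coordinates
separates clean predictions from ambiguous double matches, and the
exclusive-vs-double gap distributions are compared with a two-sided
Mann–Whitney U test (tie-corrected normal approximation for larger
samples, exact enumeration for small ones; no Fisher transform — the
test is rank-based).  The common-language effect size U/(n₁n₂), with U
the larger statistic, equals the area under the ROC curve.

## Significance calibration

The threshold separating genuine shape matches from chance is
calibrated by Monte Carlo: 100,000 pseudo-patterns with 15 iid
Uniform(−1, 1) coordinates are scored against the reference set
(best of three), and the linear-interpolation 95th percentile of the
null scores is the cutoff — exactly 5% of random patterns reach it by
construction.  The cutoff depends on the references' segment geometry:
the more the references' consecutive segments anti-align (zigzag), the
heavier the null's upper tail, because consecutive segments of a random
pattern share a point and are negatively correlated.  For reference
sets with the alternating-decay geometry produced by the default
generator the cutoff lands near 2.6–2.8; monotonically decaying
references would give ≈ 1.9.  All calibrations record their seed, n and
percentile, and there is no hidden global RNG state anywhere in the
package.

## Synthetic data

The generator produces channels as linear mixtures of band-limited
(0.5–70 Hz, zero-phase Butterworth) unit-variance Gaussian latent
sources plus independent white sensor noise.  Gaussian mixtures were
chosen because their pairwise correlations have a closed form,
r_ij = (MᵢSMⱼᵀ)/√(MᵢSMᵢᵀ·MⱼSMⱼᵀ) with S the diagonal of time-averaged
source variances — the parameter-recovery tests validate the whole
forward pipeline against it to within 0.05 at 300 s / 256 Hz.  Source
amplitudes can be modulated (sinusoid or piecewise switch); modulation
makes the order-1 dynamic series non-constant, which keeps orders 2–5
nondegenerate.

`default_reference_spec` defines the conditions for building reference
sets: two shared sources with independent infra-slow amplitude
modulations (0.02 and 0.05 Hz, depth 0.8), one private source per
channel with distinct gains, noise sd 0.1, 300 s at 256 Hz.  Two
independently co-modulated shared sources make the three pairwise
couplings fluctuate against each other, and the resulting patterns show
the profile characteristic of scalp EEG rdFC: strong first-order
coupling followed by an alternating, spiral-like decay of higher-order
points toward the origin (computing 20 orders shows the coordinates
continuing to shrink).  Under these conditions the Monte-Carlo cutoff
is reproducibly in the 2.6–2.8 range across seeds.

What the generator does *not* emulate: oscillatory rhythms (an
`("sin", f, depth)` envelope can approximate slow waxing-waning, but
there are no alpha spindles), heavy-tailed artefacts, non-stationary
noise floors, or volume-conduction field spread.  Passing tests
therefore demonstrate the algorithmic and statistical properties of the
method, not clinical prevalence figures, which require real cohorts.

## Preprocessing conventions

- Band-pass 0.5–70 Hz, 4th-order Butterworth, applied forward-backward
  (zero phase); power-line notch (50 or 60 Hz) as a second-order IIR
  with quality factor 30, also forward-backward.  The band edges are the
  clinical recording standard; the realizations are ordinary clinical
  practice choices.  When a record's rate puts 70 Hz at or above
  Nyquist, the batch pipeline clamps the high edge to 0.45 × rate and
  logs it.
- Re-referencing: `average` subtracts the instantaneous channel mean
  (idempotent); `common:<label>` re-expresses channels against one
  electrode.  Bipolar montages are converted algebraically by
  telescoping channel chains; montages whose graph does not connect to
  the target reference are refused with a logged skip.
- Resampling is polyphase and anti-aliased.
- Epochs are 300 s on a non-overlapping grid anchored at the record
  start, 1-based; the default epoch index 2 avoids calibration
  sequences at the head of clinical records.  A channel is flat-lined
  when any contiguous ≥ 1 s span has zero peak-to-peak amplitude
  (catches disconnected electrodes without flagging low-amplitude
  sleep EEG); a flat epoch is replaced by the next epoch on the grid
  and the substitution recorded in the epoch metadata.
- The analysis window is specified in seconds (1 s default) and
  converted to samples as round(rate); the same *sample* count is used
  at every recursion order.

## Numerical choices

- Sliding correlations use rolling sums in blocks of 2¹⁶ windows
  (recomputed per block to bound floating-point drift) after removing
  each signal's global mean; a per-window direct evaluation guards the
  implementation to 1e−8 on short signals and to 1e−10 against
  `np.corrcoef` spot checks across block boundaries.
- Zero-variance windows (or constant full-length series) have no
  Pearson coefficient; they are assigned 0 and counted in a module
  counter rather than propagating NaN, which would poison all higher
  orders.  The degeneracy test is relative (variance ≤ 1e−12 of the
  window's energy).
- All correlations are clipped to [−1, 1] after computation to absorb
  rounding.
- Default triplet sets are conventions over a schematic 16-electrode
  10–20 layout: left-hemisphere triples ranked by perimeter, the 16
  tightest (near) and next 16 (intermediate) each followed by their
  right-hemisphere mirror images, plus the 5 largest-area outer-ring
  triples and mirrors (far), giving 32/32/10.  Any real study should
  override them from config with the montage actually recorded.
- The noise-robustness sweep injects 2-s white Gaussian bursts every
  30 s (10 bursts per 5-min epoch) at powers expressed relative to the
  epoch's mean signal power, using one burst realization rescaled
  across power levels (common random numbers) so the score-vs-power
  curve is a paired comparison.

## Problem sizes

Unit tests run on signals of 10²–10³ samples where the properties are
scale-free; pipeline-level tests (parameter recovery, calibration,
noise sweep, temporal courses) use the full 300 s × 256 Hz epoch size
and n = 100,000 null patterns, matching the method's intended operating
point.  The acceptance script regenerates its reference set and null
ensemble from scratch at those sizes on every run.

## Known limitations

- The match score compares segment directions only; two patterns with
  identical directions but different segment length ratios score 4.
  This is by design (shape, not size) but means the score is not a
  metric.
- The significance threshold is a property of the reference set; it
  must be recalibrated whenever references change.
- Exclusivity ("matched exactly one reference") is operationalized via
  threshold crossings; patterns with exactly tied lowest coordinates
  are reported as ambiguous and excluded from prediction accuracy.
- EDF support covers the common 16-bit continuous-signal layout with
  equal per-record rates; EDF+ discontinuous files are out of scope.
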