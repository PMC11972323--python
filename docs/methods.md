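# Methods

## The model

An ensemble of repeated 1-D measurements (hand-speed profiles, force
traces, any repeated trial of one process) varies in two distinct ways:
*spatially*, in amplitude, and *temporally*, in when things happen and how
fast the internal "clock" of each trial runs.  Conventional length
equalization — NaN-padding to a common start or end, or uniform
time-normalization to a common sample count — removes neither kind of
misalignment, so cross-sectional means flatten and widen every salient
feature.  Elastic functional data analysis (EFDA) separates the two.

Each trial is rescaled to normalized time `t ∈ [0, 1]` on the uniform grid
`t_k = k/(n−1)`.  A warping function γ is a monotone map of [0, 1] onto
itself with γ(0)=0, γ(1)=1; warping acts by composition, `x ∘ γ`, which
re-times the signal without touching amplitudes.  Signals are represented
by their square-root rate function (SRSF; the same object is called SRRF
or SRVF in parts of the literature)

    q(t) = ẋ(t) / √|ẋ(t)| ,     q = 0 where ẋ = 0,

under which the Fisher–Rao distance between two signals is the plain L2
distance of their SRSFs,

    d_FR(x₁, x₂) = ‖q₂ − q₁‖₂ ,

and warping acts by the isometry `q ↦ (q∘γ)·√γ̇`.  The isometry is the
load-bearing property: distances are invariant under simultaneous
re-timing, alignment is symmetric in its arguments, and the degenerate
"pinching" solutions of naive L2/DTW-style alignment are excluded.

## Pairwise alignment

`align_pair` minimizes

    ∫ (q_ref − (q_mov∘γ)·√γ̇)² dt  +  λ ∫ (√γ̇ − 1)² dt

over monotone lattice paths through the n×n grid of (reference, moving)
index pairs, by dynamic programming.  Admissible steps are offsets (a, b)
with a, b ∈ {1, …, grid_stride} and gcd(a,b)=1 (default stride 7), which
confines local slopes to [1/7, 7] and forbids flat or vertical segments.
Edge costs are trapezoidal quadratures with the moving SRSF linearly
interpolated at exact rational positions; ties between predecessors go to
the first candidate in the deterministically ordered slope set, so results
are reproducible across platforms.  The reported cost is the amplitude
term only (the minimized Fisher–Rao distance); the roughness penalty
shapes the optimum but is not part of the distance.

Defaults: λ = 0.01, at most 3 template iterations, no pre-smoothing,
dynamic programming — the conventional settings for this family of
elastic-registration problems.

### Discretization floor

Two-peaked signals have square-root cusps in their SRSF at every
stationary point.  A lattice path can place a cusp no closer than one grid
step, which costs `amp² ≈ O(ẍ·h)`; at n ≈ 300 this leaves a residual
amplitude distance around 0.05 for unit-scale signals *even for a pair
that is a pure re-timing of itself*.  The floor shrinks only like √h and
is insensitive to the slope-set resolution.  Warp recovery is unaffected
(sup-norm error ~2·10⁻³); consumers of near-zero amplitude distances
should interpret them relative to the unaligned distance, which is how the
package's own tests phrase the property.

## Ensemble alignment and the template

`align_ensemble` (estimator form: `ElasticAligner`) iterates:

1. initialize the template as the signal whose SRSF is closest in L2 to
   the cross-sectional mean SRSF (a medoid-like start that avoids an
   over-smoothed initial shape);
2. align every signal to the template by DP;
3. update the template as the minimizer of the summed DP quadrature —
   numerically the per-node mean of the warped SRSFs, with vertex nodes
   averaging their left/right slope limits.  Using the exact quadrature
   minimizer (rather than a plain pointwise mean of re-differentiated
   warped signals) makes the alternating scheme *exactly* monotone in the
   summed objective, which the tests assert at 1e-9;
4. stop after `max_iterations` (default 3) or when the template changes by
   less than 1e-4 in relative L2;
5. center: with γ̄ the pointwise mean warp, replace every γᵢ by
   γᵢ∘γ̄⁻¹ and compose the template with γ̄⁻¹, so the mean warp is the
   identity (exactly, up to interpolation).  Centering is pointwise, not a
   Karcher mean on the warp manifold; for the moderate warps this package
   targets the two agree closely, but users doing inference *on the warps
   themselves* should be aware of the choice.

The reported template is the cross-sectional mean of the aligned signals
in signal space (the reference trial itself in reference mode); mapping
the q-space template back through the inverse transform would add an
avoidable ~10⁻³ integration error.  Amplitude distances are computed
against the final template before centering; centering is an isometry, so
they are unchanged.

`align_to_reference` fixes the template to a chosen trial and skips
centering; `elastic_distance` returns the pair (amplitude, phase) where
phase is the L2 distance between √γ̇* and 1.

## Variability decomposition

With aligned signals X (M×N) and warps Γ, sample SDs taken across trials
with denominator M−1:

    Var_Spat     = (1/N) Σ_k SD(x·ₖ)        [signal units]
    Var_Temp     = (1/N) Σ_k SD(γ·ₖ)        [normalized time, unitless]
    Var_Temp2Spat= (1/N) Σ_k SD(x^w·ₖ)      [signal units]

where `x^w` warps the aligned mean by each trial's γ — same shape and
amplitude everywhere, only the timing varies — expressing the timing noise
in signal units.  The scalars are time *averages* of the SD curves (the
1/N prefactor), which keeps them independent of grid resolution.  Both
Var_Temp and Var_Temp2Spat are exactly zero for identity warps, and
Var_Temp is invariant to first subtracting the identity (or any fixed
curve) from every warp.

## Baselines

`pad_ensemble` stacks trials at a common start (`left`) or end (`right`),
preserving samples bit-exactly, NaN elsewhere; `normalize_ensemble`
resamples each trial to a common count.  `ensemble_stats` computes
NaN-aware per-column means/SDs and masks columns with fewer than
`min_count` (default 2) finite entries — sparse padded tails would
otherwise be dominated by one or two long trials.  The padded
spatial-variability scalar averages the SD curve over the unmasked columns
only; the threshold is configurable because either reading of how sparse
tails should enter the integral is defensible.

## The synthetic benchmark

`generate_ensemble` draws, per signal, independent zero-mean Gaussian
perturbations of the triple-Gaussian parameters

| parameter | value | noise SD | units |
|---|---|---|---|
| A1 | 3 | 0.3 | signal |
| A2 | 4 | 0.3 | signal |
| W1, W2 (FWHM) | 0.16 | 0.05 | s |
| ΔT (peak separation) | 0.4 | 0.03 | s |
| t0 (first peak) | 0.3 | — | s |
| onset/offset threshold | 2 % of max | — | |

with T1 = t0, T2 = t0 + ΔT, and a third "flick" term reusing scaled
second-peak parameters (amplitude A2/3, width W2/5, centered at
T2 + W2/2).  Noise on t0 is off by default but available (`sigma_t0`) —
the flick is a landmark, and t0 noise is the one parameter for which the
benchmark tables give no spread.  Non-positive draws of amplitudes and
widths are rejected and redrawn (per-draw probability ≲ 0.1 %).  Signals
are evaluated on [0, 1] s at dt = 0.002 s (500 Hz, a typical capture
rate) and trimmed to the span above 2 % of their own maximum, so trials
genuinely differ in length and duration.  Given a seed the ensemble is
bit-reproducible.

### What the generator does and does not emulate

It reproduces the structure the alignment methods are compared on —
trial-to-trial amplitude, width and timing noise, ragged trial lengths, a
small sharp landmark that naive averaging destroys.  It does not contain
measurement noise on the samples themselves, baseline drift, multi-modal
trial families, or outlier trials; passing the benchmark therefore shows
correct method behavior under parameterized shape variability, not
robustness to dirty recordings.

## Feature extraction

`extract_features` locates the two most prominent local maxima
(time-ordered), refines apex time/amplitude by a 3-point parabola, and
finds each FWHM from the half-maximum crossings walking outward with
linear interpolation.  A walk that starts rising by more than 2 % of the
peak amplitude above its running minimum before crossing the half-maximum
has entered a neighbouring bump — in the benchmark, the flick sits exactly
on the second peak's half-max shoulder — and is abandoned; that side's
half-width is then mirrored from the opposite side.  On noise-free input
this recovers W2 exactly; on padded/normalized mean curves, where the
flick has washed into the shoulder, the crossing usually survives and the
measured widening is reported as-is.

## Benchmark scoring

Ground truth uses the drawn parameter values (and their SDs for
SD_A1/SD_A2), not re-extracted features.  Time features are scored in
seconds from each trial's trim onset — the only frame all three methods
share, since no method sees samples before the 2 % threshold.  Estimates
from a padded mean are already in seconds; normalized/warped estimates are
scaled back by the ensemble's mean duration.  SD_A1/SD_A2 estimates read
the method's pointwise-SD curve at the mean curve's two peak times.
Problem sizes: 500 signals per ensemble on a 200-sample common grid; the
acceptance script averages its width-error ratio over 5 seeded ensembles.
These sizes make a full run take a few minutes on one core while leaving
Monte-Carlo error well below the effects being measured.

## Known limitations

- One-dimensional signals only; multi-channel trials need one warp per
  channel or an external common warp.
- The DP lattice bounds warp slopes to [1/stride, stride]; genuinely more
  extreme local time distortion saturates there.
- Amplitude distances carry the cusp discretization floor described above.
- Pointwise (not Karcher) warp centering.
- The padded baseline assumes a shared sampling rate across trials.
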