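# Methods

This note documents the models and numerical choices behind `islet3d`, in
the spirit of a methods appendix: what each stage assumes, which parameters
matter, and what the synthetic data does and does not emulate.

## The measurement model

The unit of analysis is one islet recording: N cells with 3D positions
(micrometres, islet-local origin at the position mean) and an N×T matrix of
per-cell fluorescence traces sampled at a fixed rate (default 2.02 Hz,
matching volumetric acquisition of a ~130 μm stack). Traces are assumed to
be slow Ca²⁺ oscillations — square-ish waves with a period of minutes —
shared across the islet up to per-cell phase lags, amplitudes and noise.
Fast electrical bursting within the active phase is out of scope.

## Synthetic islets

`generate_islet` builds recordings with known ground truth:

* **Geometry.** Cell centres are rejection-sampled uniformly in a sphere
  (default radius 60 μm) with pairwise spacing ≥ 9.3 μm, the β-cell ROI
  diameter after nuclear expansion; a budget of 10,000 attempts per cell
  guards infeasible configurations (raised as `PackingError`). At the
  default 500 cells in a 60 μm sphere the hard-sphere volume fraction is
  ~0.23, comfortably below the random-packing limit. A single cell is placed
  at the origin.
* **Pulses.** Each oscillation contributes
  `baseline + amplitude · σ((t−t_on)/s) · σ((t_off−t)/s)` with logistic σ and
  `s` set so the 10–90% rise takes `rise_time` (default 8 s). The product of
  two logistics crosses half-amplitude at `t_on` and `t_off`, so the active
  phase at half-max equals `duty_cycle · period` (defaults 0.45 and 406.2 s,
  i.e. a 6.77 min period) by construction — which is what makes one-frame
  recovery tests meaningful.
* **Travelling wave.** Oscillation k carries a unit axis (a supplied
  schedule, or drawn uniformly on the sphere); cell n is delayed by
  `(pₙ − min pₘ)/wave_speed` with pₙ the projection on the axis. Cells at
  the low-projection pole lead, so the early→late direction equals the
  imposed axis. The default wave speed of 15 μm/s gives ~8 s of lag across a
  120 μm islet — several frames at 2 Hz, in the range of slow islet Ca²⁺
  waves.
* **Noise.** Independent Gaussian noise with SD interpolated linearly from
  `noise_sd_center` (0.05 AU) at the origin to `noise_sd_edge` (0.15 AU) at
  the surface reproduces the empirical pattern that peripheral cells are
  less synchronized; a shared component drawn per frame from a
  squared-exponential spatial kernel (SD 0.05 AU, length scale 20 μm) gives
  nearby cells correlated fluctuations and hence an *emergent* high-degree
  region. Real GCaMP noise levels are not published for this preparation, so
  these are free parameters; all recovery guarantees are therefore stated
  on noiseless or parametrically controlled instances. The generator also
  omits photobleaching, motion, optical sectioning and camera noise.
* **Determinism.** One seed feeds a `SeedSequence` whose spawned children
  drive packing, axes, independent and shared noise; identical configs are
  bit-identical.

`render_volume`/`extract_traces` close the loop to image space: spheres of
radius 4.65 μm (nearest cell wins on overlap) rasterised at a chosen voxel
size, and mean-intensity spherical-ROI extraction with membership computed
once. A voxel budget (2×10⁸) guards accidental huge allocations.

## Oscillation segmentation

Peaks of the islet-average trace are detected with prominence (default: ¼
of the robust 5–95% range) and minimum separation, then refined to the
midpoint of the above-half-max plateau — on square-ish waves the raw argmax
wanders the flat plateau with noise, while the half-max crossings sit on
steep edges and pin the midpoint to ±1 frame. A manual peak list bypasses
detection (validated, not modified), mirroring semi-automated practice.

Depolarization/repolarization edges are the extrema of the
Gaussian-smoothed (σ = 1 frame) central-difference derivative either side of
each peak; the edge start/stop is where the signed derivative decays below
10% of its extremum. Raw differences on noisy traces produce spurious
extrema; one frame of smoothing biases boundaries by well under a frame at
these rise times.

The analysis window pads the [depol_start, repol_end] core by x seconds
before and x/2 after, with **x = ¼ of the active-phase duration**
(duty cycle × period). The padding fraction is stated in the source
convention ambiguously ("x = ¼ oscillation duty cycle"); a duty cycle is
dimensionless, and ¼ of the active phase is the only reading that yields a
time, so that is the implemented default (the leading pad is twice the
trailing pad in any case). Windows are clipped to the recording — segments
truncated at either end are flagged `incomplete` and skipped downstream —
and trimmed to be disjoint at the midpoint between adjacent cores.

Per-oscillation metrics use the half-max level (window min+max)/2, so a
drifting baseline does not bias the duty cycle, and the period is the
peak-to-peak spacing (the last oscillation reuses the preceding spacing).
Flat windows are flagged rather than producing NaN arithmetic downstream.

## Functional network

Pearson correlation of z-scored traces within each oscillation window
(Spearman available); zero-variance cells are flagged and given zero
correlation. One threshold per islet is calibrated on the pooled
off-diagonal correlations of all oscillations so the oscillation-averaged
mean degree is as close as possible to 7 — the fixed-average-degree
convention that compensates islet-to-islet differences in overall
synchrony. Because edges are discrete, the target is generally not exactly
attainable: the closest achievable count wins, ties resolve to the sparser
network, and the edge rule is strict (r > τ). A warning is emitted if no
threshold lands within one degree of the target (e.g. when all correlations
are identical). Top/bottom `round(0.10·N)` cells by degree (ties broken by
ascending cell id, for reproducibility) form the high/low-degree sets; the
mean degree is a non-increasing step function of τ, which the test suite
asserts exhaustively on small instances.

Spatial statistics normalize each cell's distance-from-centre by the islet's
maximum cell radius, so the farthest cell scores exactly 1 and islets of
different sizes are comparable; subpopulation centre-of-gravity
displacements between oscillations are normalized the same way.

## Wave analysis

Phases are argmax lags of the Pearson cross-correlation against the
islet-mean trace over integer frame lags in ±max_lag (default half the
period). No sub-frame interpolation is used for the argmax — at 2 Hz the
frame grid is the natural resolution — whereas half-max *crossing* times in
`depolarization_times` are linearly interpolated, because a level crossing
has a well-defined sub-frame location. The sign convention is stated
everywhere: positive phase lags the islet mean (late cell), negative leads.
Ties resolve to the smallest |lag|, then the negative one.

The wave axis is the first principal component of the retained early+late
cell positions, computed from the 3×3 covariance. Cells farther than 50 μm
from their own set's centre of gravity are excluded as spurious. The
eigenvector sign is fixed deterministically (largest-magnitude component
positive) before orienting the axis from the early toward the late centre
of gravity. With 10% subpopulations a single islet's axis carries a few
degrees of sampling error; the median angular error over many noiseless
islets is below 5°.

Axis variability per transition is the squared Euclidean distance between
consecutive unit axes (range [0, 4]). To compare islets of different shapes
it is normalized by the variability of axes fit to randomly drawn early/late
sets of the true sizes: default 50,000 resamples and the `max` of the
resampled changes (the maximum variability attainable with no wave
structure); `mean` and `p95` modes are provided because the maximum of many
draws is an unstable extreme statistic. The resampling is vectorised
(batched 3×3 eigendecompositions), so the default count runs in seconds;
the pipeline demo configuration uses 2,000 resamples, a size chosen to keep
the end-to-end examples fast while leaving the per-transition normalizer
within a few percent of the large-sample value.

No cutoff for "substantial" axis change is shipped: the normalized change
distribution is reported and left to the user to threshold.

## Consistency (normalized KL divergence)

Cells are ranked 1..N per oscillation by descending degree or ascending
phase (cellular mode) or by ascending distance to the top-set centre of
gravity (regional mode); ties break by ascending id and flagged cells rank
last. Ranks become probabilities through a normal density with mean (N+1)/2
and SD N/6 — the rank range spans about ±3 SD — renormalized to sum to 1.
The SD is configurable; the qualitative orderings reported by the package
are insensitive to SD within [N/8, N/3]. Raw divergence is
D_KL(Pᵢ‖Pⱼ) = Σ Pᵢ log(Pᵢ/Pⱼ) with the natural log (the base cancels under
normalization). Each consecutive pair's divergence is divided by the mean of
100 KLs computed after uniformly permuting the second ranking; with the
mean normalizer, unrelated rankings score 1 in expectation, matching the
"0 = predictable, 1 = random" reading. A `max` normalizer is available.
Consecutive pairs are the default; an all-pairs mode exists.

## Pipeline, 2D planes, pre/post comparison

`analyze_population` chains the stages on any cell population and
`analyze_dataset` adds thin-plane subsets: a plane at ¼ or ½ of the z-extent
of the *cell positions* (the package has no access to the imaging stack
itself), keeping cells within ±3 μm. Subsets keep their ids so retention
and consistency remain comparable. Reports are deterministic given seeds —
byte-identical JSON across runs — and every input cell appears exactly once
per oscillation in the per-cell tables, flagged or analyzed.

`compare_conditions` pairs two reports of the same cells (e.g. before/after
a glucokinase or pyruvate-kinase activator, which the synthetic generator
emulates as a longer duty cycle with a frozen axis schedule, or a shorter
period). Oscillation-indexed metrics are truncated to the common count;
outputs are mean deltas with SEM plus subpopulation retention across the
treatment boundary. Formal hypothesis testing is intentionally out of
scope — the package reports effect directions and paired summaries only.

## Problem sizes and tolerances

The shipped tests and the acceptance script run on synthetic islets of
60–500 cells, 1–6 oscillations, ~100–406 s periods at 2 Hz sampling —
sizes chosen so the full suite completes in well under a minute per module
while still exercising 10%-subpopulation granularity. Recovery tolerances
are one frame interval for times and periods, 1e-12 for algebraic oracles,
and 5° (median) for axis direction. Degenerate inputs (flat windows,
zero-variance cells, empty slabs, infeasible packings, unreachable degree
targets) raise or flag explicitly rather than propagating NaNs.

## Known limitations

* The generator's phase-lag templates contain no biophysics (no K_ATP/
  electrical coupling model); passing tests demonstrate correctness of the
  *analysis*, not realism of islet dynamics.
* Noise amplitudes are free parameters; absolute consistency values on real
  recordings will differ from synthetic ones.
* The phase grid is integer frames; lags below half a frame interval are
  indistinguishable.
* 2D plane depth is defined on the cell z-extent, not the acquisition
  stack, which may differ when the islet is not centred in the stack.
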