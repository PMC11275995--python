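# Methods

## FRAP preprocessing

A movie is reduced to three per-frame series: `I_bleach(t)` (mean intensity
in the circular bleach ROI, tracked by piecewise-linear interpolation of
sparse anchor positions), `I_nonbleach(t)` (mean over the segmented nucleus
excluding the ROI) and `I_background(t)` (mean outside nucleus and ROI).
Segmentation uses Otsu's threshold computed on the first frame; the mask is
re-derived per frame with that threshold so it follows nuclear drift, and a
user-supplied static mask can replace it. The background region explicitly
excludes the ROI because a deeply bleached spot can fall below the threshold.
Movies whose tracked ROI moves more than 20% of the nucleus equivalent
diameter over any 10-frame span are flagged (not dropped) as
excessive-drift; the ceiling is configurable.

Acquisition photobleaching is corrected with

    C(t) = net_s(t) / ⟨net_s⟩_prebleach,   net_s = smooth(I_nonbleach) − I_background,

where `smooth` is a centered moving average (default width 5 frames, edges
handled by shrinking the window; the width is a free choice, as no canonical
value exists). Using the smoothed series in the denominator makes the
prebleach mean of C exactly 1. The normalized signal is the **double
normalization**

    Ī(t) = [(I_bleach − I_background) / C(t)] / ⟨(I_bleach − I_background) / C(t)⟩_prebleach.

Dividing by C(t) removes a multiplicative decay shared by spot and nucleus
exactly: for noiseless input with exponential photobleaching at rates up to
2×10⁻³ s⁻¹ the corrected curve equals the underlying model to machine
precision when smoothing is disabled (`smooth_window=1`, the appropriate
setting for noiseless data — smoothing is purely a noise-reduction device and
introduces an O((λΔt)²) bias across the phase transition of the frame grid,
of order 10⁻⁴ at the default width; negligible against measurement noise,
visible only in exactness tests). Scale invariance (all three series × k)
holds to 1e−12 by construction.

Times are anchored at the first post-bleach frame (t = 0 there); the
reference schedule is 25 frames at 0.5 s followed by 160 frames at 4 s with
8 prebleach frames, phases contiguous, total 652 s.

## Two-state kinetic fitting

The model `1 − C_f e^(−k_f t) − C_s e^(−k_s t)` is fitted by unweighted
least squares with constraints imposed by reparameterization: total bound
amplitude and its split through logistic transforms (guaranteeing
C_f, C_s ≥ 0 and C_f + C_s ≤ 1) and rates through log transforms (clipped to
[e⁻¹², e¹²] min⁻¹ to keep exponentials finite). Optimization is
Levenberg–Marquardt from 8 starts — the four corners of the rate box
[0.05, 50] min⁻¹ crossed with amplitude assignments (0.1, 0.3) and
(0.3, 0.1) — keeping the best SSE, ties broken toward the smaller slow rate.
A constant-1 candidate competes with the exponential fits so a curve with no
recovery deficit yields zero amplitudes (residence time flagged undefined)
rather than an arbitrary degenerate fit. Components are sorted afterwards so
`k_off,slow < k_off,fast`. Failure of every start returns a fit-failure
result, not an exception.

The fit target is the pointwise mean of the (re)sampled movies, not the mean
of per-movie fits — averaging first suppresses noise where single curves are
least informative and matches how grouped recovery data are normally
modelled. Bootstrap: draw `sample_size` (default 16) curves with replacement
`n_resamples` (default 2500) times, fit each mean curve, and keep the bound
fraction and residence time as one draw; failed or flat fits are dropped and
counted rather than redrawn, so the resample count keeps its interpretation,
and a >50% failure rate raises a warning flag. All resampling is driven by a
single seeded generator; runs are bit-reproducible.

Residence time is reported in minutes. The bound fraction may be normalized
to a reference-condition mean (e.g. wild type) for cross-condition plots.

## Synthetic FRAP data

The renderer draws a hard-edged filled nucleus ellipse (no point-spread
function — sufficient to exercise extraction and correction, not an optics
model) over constant background, multiplies nuclear signal by
`exp(−photobleach_rate·t)`, and after the bleach multiplies spot signal by
`1 − bleach_depth·(1 − recovery(t))`. Bleach depth is deliberately a free
parameter, separate from the model's instantaneous-recovery floor
`1 − C_f − C_s`: normalization, not the generator, determines the fitted
floor. Nucleus and spot drift together at a constant pixels-per-frame
velocity; ROI anchors are emitted every 20 frames so linear drift is
recovered exactly by the interpolating tracker. The generator also returns
the closed-form noiseless trace for oracle comparisons. Pixel noise is
Gaussian and additive; there is no photon shot noise, so passing tests show
correctness of the estimators under the assumed noise model, not robustness
to detector physics.

Default generative conditions used throughout testing: bound fractions 0.2
(fast) / 0.3 (slow), rates 2.0 and 0.5–0.67 min⁻¹ (residence times around
1.5 min), curve noise sd 0.02, 30 movies per dataset — magnitudes typical of
single-nucleus confocal FRAP of sequence-specific factors.

## Synthetic Hi-C data

Expected counts decay as `max(d,1)^α` (default α = −1). A TAD
`(start, end, enrichment)` multiplies within-domain pixels by the enrichment
and divides boundary-crossing pixels (exactly one end inside) by it —
domains both self-associate and insulate, which is what makes their edges
insulation minima in an otherwise homogeneous background. Loops add
multiplicative 2-D Gaussian bumps at anchor pairs. The expected matrix is
scaled to a total depth and Poisson-sampled on the upper triangle, then
mirrored, so sampled matrices are exactly symmetric. No compartment or
replication-timing structure is modelled.

## Hi-C statistics

- **ICE balancing**: rows/columns are iteratively divided by mean-normalized
  marginals until the coefficient of variation of non-masked row sums drops
  below 1e−9 (default) or 1000 iterations; all-zero rows are masked with
  bias 1, and the returned bias vector reconstructs the raw matrix as
  `bias_i·bias_j·balanced`.
- **P(s)**: per-diagonal mean counts (d ≥ 1 bin), aggregated into log-spaced
  bins (10/decade default) by pair-weighted averaging; the representative
  distance of a bin is the pair-weighted geometric mean of its members; the
  curve is normalized to sum to 1, making it depth-invariant.
- **P'max**: log10 P is smoothed with a local-linear tricube-weighted (Loess)
  smoother, span 0.3 by default, derivative by centered finite differences;
  the estimate is the interior strict local maximum of the derivative within
  the search window (50 kb – 2 Mb default). If no interior maximum exists or
  the derivative's range within the window is below 0.01 (a flat/pure power
  law), a no-peak flag is returned instead of a fabricated location. Both the
  peak location and the derivative's value there are reported.
- **Insulation**: for bin i the diamond is the w×w block of contacts between
  the w bins upstream and the w bins starting at i (all pairs crossing the
  bin's left edge); the score is log2 of its mean over the mean of all valid
  diamonds, so it is exactly invariant to global scaling. Default window
  100 kb at 10 kb bins. Boundaries are strict local minima below −0.5
  (configurable), greedily thinned to a minimum separation of w bins.
- **Pileups**: mean of fixed-size windows centered on anchor pairs (matrices)
  or site positions (insulation tracks); anchors whose window leaves the
  matrix are excluded and counted. Depth equalization across samples is
  available as seeded binomial thinning.

All matrix operations are per-chromosome; trans contacts are out of scope.

## Associations

Ordinary least squares of a genomic summary on a kinetic parameter across
conditions; R² = 1 − SSE/SST and the slope F-test p-value (identical to the
slope t-test for one predictor). A constant response returns R² = 0, p = 1;
an exact fit is flagged and its p-value floored at 1e−300 instead of
underflowing to 0. For the small condition panels typical here an exact
permutation p-value (all n! orderings for n ≤ 8, otherwise 10⁴ seeded
permutations) is available. Interval overlap between two BED files counts a
query interval as overlapping if it shares ≥ 1 bp with any reference
interval (half-open coordinates).

## Problem sizes and numerical choices

Validation simulations use 20 datasets of 30 curves for point-estimate
recovery, 500 bootstrap resamples of 16 across 20 meta-replicates for
interval calibration, 50–300-bin matrices at 10 kb for the Hi-C oracles, and
5 seeds for the loop-size recovery — sizes at which every stochastic check
is stable under reseeding while the full suite stays inexpensive. The
independent oracles are brute-force computations: per-diagonal averaging,
diamond sums, dense numerical differentiation of an analytic P(s), a 15⁴
grid search over the kinetic parameter box, and closed-form OLS formulas.

## Known limitations

Manual curation steps of the original protocol (GUI-based ROI updates,
manual drift exclusion, hand-tuned segmentation) are replaced by their
scriptable counterparts (anchor interpolation, a drift flag, Otsu
segmentation). The two-state fit assumes the reaction-dominant regime; it
will silently mis-describe diffusion-limited recoveries. P'max on sampled
matrices is quantized to the log-distance grid and sits on the rising edge
of the loop bump, so it systematically reads slightly below the placed loop
separation. Insulation boundary calls use a fixed global threshold, not a
significance model.
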