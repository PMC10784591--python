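# Methods

This note records the models implemented in `smlmclust`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Photophysics model

A photoconvertible fluorescent protein is modeled with four states:
nonactive (N), active/emitting (A), reversible dark (D) and bleached (B).
Transitions: N→A at `k_a` (photoactivation), A→B at `k_b` (photobleach),
A→D at `k_d` (dark conversion), D→A as a two-component exponential
mixture — fast rate `k_r2` with weight `alpha`, slow rate `k_r1`.
Consequences used throughout:

* blink count before bleaching is geometric with dark-branch probability
  `h = k_d/(k_d + k_b)`; mean `⟨N_blink⟩ = k_d/k_b`;
* on-times are Exp(`k_b + k_d`);
* expected localizations per molecule (*multiplicity*) is
  `1 + ⟨N_blink⟩ = 1/(1 − h)`.

Only derived quantities of this scheme are experimentally reported
(`⟨N_blink⟩ = 1.7` at 33 ms/frame, hence multiplicity 2.7); the absolute
rates are free parameters. Defaults: `k_a = 0.05 /s`, `k_b = 10 /s`,
`k_d = 17 /s` (fixing `k_d/k_b = 1.7`), `k_r1 = 2 /s`, `k_r2 = 50 /s`,
`alpha = 0.2`. The recovery rates were chosen so dark times sit mostly
between one frame (33 ms) and the 2.5 s dark-time threshold used for
trace grouping: much shorter and re-blinks merge at frame resolution,
much longer and single molecules split into multiple traces. All defaults
are overridable.

### Emission model of the field generator

Each emission burst (on-interval) produces exactly **one** localization,
stamped at the frame containing the burst midpoint, so a molecule yields
`1 + N_blink` table rows. This matches the counting convention in which
cluster localization counts divided by `1 + ⟨N_blink⟩` give molecule
numbers; it deliberately does not model one detection per camera frame
during long bursts (with the default `⟨T_on⟩ ≈ 37 ms` the distinction is
a ~10% effect that the multiplicity bookkeeping would then have to
absorb). Localization noise is isotropic Gaussian with SD `precision_nm`
(default 20 nm); per-localization uncertainties are drawn from a narrow
lognormal around the precision (CV 0.2) so the KDE stage sees realistic
spread.

`add_noise_localizations` plants a configurable fraction (2% in the
validation workflows) of spurious localizations with uncertainties far
outside the single-molecule range, uniformly over the field. Real
localization tables contain such false detections, and the percentile
uncertainty filter exists to remove them; without this population the
filter would discard genuine signal and bias counting low by the filtered
fraction.

## Trace grouping and blink fitting

Calibration tables (immobilized emitters) are grouped into traces:
a localization joins the nearest open trace within a spatial gate of its
running centroid, provided the frame gap is at most the dark-time
threshold (default 2.5 s). The gate is `link_radius · sqrt(1 + 1/n)` for
a trace of `n` localizations, default `link_radius` = 4× the median
uncertainty. The widening term accounts for the noise of a young trace's
centroid: the distance between a re-blink and a single-point trace is
Rayleigh with scale √2 × precision, and a plain 3σ point gate splits
about 1% of re-blinks into spurious traces — enough to violate a 2%
trace-count budget at `⟨N_blink⟩ = 1.7`.

The geometric law is fitted by its closed-form maximum-likelihood
estimator `h = m/(1 + m)` (`m` = sample mean blink count), which avoids
any binning choice; the fitted-vs-empirical histogram is kept as a
diagnostic. On-time fitting distinguishes continuous samples (rate =
1/mean, the exponential MLE) from frame-quantized samples: the number of
frames spanned by a burst is not geometric in its first bin (the single-
frame bin is censored by the burst's random phase against the frame
grid), so the rate is estimated from the `k ≥ 2` tail, where
memorylessness makes the distribution exactly geometric with ratio
`exp(−rate·Δ)`. Intensity distributions are fitted as lognormal mixtures
(Gaussian mixtures on log intensities) with the component count selected
by AIC and BIC; disagreement between the criteria is reported rather than
silently resolved.

## KDE segmentation and counting

The existence-probability map is the average of isotropic Gaussian
kernels centered on each localization with SD `A·u_i` (default `A = 6`),
evaluated at pixel centers and truncated where either axis offset exceeds
4 SD. Raster resolution defaults to 20 nm/pixel — finer than the 47.1 nm
camera pixel, comparable to the localization precision; the map then
integrates to 1 within ~0.1% (truncation aside), and the implementation
is tested against a brute-force kernel sum at random pixels to 10⁻⁶
relative error.

Thresholding uses classical Otsu on the histogram of map values: 256
equal-width bins over [min, max], exhaustive maximization of the
between-class variance, ties broken toward the lower threshold. (The
intra-class "variance" objective sometimes written for this procedure
reduces algebraically to the global mean of the map and cannot select a
threshold; the classical histogram criterion is what the method's own
citation defines.) The mask is `p ≥ θ`; 8-connected components with at
least `min_cluster_pixels` (default 4, suppressing single-pixel threshold
noise) become clusters. Counting is strictly mask-interior: each
localization falls in pixel `(floor(x/px), floor(y/px))` and increments
the cluster owning that pixel; corrected counts divide by the
multiplicity. Boundary pixels are mask pixels with at least one
background neighbour and count as inside for all downstream analyses.

Cluster statistics report the overall mean corrected count, per-cell
means with SEM (one input table per cell), and the "large-cluster
density": summed corrected counts over clusters above a configurable
threshold (default 800 molecules) per µm² of cell area.

## Coordinate-based colocalization

Radial profiles `D(r_j) = N(r_j)/N(R_max) · R_max²/r_j²` are built over
`r_j = dR, …, R_max` (defaults 50 and 500 nm) for both channels around
each localization, excluding the localization itself from its own-channel
counts (including it adds a constant shared across radii and distorts
small-count profiles). Scores are skipped when **both** channels have
fewer than `min_count = 5·R_max/dR = 50` neighbours within `R_max` (an
either/or variant is available by flag). The Spearman correlation is
computed on `counts_j/j²`, a positive scalar multiple of `D(r_j)`: with
integer operands, mathematically tied profile values are exactly tied
floats, making tie handling independent of floating-point association
order. Profiles with fewer than three distinct values leave the score
undefined (absent, counted). The final score multiplies the correlation
by `exp(−E/R_max)` with `E` the true (uncapped) nearest-neighbour
distance to the other channel. Neighbour search uses an exact k-d tree
and is verified against an all-pairs brute-force implementation to
10⁻¹². Histograms use bin width 0.1 (20 bins over [−1, 1]) so the
colocalization index — the summed frequency over [0.7, 1.0] — covers
exactly three bins.

Two caveats worth knowing. First, CBC scores within one field share the
channel realization and are strongly correlated: null checks must be run
over replicate simulations, not per-localization standard errors. Second,
when `R_max` is comparable to the field size, boundary truncation
depresses both channels' profiles at large radii identically and induces
a positive score bias even for independent channels; fields (or cells)
should be large relative to `R_max`.

## Residency analysis

Within-mask run durations are maximal runs of consecutive-frame samples
whose positions fall inside any cluster mask; a missing frame ends a run,
and runs touching a trajectory's first or last sample are flagged
censored and excluded from lifetime fitting by default (exclusion biases
the estimate by only `(1/τ + 1/τ_bleach)⁻¹` relative to `τ`, under 2%
for 150 ms dwells against 7.3 s bleaching). The lifetime is fitted by
least squares of `A·exp(−t/τ)` through the duration histogram at
frame-interval binning, empty bins included — dropping them would
truncate the sparse tail and bias `τ` upward — and the 68.3% confidence
limit comes from the fit covariance. Durations are reported at integer
frames, so the realized run of a dwell `D` starting at a frame boundary
is `ceil(D/Δ)` frames; the geometric tail of that distribution has
exactly the ratio `exp(−Δ/τ)`, which is what the histogram fit measures.

Randomized control trajectories are translated so the first sample lands
on a uniformly random in-bounds pixel (integer-pixel offsets on the
segmentation raster), rejection-sampled until the whole trajectory fits;
a single shared shift constant keeps internal displacement vectors intact
to float precision. Molecule-density histograms count localizations
within a fixed radius (default 100 nm; smaller radii are allowed but
warned against, as quarter-area counts make the difference histogram
fluctuate) around every spot-frame, divide by the multiplicity, bin at
one molecule per bin from zero, and normalize by observation period and
area. The observed-minus-randomized difference histogram is summarized
over the longest contiguous run of strictly positive bins by its sum and
its difference-weighted mean count (the weighted-mean convention is
recorded in the output metadata, as a midpoint convention would also be
defensible).

## Trajectory generator

Synthetic trajectories alternate unbound periods (Exp(`free_tau_ms`),
default 300 ms, Gaussian random-walk steps kept outside masks) and bound
dwells (Exp(`residency_tau_ms`) spent inside a randomly chosen cluster
mask), truncated at a photobleach time Exp(`bleach_tau_s`, default
7.3 s). Binding teleports the molecule into the cluster and unbinding
steps it just outside — the generator makes no attempt at diffusion-
limited encounter kinetics, only at the dwell/visit statistics the
residency analysis estimates. Ground truth records each dwell's
continuous duration, its realized in-mask sample count and a bleach-
censoring flag.

## What the generator does not emulate

Raw camera images (PSF shape, shot noise, pixelation), spot detection and
its failure modes, drift and drift correction, sample movement, two-
camera registration error, multi-emitter fitting artifacts, and
astigmatic 3-D localization are all outside the generator. Passing
recovery tests therefore validates the analysis stages downstream of
localization, not the upstream image-processing chain; on real data the
pipeline inherits whatever biases the spot detector introduces.
Calibration photophysics measured on immobilized purified protein may
also differ from intracellular behaviour, which is why every counting
entry point accepts a user-supplied multiplicity override.

## Numerical choices and degenerate inputs

* Coordinates are continuous nm, origin lower-left, y up; pixels are
  half-open, 0-based, `floor(x/px)`.
* Otsu requires at least two distinct map values; constant maps raise.
* Geometric fits require ≥ 50 traces; an all-zero blink sample warns and
  returns `h = 0`. On-time fits require ≥ 50 values and at least two
  distinct ones; lifetime fits require ≥ 30 events and non-constant
  durations.
* Welch's t-test requires n ≥ 2 per sample and nonzero variance in at
  least one; the Holm–Šidák step-down compares sorted p-values with
  `1 − (1−α)^(1/(m−i+1))` and reports monotone adjusted p-values.
* Statistical guards (min-count skip rules, underpowered-sample flags)
  fail loudly or mark results absent rather than returning zeros.
* Problem sizes in the validation workflows — 5 000 traces, 100×52 and
  200×20 cluster fields, 2 000 dwell events and 2 000 bleach times —
  were chosen so each recovered quantity's sampling error is a few
  percent, well inside the tolerance it is checked against.

## Known limitations

* The trace-grouping gate assumes immobile emitters; mobile calibration
  data would need a tracking-based grouper.
* Dark-time structure (`k_r1`, `k_r2`, `alpha`) is a simulation-side
  assumption; the calibration path estimates only `h` and `k_b + k_d`.
* CBC edge bias (above) is not corrected; the rotation control shares it,
  which is precisely why the control is informative.
* Per-cluster corrected counts are unbiased on average but noisy for
  small clusters (geometric blink variance); comparisons should use the
  cluster-population statistics, not single clusters.
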