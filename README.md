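# smlmclust

Quantitative cluster analysis for single-molecule localization microscopy
(PALM/dSTORM), built around the question "how many molecules are in that
cluster, and who visits it?". The package is aimed at quantitative cell
biologists analyzing localization tables (ThunderSTORM-style CSV) of
photoconvertible-protein imaging — for example STING clustering at the
trans-Golgi network and the transient recruitment of TBK1 to those
clusters — and at method developers who need a fully synthetic,
ground-truth-controlled test bed for such pipelines.

## What it computes

**Blink calibration and molecule counting.** A photoconvertible
fluorophore such as mEos4b blinks: after activation it cycles through a
reversible dark state `N_blink` times before photobleaching. With dark
rate `k_d` and bleach rate `k_b`, the blink count is geometric,

    P(N_blink = n) = h^n (1 − h),    h = k_d / (k_d + k_b),

so `⟨N_blink⟩ = k_d/k_b` and one molecule yields on average
`1 + ⟨N_blink⟩` localizations (the *multiplicity*; 2.7 at 33 ms/frame for
the calibration shipped as default). Dividing per-cluster localization
counts by the multiplicity gives unbiased molecule counts.

**KDE segmentation.** The localization set is rendered as an
existence-probability map, the average of per-localization Gaussian
kernels with SD `A·u_i` proportional to each localization's uncertainty
(`A ≈ 6`). The map histogram is bimodal (clusters vs background), so a
classical Otsu threshold separates them; 8-connected supra-threshold
components are clusters with areas, boundaries and corrected molecule
counts.

**Coordinate-based colocalization (CBC).** For each localization, the
radial density profiles of its own and the other channel
(`D(r_j) = N(r_j)/N(R_max) · R_max²/r_j²`, `r_j = 50 … 500 nm`) are
compared by Spearman rank correlation and weighted by
`exp(−E/R_max)` with `E` the nearest-neighbour distance, giving a score
in [−1, 1] per localization; a 180°-rotated channel is the negative
control.

**Cluster residency.** Tracked single molecules (e.g. a kinase visiting
clusters of its scaffold) yield within-mask run durations; a
single-exponential fit of the duration histogram gives the residency
lifetime, with log-rank comparisons, shape-preserving randomized
trajectories as the in-silico null, and local molecule-density
difference histograms around tracked spots.

**Synthetic data.** Every stage is backed by a generator with the
matching statistical structure — four-state photophysics (geometric
blinks, exponential on-times, bi-exponential dark times), clustered 2-D
fields at 20 nm precision, two-channel colocalized/segregated fields, and
trajectories with exponential dwell and photobleaching — so recovery of
known ground truth can be tested end to end.

## Worked example

```python
from smlmclust import (
    ClusterSpec, KineticModelParams, grid_centers, simulate_cluster_field,
    add_noise_localizations, filter_uncertainties, compute_kde_map,
    otsu_threshold, segment_clusters, BlinkCalibration, cluster_statistics,
)

params = KineticModelParams(k_d=17.0, k_b=10.0)      # h = 0.63, <N_blink> = 1.7
cal = BlinkCalibration.from_rates(k_d=17.0, k_b=10.0)
print(f"multiplicity (localizations per molecule): {cal.multiplicity:.2f}")

spec = ClusterSpec(centers=grid_centers(25, spacing_nm=2000.0),
                   molecules_per_cluster=52, cluster_radius_nm=60.0)
table, truth = simulate_cluster_field(spec, params, seed=42)
table = add_noise_localizations(table, fraction=0.02, seed=42)
print(f"simulated localizations: {len(table)}")

filtered = filter_uncertainties(table, 1.0, 99.0)
kde = compute_kde_map(filtered, A=6.0, grid_pixel_nm=20.0)
theta = otsu_threshold(kde)
clusters = segment_clusters(kde, theta, cal.multiplicity, filtered)
stats = cluster_statistics(clusters)
print(f"clusters found: {len(clusters)}")
print(f"mean molecules per cluster: {stats.mean_per_cluster:.1f}")
```

prints

```
multiplicity (localizations per molecule): 2.70
simulated localizations: 3579
clusters found: 25
mean molecules per cluster: 52.0
```

Twenty-five synthetic clusters of exactly 52 molecules each were rendered
through the blinking model (~2.7 localizations per molecule, so ~3 500
rows), segmented from the KDE map, and the blink-corrected mean lands on
the true 52.

A command-line interface mirrors the library
(`smlmclust simulate|calibrate|segment|count|cbc|recruit`), each
subcommand taking `--config`, `--seed` and `--out` and writing CSV/JSON
results plus a machine-readable run log.

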