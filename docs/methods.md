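# Methods

This note documents the models, numerical choices and limitations of the
`ecoregions` package: what each stage computes, which knobs matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Anomaly computation

Per cell, the monthly climatology (mean of all Januaries, all Februaries, …)
is subtracted first, then an ordinary-least-squares linear fit against the
month index (slope and intercept). The two projections commute only
approximately; the order climatology-then-trend is fixed for
reproducibility. Both operations are idempotent, preserve the land mask and
coordinates, and require at least two full years (climatology) or three time
points (trend). By default the full record is detrended before any time-slot
slicing; per-slot detrending is available via `PipelineConfig(detrend_scope=
"slot")` — the two differ when trends vary across decades, and full-record
detrending is the stabler default for sweeps with overlapping windows.

## Domain identification

*Local homogeneity* of a cell is the mean Pearson correlation over all
unordered pairs within the cell plus its K nearest ocean cells (K = 4 by
default). "Nearest" is great-circle distance, computed as unit-sphere chord
length and searched within a Chebyshev window of 2 cells, so neighborhoods
truncate at coasts and never jump across land; geometrically tied distances
are quantized (12 decimals of chord length) and broken by grid index so the
neighborhood is deterministic. Zero-variance cells are undefined: they are
excluded as centers and neighbors and can never become cores.

*Cores* are cells whose homogeneity strictly exceeds that of every defined
neighborhood member and exceeds δ. *Expansion* is globally best-first: a
single priority queue over (domain, frontier-cell) candidates ordered by the
average pairwise correlation the domain would have after adding the cell,
ties broken by grid index; a candidate is accepted while that average stays
≥ δ. Since a domain's candidate priorities change whenever it grows, its
whole frontier is re-pushed on growth and stale heap entries are skipped, so
the first fresh entry popped is the true global best. *Merging* runs after
expansion: adjacent domain pairs whose union still has average pairwise
correlation ≥ δ are merged, best pair first, until none remains. Merging is
restricted to 4-adjacent pairs because domains must stay 4-connected.
Incremental sums make each candidate evaluation O(T): with series normalized
so that z_i·z_j is the correlation, a domain keeps Σz (its member sum) and
the running sum of within-pair correlations.

The threshold δ defaults to 0.545, the midpoint of the 0.54–0.55 band that
the significance-level calibration targets; `delta_from_alpha(α, T)` =
t*/√(T−2+t*²) with t* the two-sided t quantile at T−2 degrees of freedom is
available, as is a per-slot-length α table (1e-3 for 4-year validation
windows, 6e-5 / 2e-5 / 3e-6 for 6 / 7 / 8-year slots). The plain t-mapping
with those α values yields δ ≈ 0.44 at T = 84, visibly below the 0.54–0.55
band; since the exact mapping that produces the band is not derivable, the
direct δ override is the default and α mode is opt-in.

Domains are disjoint: a cell belongs to the first domain that claims it in
best-first order. High within-domain correlation (snr well above 1) makes
the average-correlation acceptance rule permissive near domain peripheries,
so recovered domains absorb adjacent background cells up to roughly a third
of their size; with the default 90% region coverage this inflates domains by
only a few percent.

## Network inference

Domain signals are cosine-latitude-weighted sums of member anomaly series
(cos of the cell-center latitude in radians, an area proxy on a regular
grid). Cross-correlations r_AB(τ) use the overlapping T−|τ| samples per lag,
τ ∈ [−12, 12] months by default.

Significance per lag follows Bartlett's approximation for the variance of
the cross-correlation of two independent autocorrelated series:
var ≈ (1/(T−|τ|))·Σ_k ρ̂_A(k)·ρ̂_B(k), the sum over k = −K…K with sample
autocorrelations (biased estimator, FFT) truncated at K = min(T/3, 50) —
a standard truncation; terms beyond it are negligible for the monthly
persistence levels involved. A non-positive variance estimate is clamped to
the white-noise floor 1/(T−|τ|). The statistic r/√var is referred to a t
distribution with T−2 degrees of freedom at two-sided level 0.03 (a normal
reference is a config switch; at T ≥ 84 the two are nearly identical).

Testing 2·τ_max+1 = 25 lags per pair is uncorrected by default
(`lag_correction="none"`), which inflates the per-pair false-edge rate to
≈ 1−(1−level)^25 ≈ 0.53 and can contaminate a true edge's lag set with an
isolated opposite-sign lag, flipping its direction label to "undirected".
`lag_correction="sidak"` deflates the per-lag level to 1−(1−level)^(1/25),
making the per-pair false-edge probability equal the nominal level; the
recovery and null-calibration analyses use this mode and the documented
caveat stands for the default.

Edge direction: strictly positive significant lags → A→B, strictly negative
→ B→A, any set containing 0 → undirected. A mixed-sign set without 0 (not
produced by the rule's intended cases but possible with false lags) is
conservatively labeled undirected. The weight is the sample covariance
(denominator N−1) of the aligned overlap at the |r|-maximizing significant
lag (ties: smaller |τ|, then positive τ); weight and correlation share sign
by construction. Strength is the sum of incident |w|, so Σ_A strength(A) =
2·Σ_edges |w|.

## KE fronts and segmentation

KE = ½(u²+v²) per unit mass. The front threshold is the q-th percentile
(linear-interpolation convention) of KE over all ocean cells and all months
of the reference period; the front mask marks cells whose slot-mean KE
exceeds it. The boundary matrix marks ocean cells with at least one
4-neighbor of a different domain label (background counts as a label; a
differing *land* neighbor does not create a boundary by default —
`coast_as_boundary=True` switches that), then applies one binary dilation
with the 3×3 structuring element ("augmented by one grid point in each
direction"). The overlap fraction is |boundary ∧ front| / |boundary|.

K-means segmentation is 1-D on slot-mean KE intensities (k = 4, 10 restarts,
fixed seed), clusters relabeled by increasing centroid; the maximum-
intensity cluster indicates KE fronts and its pixel count measures their
abundance. Front occurrence counts, per cell, the slot months with KE above
the full-record threshold.

## Synthetic generator

The generator plants everything the analysis assumes, with defaults chosen
once as the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| grid | 40×40 at 0.375° | Mediterranean-like latitudes 30–45°N; equal degree spacing keeps the K=4 neighborhood von Neumann below 60° |
| record | 30 years monthly | a reanalysis-length record (T = 360) |
| regions | 4, covering 90% of the ocean | basin mostly partitioned, a thin background margin |
| latent AR(1) | 0.5 | moderate month-to-month SST-anomaly persistence |
| snr | 5 | per-cell noise std = latent std / 5; within-region pair correlation ≈ 0.96 |
| seasonal | 2 °C pure 12-month sinusoid | removed exactly by the monthly climatology |
| trend | 0.04 °C/yr | a realistic basin warming rate |
| couplings | 1→2 (+0.5, lag 3), 3→4 (−0.45, lag 5) | one positive and one negative directed link; lag-0 leakage 0.5·0.5³ ≈ 0.06 keeps coupled regions separable at δ = 0.545 |
| jets | 0.3 m/s, half-width 1 | boundary-current speed; the axis (the two-cell interface band) dilated once, since real jets are mesoscale-wide, not one grid point |
| background currents | 10% of jet speed, per-cell factor U(0.5, 1.5), 1% monthly noise | heterogeneous quiet ocean; small temporal noise so slot-mean KE cleanly reflects planted geometry |

Regions grow by seeded random breadth-first accretion from farthest-point
seed cells, round-robin so sizes stay balanced; single-cell background
pinholes (every ocean neighbor in one region) are filled, as they are
accretion artifacts rather than meaningful background. Latents are
unit-variance AR(1); a coupled target is rebuilt as c·source(t−lag) +
√(1−c²)·own and re-standardized, so the planted cross-correlation at the
coupling lag equals c. Couplings are validated to be chain-free with unique
targets and lags within ±τ_max. Jets carry speed along the boundary tangent
of the nearest axis cell; land cells are NaN in every field.

What the generator does *not* emulate: ocean dynamics of any kind —
mesoscale turbulence, realistic coastlines, advection actually coupling SST
to the velocity field (SST and jets are planted consistently but not
dynamically linked), spatially correlated noise, missing data. Passing
recovery tests therefore demonstrates the statistical machinery — that the
pipeline recovers exactly the structure its assumptions describe — not that
the assumptions hold in any particular ocean.

## Problem sizes in tests and the acceptance script

Recovery statistics use 20 seeded fields at the default conditions;
significance calibration uses 2,000 independent AR(1) pairs (coefficient
0.8, T = 360); the null-edge count uses 30 repetitions of 10 independent
signals; the fragmentation suite uses six 7-year slots with 2–7 planted
regions and fixed jet speed, so region count drives jet extent and hence
mean KE. These sizes give stable statistics (the whole battery runs in about
half a minute on one CPU).

## Known limitations

- Expansion can absorb unstructured cells adjacent to very coherent domains
  (see above); boundaries are accurate to roughly one cell, which is why the
  boundary matrix is dilated before overlap scoring.
- The α→δ mapping matching the 0.54–0.55 calibration band is not derivable
  from a plain t-test; δ is therefore set directly by default.
- No multiple-testing correction across lags by default (see caveat above),
  and none across domain pairs in either mode.
- The east/west basin partition is a configured split meridian, not a
  geographic polygon; trend-period breakpoints are config inputs, not
  detected.
- `compare_networks` matches counterpart domains by spatial Jaccard ≥ 0.3,
  which can fail to match after drastic re-fragmentation; unmatched
  counterparts are reported as lost/gained edges.
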