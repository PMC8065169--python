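# ecoregions

Connectivity-based ocean ecoregionalization from gridded sea-surface
temperature (SST) fields.

Marine ecoregions — areas with relatively homogeneous ecosystem and
connectivity properties — are usually inferred by computationally expensive
Lagrangian particle tracking. This package implements the cheap alternative:
a complex-network analysis of monthly SST anomalies. Because SST anomalies at
mid latitudes are shaped by horizontal advection on monthly-and-longer time
scales, spatially contiguous sets of highly correlated SST cells delineate
water bodies with common dynamics, and their lagged cross-correlations trace
directed connectivity between them. The package is aimed at physical and
ecological oceanographers who want basin-scale, decade-resolved
ecoregionalization from reanalysis or satellite SST plus velocity fields.

## Method

**Domain identification.** Each grid cell *i* carries a deseasonalized,
detrended anomaly series *x_i(t)*. The *local homogeneity* of a cell is the
average pairwise Pearson correlation within its K-neighborhood (the cell and
its K nearest ocean cells; K = 4 is the von Neumann neighborhood away from
coasts). Cells whose homogeneity is a strict local maximum above a threshold
δ are *cores*; cores are expanded best-first (always adding the adjacent cell
that keeps the domain's average pairwise correlation highest, while it stays
≥ δ) and adjacent domains whose union still averages ≥ δ are merged. The
result is a set of spatially contiguous, disjoint *domains* (ecoregions).
δ can be set directly (default 0.545) or derived from a significance level α
via the t distribution: δ = t*/√(T−2+t*²).

**Network inference.** Each domain *A* gets a signal

    X_A(t) = Σ_{i ∈ A} x_i(t) · cos φ_i

(φ_i the cell latitude, so cell weights scale with cell area). For every pair
(A, B), the Pearson cross-correlation r_AB(τ) is computed for lags
τ ∈ [−τ_max, τ_max] (default 12 months). Each lag is tested at level 0.03
against a null variance that sums the products of the two signals' sample
autocorrelations (Bartlett's formula), so the serial correlation of the
signals does not inflate significance. Domains are linked if any lag is
significant; a strictly positive (negative) significant-lag set makes the
link directed A→B (B→A), a set containing 0 leaves it undirected. The edge
weight is the covariance at the |r|-maximizing significant lag, and a
domain's *strength* is the sum of incident absolute weights.

**KE-front validation.** Kinetic energy per unit mass, KE = ½(u²+v²), is
computed from the velocity components. Fronts — jets, persistent currents,
large eddies — are cells whose slot-mean KE exceeds a basin-wide percentile
(50th/60th) of the full-record KE. Validation computes the overlap between
the domain-boundary matrix (boundaries dilated by one grid point) and the
front mask. Per time slot, the slot-mean KE map is also segmented by 1-D
K-means into four intensity clusters; the pixel count of the maximum-
intensity cluster measures front abundance, and per-cell counts of months
above the front threshold measure front persistence.

**Time-slot analysis.** The record is swept with Δ-year windows
[yr_ini, yr_ini+Δ) sliding yearly (Δ = 6–8, default 7; windows straddling a
configured trend breakpoint by more than one year are excluded). Per slot the
pipeline reports the number of domains (*fragmentation*), the network, the
mean KE and the front statistics; across slots it correlates fragmentation
and mean strength with mean KE, optionally split at a meridian into eastern
and western sub-basins.

Because real reanalysis inputs are multi-gigabyte downloads, the package
ships a first-class synthetic generator (`ecoregions.synth`) that plants
contiguous regions sharing lag-coupled AR(1) latent signals, a seasonal cycle
and a warming trend, plus velocity jets along region boundaries — everything
needed to test recovery of domains, edges, and front overlap against known
ground truth.

## Worked example

```python
import ecoregions as er

cfg = er.SynthConfig(seed=3)                 # 40x40 grid, 30 y, 4 regions
truth = er.generate_truth(cfg)
sst = er.generate_sst(truth, cfg)
u, v = er.generate_velocity(truth, cfg)

anoms = er.anomalies(sst)                    # deseasonalize + detrend
domains = er.identify_domains(anoms, K=4, delta=0.545)
net = er.infer_network(er.domain_signals(domains, anoms),
                       tau_max=12, level=0.03, lag_correction="sidak")

ke = er.kinetic_energy(u, v)
thr = er.ke_threshold(ke, 50)
bm = er.boundary_matrix(domains.label_map(), ke.mask)
print(er.overlap_fraction(bm, er.front_mask(ke, thr, 50)))
```

prints (abbreviated):

```
4 domains (delta = 0.545)
  domain 1: 382 cells, 70 cores
  ...
  edge 1-3: A->B, tau*=5, r=-0.47, w=-38678.3
  edge 2-4: B->A, tau*=-3, r=+0.39, w=+30970.7
KE 50th percentile threshold: 0.00061 m2/s2
boundary-front overlap: 0.80
```

The four planted regions are recovered as four domains; the two planted
lagged couplings (1→2 at +3 months, 3→4 at +5 months with negative sign)
appear as the two directed edges with the right lags and signs, and 80% of
the recovered domain boundaries coincide with kinetic-energy fronts — the
synthetic analogue of boundary currents separating ecoregions.

A `click` CLI wraps the same steps for NetCDF inputs:
`ecoregions synth | anomalies | domains | network | fronts | run | compare`
(see `ecoregions --help`).

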