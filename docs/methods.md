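# Methods

This note records the models implemented in `nicheevo`, the conventions
chosen where the underlying methodology leaves room, and what the
synthetic study system does and does not emulate.

## Bioclim-style predictors

Each 12-month series is summarised by the temperature-family bioclim
transformations. Conventions:

- **Seasonality (BIO4)** is the *sample* standard deviation (ddof = 1) of
  the 12 monthly values multiplied by 100, the convention of the
  mainstream bioclim tooling. `seasonality_scale` and `ddof` arguments
  expose the raw population SD for users who prefer it.
- **Quarters** are three consecutive months with December→January
  wrap-around; ties between windows resolve to the earliest start month.
- **Day/night pairs** treat the daytime series as the daily maximum and
  the night-time series as the daily minimum, which defines mean diurnal
  range (BIO2 = mean month-wise day−night difference) and isothermality
  (BIO3 = 100·BIO2/BIO7). BIO3 is defined as 0 when the annual range
  BIO7 vanishes (constant series), keeping it bounded.
- **Variable numbering.** The thirty predictors are blocked
  MIR (X1–X7), day/night LST (X8–X16), NDVI (X17–X23), EVI (X24–X30).
  Within a single-series block the order is BIO1, BIO5, BIO6, BIO4,
  BIO10, BIO11, BIO7; within the day/night block BIO1, BIO2, BIO3, BIO5,
  BIO6, BIO4, BIO10, BIO11, BIO7. This places MIR seasonality at X4, MIR
  annual range at X7 and LST seasonality at X13, the names used when
  interpreting component loadings.

A cell masked in any input stack is masked in all thirty outputs.

## Ordination and backgrounds

Because the predictors mix units (kelvins/degrees vs. unitless
reflectance indices), PCA operates on the correlation matrix: variables
are centred and scaled by their sample SD before the rotation. Retention
follows the Kaiser rule with a strict eigenvalue > 1 cut (ties at exactly
1 excluded); component signs are fixed so the largest-magnitude loading
of each component is positive. The per-variable Pearson correlation with
each retained score is computed empirically and reported alongside the
loadings.

The PCA feeding the clade envelope models is trained on the full valid
extent by default; the pairwise overlap analyses train their own PCA on
the union of the two clades' background cells (`sdm_pca_scope` switches
the former to pooled backgrounds). A clade's background is every cell
whose centre lies within `buffer_km` (default 100 km) of any record,
by haversine distance on a spherical Earth of radius 6371 km.

## Envelope suitability

The boxcar envelope stores the empirical distribution of training scores
per retained component. The suitability of a query is the per-axis
percentile score s = 1 − 2|F(x) − 0.5| with the midpoint empirical CDF
F(x) = (#{v < x} + ½·#{v = x})/n, aggregated across axes by the minimum
and clamped to exactly 0 outside the per-axis min–max box. This
continuous dialect peaks at 1 at the axis medians and treats every axis
equally — no weighting, no interactions. The classic presence/absence
box is available with `mode="binary"`. A constant training axis is
degenerate (its score is 1 at the training value and 0 elsewhere) and is
reported with a warning at fit time.

## Overlap in environmental space

Occurrences and backgrounds of a clade pair are projected onto the first
two components of their pooled-background PCA. Densities are evaluated
on an r × r lattice (default r = 100) spanning the pooled background
envelope expanded by a 5% margin per axis:

- **Kernel density.** Gaussian product kernel with per-axis
  normal-reference (Silverman) bandwidths, h_j = σ_j (4/(d+2))^{1/(d+4)}
  n^{−1/(d+4)} with d = 2; a fixed bandwidth pair can be supplied
  instead.
- **Occupancy correction.** z ∝ o/e where o is the occurrence density
  and e the background density, restricted to lattice cells that contain
  at least one actual background point (e additionally floored at
  1e−12); z is zero elsewhere and normalised to unit mass. The
  restriction matters: the smoothed e decays into environments that were
  never observed, and the raw ratio there is pure noise — without the
  restriction, replicate samples from one and the same niche can show
  spuriously depressed overlap. Uncorrected densities (z ∝ o) are
  available via `occupancy_corrected=False`.
- **Schoener's D** = 1 − ½ Σ|z₁ − z₂|, in [0, 1]; verbal classes none /
  low / moderate / high / very high on 0.2-wide bins.
- **Equivalency test.** Pool both clades' records, re-split at the
  original sample sizes, recompute D; repeated `n_reps` (default 100)
  times. Rejection when the observed D falls outside the simulated 2.5th
  to 97.5th percentile band.
- **Similarity test.** Simulated overlaps pair the focal clade's records
  with pseudo-records drawn uniformly (with replacement) from the other
  clade's background cells, matching the other clade's sample size; run
  in both directions, same two-sided 95% band.
- **P-values** use the add-one permutation correction,
  p = 2·(min(#{sim ≤ obs}, #{sim ≥ obs}) + 1)/(n_reps + 1), capped at 1.
  With 100 replicates the saturating value is 2/101, which rounds to
  0.02.

Components beyond the first two are deliberately ignored in overlap
analyses.

## Ancestral tolerance reconstruction

A PNO profile bins a clade's envelope suitability over one PC-score
raster into 100 evenly spaced categories of the observed PC range,
normalised to a probability distribution. Per Monte-Carlo iteration
(default 1000) and PC, one tolerance value per clade is drawn from its
profile (bin centres, no within-bin jitter) and internal node states are
estimated under Brownian motion by generalized least squares: the
estimate at a node is (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹y with V the tip covariance about
that node, obtained by the re-rooting identity — exact under BM and
verified in the tests against an independent R implementation
(`phytools::fastAnc`). Uncertainty in the tree is absorbed by cycling
deterministically through a supplied set of ultrametric trees (for
example age-jittered pseudo-posterior samples) across iterations.

Node clouds are summarised by their mean and the 80% **central density
interval**, implemented as the equal-tail 10th–90th percentile interval
(linear interpolation). A highest-density variant was considered and
rejected as a default because the sampled clouds are effectively
unimodal; equal-tail intervals are also stable at the default sample
size.

## Synthetic study system

The generator emulates the analysis inputs, not the sensor physics:

- **Rasters.** Five monthly stacks on a WGS84 cell-centre-registered
  lat/lon grid (default 0.25°, 50 × 50 cells over the western
  Mediterranean). Each variable is a smooth latitudinal gradient plus a
  sinusoidal seasonal cycle (variable-specific amplitude and phase;
  temperatures peak in July, vegetation indices in April) plus spatially
  autocorrelated Gaussian noise. Daytime LST is night-time LST plus a
  strictly positive diurnal-range field, so DTLST ≥ NTLST everywhere by
  construction. Reflectance-like variables are clipped at 0. Defaults:
  seasonal amplitude 8 (night-LST units; other variables scale
  proportionally), south–north gradient 10, noise SD 1.
- **Occurrences.** Clades carry truncated-Gaussian niches in a 2-D
  environmental space (mean land-surface temperature, mean NDVI — the
  system's temperature and humidity proxies). Suitability is zero beyond
  3 niche breadths, so a clade's realized environmental range is bounded
  and scenario contracts ("disjoint" means disjoint) hold at every seed.
  Cells are sampled with probability proportional to suitability;
  records sit at cell centres with uniform within-cell jitter. Niche
  centres are anchored to the *realized* environmental manifold — the
  median environment of a quantile band of the temperature axis — since
  temperature and vegetation are strongly collinear across cells and
  off-manifold centres may have no attainable environment. The
  six-clade reference scenario uses the study's record counts
  (40, 47, 121, 15, 21, 17; 261 in total) spread along the temperature
  gradient with the phylogenetically close pairs kept adjacent; the
  two-clade scenarios (identical / nested / disjoint, 120 records per
  clade, niche breadth 10% of the central environmental span, disjoint
  centres 8 breadths apart) are the controlled conditions used by the
  end-to-end recovery tests.
- **Trees.** The reference tree (VI,(V,(I,(IV,(II,III))))) with node
  ages 5.88, 4.82, 4.32, 4.14 and 2.47 Ma; pseudo-posterior samples
  jitter internal node ages with Gaussian noise and resample on ordering
  violations. Topology uncertainty is not emulated.

What passing tests on this system do **not** show: behaviour under real
remote-sensing artefacts (clouds, gaps, sensor drift), non-Gaussian or
multimodal realized niches, spatial sampling bias in occurrence records,
and coordinate/datum error — none of which the generator produces.

## Numerical choices and problem sizes

- The default test and acceptance runs use 50 × 50-cell rasters,
  120-record clades, r = 100 lattices and 100 permutations; the
  scenario-recovery suite spans 20 replicate seeds and the
  null-calibration check 50 seeds. These sizes make the full suite run
  in well under a minute while leaving the randomization tests their
  full default replicate counts.
- Degenerate inputs fail loudly: zero-variance score clouds, all-masked
  predictor tables, empty backgrounds, non-ultrametric trees and missing
  tip values all raise with the offending object named.
- Determinism: a single pipeline seed fans out to fixed per-stage
  SeedSequence-derived seeds; equal seeds reproduce stacks, occurrences,
  permutation sequences and every CSV byte for byte.

## Known limitations

- The envelope's percentile dialect is one of several Bioclim variants;
  results near the training range limits depend on the CDF convention
  (documented above).
- Bandwidth selection is the normal-reference rule per axis; strongly
  multimodal occurrence clouds would be oversmoothed.
- Similarity-test pseudo-records are drawn from background *cells*
  uniformly, not area-weighted; at coarse resolutions near the poles the
  two differ.
- Ancestral reconstruction assumes a single-rate Brownian process; no
  Ornstein–Uhlenbeck or rate-shift alternatives are provided.
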