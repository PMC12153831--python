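# Methods

This note records the models `fishspat` implements, the conventions and
defaults it adopts where several are in use in the field, and what the
synthetic validation does and does not establish.

## CPUE and gridding

A haul is one net deployment with catch *C* (tons) and effort *E* (number of
nets, ≥ 1). Cells of the 0.1° analysis grid (the *unit fishing area*) carry
CPUE = ΣC/ΣE over their hauls — the ratio of sums, which weights hauls by
effort; the mean of per-haul ratios is deliberately not used (the two
disagree whenever effort varies, e.g. cells {C=3,E=1; C=1,E=3} give 1.0
versus 5/3). Cells are anchored at integer multiples of the cell size from
(0°E, 0°N) so grids from different periods align, and indexing is half-open:
a point on a cell's west or south edge belongs to that cell. Cells with no
hauls are absent, not zero; cells with effort but zero catch are retained
with CPUE 0. Gridding conserves totals under any grouping or resolution
change — this is tested, including property-based.

## Spatial weights

Two neighbor definitions feed the autocorrelation statistics:

* **contiguity** among occupied cells (rook = shared edge, queen = edge or
  corner), the default for the global Moran test;
* **distance bands** [d_lo, d_hi) on great-circle (haversine, R = 6371 km)
  distances between cell centroids, used by the incremental sweep and Gi*.
  Distances are in km because the characteristic scales of interest (tens
  of km) would be distorted by planar degrees over a 15°-wide domain.

Weights are binary and symmetric; w_ii = 0 for Moran's I, while Gi* uses
the same structure with the focal cell included (w_ii = 1, the "star"
convention). Units with no neighbors are excluded from statistics and
flagged rather than silently scored.

## Global Moran's I

I = (n/S₀) Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ², zᵢ = xᵢ − x̄, with E(I) = −1/(n−1) and
the randomization-assumption variance (the closed form in S₀, S₁, S₂ and
the sample kurtosis b₂). Two inference routes are provided and are
cross-checked against each other in the tests:

* analytic: z = (I − E(I))/√Var(I), two-sided normal p;
* permutation: values reassigned over units; p = (1 + #{|I* − E(I)| ≥
  |I − E(I)|})/(n_perm + 1). The add-one estimator cannot return zero; with
  the 99,999 draws conventional for this analysis the floor is 10⁻⁵.
  Permutations are vectorized in blocks, so 10⁵ draws on ~10³ cells run in
  seconds.

The implementation is verified against a brute-force double loop to 10⁻¹⁰
on random instances, the closed-form variance against Monte-Carlo
relabelings to 2%, and the test's type-I error at α = 0.05 is confirmed in
[0.02, 0.08] under an iid null.

## Incremental autocorrelation and scale selection

Moran's I and z are evaluated over an increasing series of distance
thresholds. Bands are **cumulative** [0, d) by default, matching the
behavior of the "distance range" parameter in the GIS tools this analysis
mirrors; annular bands are available by option. Empty bands carry no
statistic and are flagged. Inference along the profile is one-sided
(clustering), since the profile exists to locate a positive peak.

The selected scale is the first significant local maximum of z
(z ≥ 1.96). Equal consecutive z-values form one candidate peak located at
the run's first distance; a run counts as a peak when every adjacent run
that exists is strictly lower. This rule makes a leading plateau a peak at
its smaller distance, an endpoint a peak only when strictly above its
neighbor, and it never invents a peak on a monotone rise. When no peak is
significant the downstream Gi* stage falls back to a 42 km band, the modal
scale reported for the fishery this package emulates.

On a pure monotone gradient field the z-profile of cumulative bands is not
itself monotone (later bands add pairs, shrinking the null variance), but
I declines monotonically with distance; the tests assert exactly that.

## Getis-Ord Gi* and tiers

Gi* z_i = (Σⱼ wᵢⱼxⱼ − x̄Wᵢ) / (S √[(nΣⱼwᵢⱼ² − Wᵢ²)/(n−1)]) with x̄ and S
(population sd) over all n cells and the focal cell included in its own
neighborhood. Tiers follow the conventional cutpoints: |z| > 2.58 → 99%
hot/coldspot, 1.96–2.58 → 95%, 1.65–1.96 → 90%, inside ±1.65 → random.
No multiple-testing correction is applied by default, matching standard
practice for these raw-threshold tier maps; note that with ~10³ cells some
90%-tier cells are expected by chance alone. A cell whose neighborhood
spans all n units has an undefined Gi* (zero denominator) and is flagged
unscored rather than given a value.

## Gravity centers and standard deviational ellipses

COG is the yield-weighted mean position; X is longitude and Y latitude.
The weighted SDE uses deviations (x̃, ỹ) from the COG and A = Σw x̃²,
B = Σw ỹ², C = Σw x̃ỹ:

tan θ = [(A − B) + √((A−B)² + 4C²)] / (2C)

with θ the azimuth clockwise from geographic north in [0°, 180°). The
positive root maximizes the dispersion along θ (the major axis); the code
additionally verifies numerically which rotated axis carries the larger
weighted variance and swaps if needed, so the reported σ_major ≥ σ_minor
always. Axes are 1 × SD (no √2 or 2-SD scaling). Oblateness = σ_major/σ_minor.

All SDE computation is planar in lon/lat degrees — no projection — because
the axes of interest are conventionally reported in degrees and the domain
is narrow enough (10° of latitude) that projecting would change the azimuth
by well under the sampling noise. Consequences tested: translation and
rotation equivariance, weight-scale invariance, and exact agreement (10⁻⁶)
of θ and the axis ratio with a weighted-covariance eigendecomposition.
Degenerate cases: collinear points give σ_minor = 0 (flagged, oblateness
undefined); an axis ratio within 10⁻⁹ of 1 is flagged isotropic and the
azimuth reported as 0 by convention.

## GAM stage

Response log(CPUE+1), Gaussian family, identity link. Candidate smooths in
the fixed order year, month, lon, lat, SST, Chl-a, SSS, SSH; each term is a
penalized cubic B-spline with basis dimension 10 (5 for year, whose eight
levels cannot support more; dimensions are clamped to n_unique − 1). The
penalty weight defaults to α = 1 per term — fixed rather than data-driven,
so refits are bit-reproducible; the recovery tests show this is flexible
enough to find a dome-shaped effect and stiff enough not to fit noise.
The penalized solve is statsmodels' GLMGam; the modeling logic around it
(specification, VIF screen at threshold 5, forward AIC selection, partial
effects with 95% bands, the thermal-window readout) is this package's.

Covariates are screened by VIF = 1/(1−R²) before selection; terms are then
added in the fixed order and kept only when they lower the AIC, so the
accepted path has strictly decreasing AIC by construction. Per-term
significance is a Wald chi-square on the term's coefficient block with the
term's effective degrees of freedom.

## Synthetic fishery generator

The generator emulates an eight-year purse-seine logbook: 2014–2021,
months 3–12, 4,710 hauls/year (37,680 total) inside 35–45° N, 145–160° E.
Ground truth and defaults:

* **positions**: anisotropic Gaussian clusters, σ = (1.1°, 0.45°) with the
  major axis at azimuth 58°; annual center drift (0.356, 0.300)°/yr NE from
  (150.0°E, 39.8°N); a within-year NE–SW cycle of amplitude 1.2° along the
  45° axis whose half-sine phase peaks in August and leaves the season's
  end northeast of its start. Positions are truncated to the bounding box
  by resampling.
* **environment**: SST, Chl-a, SSS, SSH on a 0.083° monthly grid, each a
  linear trend + seasonal cosine + correlated noise. The noise has a 0.4°
  (~40 km) spatial correlation scale and 60% of its variance persists
  within a year (a fixed annual eddy/front pattern plus a fresh monthly
  component). Both choices are deliberate: mesoscale variability is
  coherent over tens of km and persists for months, and without them the
  aggregated annual CPUE fields are spatially white — the opposite of the
  clustered regime such fisheries exhibit. Noise sds (1.8 °C, 0.6 mg/m³,
  0.25 psu, 0.05 m) are sized so no covariate is a near-deterministic
  function of latitude and season (collinearity stays below VIF 5).
* **catch**: lognormal, log-mean 2.1 (≈ 8 t median), log-sd 0.6, +0.12/yr
  trend, plus covariate links — a dome-shaped SST response flat on
  10–20 °C and quadratic outside, and linear links with SSH dominant
  (+6.0 per m), Chl-a −0.25, SSS −0.30. The per-haul catch distribution is
  a modeling assumption of the generator, not an observed property.
* **effort**: 1 + Poisson(1.5) nets, guaranteeing positivity.

All randomness derives from one seed through `SeedSequence` spawning;
fields and hauls are independently reproducible, and equal seeds give
byte-identical output (tested, including at the full-pipeline level).

What passing on this generator shows: the statistics recover the drift,
anisotropy, clustering scale and covariate effects that were planted, at
realistic sample sizes, and the whole chain is deterministic. What it does
not show: robustness to the things real logbooks contain that the
generator omits — ocean-dynamics structure (fronts tied to currents rather
than stationary noise), preferential/port-biased sampling of positions,
reporting error in catch and effort, and vessel heterogeneity.

## Problem sizes used in validation

The shipped validation suite runs the brute-force equivalences at n ≤ 50
over 100 random instances, inference calibration at 200 replicates × 999
permutations on a 6×6 lattice, parameter recovery at 10⁴ points (SDE) and
5,000 hauls/year (drift), GAM recovery at n = 5,000, and the determinism
check on a 700-haul/year eight-year run; the acceptance script runs the
full default study (37,680 hauls, 999 permutations per year). These sizes
were chosen so the complete validation finishes in well under a minute per
stage while leaving Monte-Carlo error far smaller than the tolerances
asserted.

## Known limitations

* Planar-degree geometry slightly compresses east–west distances at the
  north of the domain (cos 45° vs cos 35°); at this domain width the effect
  on azimuth and axes is ≲ 1% and is accepted for comparability with the
  conventional degree-based reporting.
* Cumulative incremental bands make successive profile points strongly
  dependent; the first-peak rule is a heuristic scale selector, not a test
  with controlled error rates.
* The fixed GAM penalty (α = 1) trades optimal smoothness for exact
  reproducibility; effective degrees of freedom are reported so
  under/over-smoothing is visible.
* Gi* tier maps are descriptive; no FDR control is applied by default.
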