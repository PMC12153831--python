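# fishspat

Geostatistics of fishing-ground dynamics from haul logbooks.

`fishspat` is for fisheries scientists who have per-haul production records
— date, position, catch, effort for each net deployment — and want to know
where a stock's fishing grounds are, how strongly they cluster, and how they
move. It implements the analysis chain used in spatial studies of pelagic
fisheries (e.g. sardine and mackerel grounds in the Northwest Pacific high
seas):

1. **CPUE gridding** — hauls are aggregated into 0.1° *unit fishing areas*
   with CPUE = C/E per cell (total catch over total effort, a ratio of sums).
2. **Global spatial autocorrelation** — Moran's
   *I* = (n/S₀) · Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)², with analytic
   (randomization) and permutation inference; E(*I*) = −1/(n−1).
3. **Incremental autocorrelation** — the Moran z-profile over growing
   distance thresholds; the first significant peak sets the analysis scale.
4. **Hot/coldspot analysis** — Getis-Ord Gi* z-scores per cell with the
   conventional ±1.65/±1.96/±2.58 confidence tiers.
5. **Gravity centers and deviational ellipses** — yield-weighted COG
   trajectories (Xw = ΣCᵢXᵢ/ΣCᵢ) and weighted 1-SD standard deviational
   ellipses (azimuth θ from the two-root tan θ formula, axes σ_major ≥
   σ_minor, oblateness = σ_major/σ_minor).
6. **CPUE standardization** — a Gaussian GAM, log(CPUE+1) ~ s(year) +
   s(month) + s(lon) + s(lat) + s(SST) + s(Chl-a) + s(SSS) + s(SSH), with a
   VIF < 5 collinearity screen and forward stepwise selection by AIC.

Because real production logbooks are rarely public, the package ships a
**synthetic fishery-log generator** with known ground truth — clustered haul
positions drifting northeast across years, a within-year NE–SW cycle, and
lognormal catch linked to smooth environmental fields — so every stage of
the chain can be validated against the parameters that generated the data.

## Worked example

Grid one simulated year and test it for clustering
(`examples/02_grid_and_global_moran.py`):

```python
from fishspat import (SyntheticConfig, generate_hauls, grid_hauls,
                      contiguity_weights, moran_permutation_test)

hauls = generate_hauls(SyntheticConfig(seed=7, n_hauls_per_year=2000))
grid = grid_hauls(hauls[hauls["year"] == 2021], cell_size=0.1)
w = contiguity_weights(grid, kind="queen")
r = moran_permutation_test(grid.values("cpue"), w, n_perm=9999, seed=1)
```

prints

```
2000 hauls -> 758 occupied 0.1-degree cells
cell CPUE: mean 5.20, max 62.83 t/net

Moran's I = 0.0554  (E[I] = -0.0014)
z = 2.72, permutation p = 0.0130 (9999 permutations)
```

*I* is well above its null expectation −1/(n−1) and the permutation p-value
is small: neighboring cells carry similar CPUE, i.e. the ground is spatially
clustered. The companion script `examples/05_cog_and_sde.py` then shows the
yearly centers of gravity stepping northeast (bearings 42–55°) with a stable
ellipse azimuth near 57° and oblateness ≈ 2.4 — the drift and anisotropy the
generator was configured with.

The other `examples/` scripts cover the incremental scale sweep, Gi*
hotspot tiers, the GAM stage (recovering a dome-shaped SST effect with its
optimum inside the configured 10–20 °C window), and the full pipeline.

A thin CLI wraps the same functions:

```bash
fishspat simulate --seed 7 --out hauls.csv
fishspat autocorr global hauls.csv --weights queen --nperm 9999
fishspat sde hauls.csv --group year
fishspat pipeline run --outdir out --seed 7
```

## Layout

```
src/fishspat/      library (synthetic, gridding, weights, moran, hotspots,
                   ellipse, gam, pipeline, cli)
examples/          one narrative script per capability
tests/             pytest suite incl. whole-pipeline validation
docs/methods.md    models, conventions, parameter choices, limitations
```
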