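# speciogeo

Geographic analysis of tip speciation rates: where do new species arise
fastest, and what ecological conditions accompany fast speciation?

The package is built for macroecologists and phylogeneticists studying
latitudinal gradients of diversification — the puzzling observation that
in several clades (squamates, mammals, amphibians) *mean* assemblage
speciation rates increase **away** from the species-rich tropics. It
implements the full analysis chain at desk scale:

1. **Tip speciation rates.** For tip *i* of a time-calibrated phylogeny,
   the equal-splits score is
   `ES_i = Σ_j l_j (1/2)^(j-1)` over the edges `j = 1, 2, …` of the
   tip-to-root path (terminal edge first; at an *m*-furcation the factor
   is `1/m`), and the rate proxy is `DR_i = 1 / ES_i` — high when a tip
   sits on short, recently split branches. Rates are aggregated over a
   posterior sample of trees (`speciogeo.trees`).
2. **Assemblage grids.** Species ranges on a lat/lon grid become a
   presence–absence matrix; per-cell mean, maximum, and percent
   coefficient of variation of member rates form the response surfaces
   (`speciogeo.grid`).
3. **Spatial-error regression.** `y = Xβ + u, u = λWu + ε` fitted by
   profile maximum likelihood over λ with an eigenvalue log-determinant;
   distance-band inverse-square weights (`1/d²`, default 5° cutoff,
   row-standardised), Nagelkerke pseudo-R², and AIC selection of the
   neighbourhood cutoff (`speciogeo.sar`).
4. **Tropical vs non-tropical speciation.** Species are classed by range
   latitudinal midpoint against the tropics of Cancer/Capricorn
   (23.44°); a nonparametric FiSSE-style test compares per-state mean
   tip rates against a trait-simulation null with a parsimony-calibrated
   Mk transition rate (`speciogeo.fisse`).
5. **Drivers.** Per-bioregion climate-change velocity (temporal rate of
   climate change over the local spatial climate gradient, km/yr),
   terrain roughness (3×3 max−min), net relatedness index (−z of mean
   pairwise phylogenetic distance under a regional tip-shuffle null),
   merged with supplied area/productivity/temperature tables into a
   six-predictor spatial-error model (`speciogeo.drivers`).
6. **Synthetic worlds.** Birth–death and BiSSE forward simulators,
   clade-structured posteriors, spreading-dye ranges, smooth climate and
   elevation rasters and bioregion partitions with *planted* effects, so
   every stage is testable without downloads (`speciogeo.simulate`).

## Worked example

A synthetic world with a fast clade (birth rate 0.8 vs 0.05) anchored
near 45° latitude in both hemispheres:

```python
from speciogeo.simulate import planted_gradient_config, build_world
from speciogeo.trees import aggregate_posterior, rate_age_correlation
from speciogeo.grid import build_pam, cell_summaries, classify_latitude
from speciogeo.pipeline import latitude_sar
from speciogeo.fisse import fisse_batch

cfg = planted_gradient_config(seed=42)
world = build_world(cfg)
rates = aggregate_posterior(world.posterior)     # 350 species x 3 trees
agrid = build_pam(world.ranges, cfg.grid, rates)
summ = cell_summaries(agrid, rates)
fit, ols = latitude_sar(summ)                    # SAR error model, 5 deg
```

Output for this seed:

```
species: 350
rate-age Spearman rho = -0.883 (p = 4.17e-116)
occupied cells: 1008  cells with CV > 30%: 56%
SAR slope on |lat| = 0.00911 (SE 0.00263, p = 5.3e-04)
lambda = 0.889, pseudo-R2 (predictor+space) = 1.000, OLS adj R2 = 0.265
tropical: 76 non-tropical: 274
mean lambda tropical = 0.0735, non-tropical = 0.5603
```

Reading the numbers: the planted inverse gradient is recovered — cell
mean rate rises significantly with absolute latitude even after the
spatial-error term absorbs the strong residual autocorrelation
(λ = 0.89). Rates correlate negatively with species age (young species
sit on short terminal branches), mixed fast/slow assemblages push the
within-cell coefficient of variation past 30%, and the per-state mean
rates mirror the planted tropical/non-tropical contrast.

The same pipeline runs end to end from a JSON config:

```bash
speciogeo run --config examples/demo.json --out out/
```

writing tip rates, the presence–absence matrix, cell summaries, the
latitudinal SAR table, the per-tree rate-test results, the bioregion
driver table and a manifest (seed, config hash, versions) as CSV/JSON,
plus ASCII-grid rasters.

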