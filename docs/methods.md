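# Methods

This note documents the models, estimators, null models and numerical
choices behind `speciogeo`, and what the synthetic worlds do and do not
emulate.

## Tip speciation rates

The tip rate statistic is the inverse equal-splits measure. For tip *i*,
walk the path from the tip to the root; the terminal edge enters with
weight 1 and the weight is divided by the number of daughter lineages of
each internal node crossed rootward (1/2 at bifurcations, 1/*m* at an
*m*-furcation — the generalisation keeps the "credit splitting"
interpretation without forcing arbitrary resolution of polytomies):

    ES_i = Σ_edges  length × weight,     DR_i = 1 / ES_i.

DR is a speciation-rate proxy: it is largest for tips subtended by short
branches in recently splitting clades. Two calibration facts matter for
interpretation and are verified by the test suite:

* **Scale equivariance** — multiplying all branch lengths by *c* divides
  every DR by *c* (exact).
* **Yule calibration** — on pure-birth trees at rate λ the *harmonic*
  grand mean of tip DR recovers λ closely (measured ≈ 1.02 λ at
  λ = 0.1, 200 tips), while the arithmetic tip mean overestimates λ by
  roughly 40%. This upward bias of the arithmetic mean is a property of
  the statistic itself (the reciprocal of a mean path length), so the
  calibration check uses the harmonic mean; aggregation across a
  posterior (`aggregate_posterior`) defaults to the arithmetic per-species
  mean — the conventional reporting choice — with the harmonic mean
  available via `mean="harmonic"`.

Species age is operationalised as the terminal branch length, averaged
across the posterior. The rate–age check defaults to Spearman rank
correlation because DR is heavy-tailed; Pearson is available by flag.
Zero-length terminal paths are rejected with an explicit error rather
than producing infinite rates.

## Assemblage grids

Ranges are sets of grid cells (the analysis only ever consumes the
presence–absence matrix, so polygon rasterisation is avoided; polygon
export to GeoJSON is provided for interoperability). A species is present
in a cell if its range occupies it; cells with zero species are dropped
with a logged count, and species missing from the rate table are excluded
with a warning (mirroring the intersection of range data with the
phylogeny).

Per-cell summaries: arithmetic mean, maximum, and percent coefficient of
variation `100·sd/mean` using the sample (n−1) standard deviation; CV is
undefined (NaN) for richness-1 cells. CV is scale-free, so it separates
genuinely mixed fast/slow assemblages from uniformly fast ones.

Latitudinal classification: the range midpoint is the area-weighted mean
of member-cell centroid latitudes (weights ∝ cos lat, since geographic
cells shrink poleward); a bounding-box midpoint is available because
range tools differ on this point. Species with |midpoint| ≤ 23.44° are
tropical; the boundary is inclusive (documented tie rule, configurable).

## State-dependent speciation test

A nonparametric two-sample contrast in the FiSSE tradition. The per-state
estimate is the arithmetic mean of the inverse equal-splits statistic over
the tips in each state; the observed contrast is
`Δ = λ̂₁ − λ̂₀`. The null re-simulates the character along the tree under
a symmetric two-state Mk model whose transition rate is calibrated
nonparametrically: Fitch parsimony change count divided by total tree
length (minimum 1/tree-length). The root state is drawn from the observed
tip frequency. Null simulation is vectorised: one preorder sweep flips a
whole matrix of replicate states per edge with probability
`(1 − exp(−2qt))/2`; monomorphic draws (contrast undefined) are resampled.

The p-value doubles the smaller tail with a +1 pseudocount:
`p = min(1, 2·min(p₊, p₋))`, `p₊ = (1 + #{Δ_null ≥ Δ})/(n_null + 1)` — the
standard permutation-test convention that keeps p > 0. Null generation is
canonically oriented (the lexicographically smaller of the trait vector
and its complement) so that swapping the state labels negates Δ and its
entire null set *exactly*, leaving the two-tailed p bit-identical.

Measured operating characteristics (see the acceptance suite): type-I
error ≈ 0.02–0.03 at nominal α = 0.05 (conservative, as expected for a
trait-simulation null that preserves phylogenetic signal), and the
directional estimate λ̂₁ > λ̂₀ in ≥ 94% of simulations when state 1
truly speciates twice as fast. For strongly clade-structured traits
(e.g. a single fast high-latitude clade) the test is deliberately
conservative: clade-structured null traits reproduce large contrasts, so
a big Δ alone is not evidence of state dependence.

## Spatial-error regression

Model: `y = Xβ + u`, `u = λWu + ε`, `ε ~ iid N(0, σ²)`. W is a
distance-band matrix with inverse-square weights (`1/d²` up to the
cutoff; great-circle distances in degrees of arc, matching cutoff
conventions stated in degrees), row-standardised by default (the
ecology-standard "W" style; raw weights retained as an option). Sites
with no neighbour inside the cutoff are kept as zero rows with a warning
— dropping them would silently change n.

Estimation profiles the log-likelihood over λ: given λ, β and σ² have
closed forms via the transformed regression `(I−λW)y on (I−λW)X`, and

    logL(λ) = −n/2 (log 2πσ̂² + 1) + Σ_i log|1 − λ e_i|,

with `e_i` the eigenvalues of W (for a row-standardised matrix built from
a symmetric base, W is similar to a symmetric matrix, so a symmetric
eigensolve suffices — exact and fast at desk scale; sparse approximations
are out of scope). λ is restricted to the eigenvalue-bounded interval
intersected with (−1, 1); optimisation is bounded Brent to 1e-8. Standard
errors come from the inverse numerical Hessian of the full log-likelihood
in (β, λ, log σ²). AIC counts k = #β + 2 parameters. A spatial-lag
variant (autoregression on the response) is provided for cutoff-selection
parity only.

Fit statistics: two pseudo-R² values are reported because they answer
different questions. Against the intercept-only *spatial* null
(`nagelkerke_r2`), the value isolates the predictors' contribution beyond
spatially structured error; against the flat non-spatial Gaussian null
(`pseudo_r2_full`), it measures what predictors and space explain
together — the quantity usually printed alongside an OLS R² in
assemblage-gradient tables. The Nagelkerke normalisation (Cox–Snell over
its maximum `1 − exp((2/n) logL0)`) assumes a likelihood bounded by 1;
for continuous densities with positive log-likelihood the normaliser is
inert and the raw Cox–Snell ratio (still in [0, 1)) is returned.

Cutoff selection fits one model per candidate cutoff (default 10–100° in
steps of 10°) and returns the lowest-AIC fit with the full table;
per-cutoff failures are recorded, not fatal.

## Bioregion drivers

* **Climate-change velocity** (km/yr): per cell, `|current − past| / Δt`
  divided by the slope magnitude of the current-conditions surface.
  The slope uses Horn's 3×3 average-maximum stencil with one-cell odd
  reflection at borders — odd reflection extends linear ramps exactly, so
  a uniform-gradient world yields the closed-form velocity in every cell
  including edges. Cells with zero spatial gradient are flagged undefined
  (NaN) and excluded from regional means rather than capped: infinite
  velocities would otherwise dominate. Per-variable velocities are
  combined by arithmetic mean (median by flag), and each past horizon is
  compared against the present before averaging across horizons.
* **Roughness**: per-cell max − min elevation over the 3×3
  neighbourhood; border cells use their available neighbours. Averaged
  per bioregion.
* **NRI**: per cell with richness ≥ 2, the observed mean pairwise
  patristic distance (MPD) is z-scored against nulls that shuffle tip
  identities within the regional species pool and negated
  (positive = clustering). The shuffle leaves the presence–absence
  matrix untouched, so richness and range-size frequencies are preserved
  exactly. Patristic distances are computed once per tree (O(n²) memory,
  fine at desk scale). Cells whose null has zero variance (degenerate
  pools) are flagged undefined. Region values average member cells;
  computing per cell against a regional pool (rather than once per
  region) keeps the index sensitive to within-region assemblage
  structure. NRI is invariant to rescaling all branch lengths — doubling
  doubles MPD observed and null alike, leaving the z-score unchanged.

The driver model regresses per-region mean rate (mean over member cells
of cell mean DR, so widespread species weigh by occupancy) on six
standardised predictors: the three computed above plus supplied
time-integrated area, productivity and temperature tables (these are
inputs, not derived quantities). Predictors are z-scored so coefficients
are comparable effect sizes; constant predictors raise, and pairwise
collinearity |r| > 0.95 triggers a hard warning. Fitting requires ≥ 10
regions.

## Synthetic worlds

The generators emulate the statistical structure the analysis assumes:

* **Trees**: Gillespie forward simulation of (state-dependent)
  birth–death processes conditioned on the extant tip count by stopping
  at the n-th tip plus a uniform fraction of the next inter-event
  interval (terminal branches strictly positive); extinct lineages are
  pruned and unifurcations contracted. Clade-structured trees join
  independent Yule clades on a root polytomy with stem lengths chosen to
  keep the tree ultrametric; a "posterior" resimulates branch lengths
  and within-clade topology per draw with a fixed label partition.
* **Ranges**: spreading-dye growth (uniform frontier expansion) gives
  contiguous ranges; sizes are lognormal (many small, few large ranges);
  anchoring pins seeds to a latitude band or a home bioregion to plant
  geographic rate structure.
* **Climate/elevation**: deterministic meridional gradient plus uniform
  temporal trend, with optional Gaussian-smoothed noise (zero by default
  so velocity has a closed form); elevation is a Gaussian-filtered random
  field with tunable relief.
* **Bioregions**: nearest-seed (Voronoi) partition — contiguous,
  irregular, covering the grid; supplied predictor columns are drawn from
  lognormal/latitude-linked distributions because the real analysis
  consumes them from external tables.

Planted-effect worlds define the study conditions for the end-to-end
checks. `planted_gradient_config`: 350 species, 60/40 slow/fast clade
split with birth rates 0.05 vs 0.8, the fast clade anchored at ±45°
(jitter sd 3°), modest range sizes (lognormal μ = 2.0, σ = 0.8 cells) on
a 48 × 24-cell grid at 2.5° — sized so the planted latitudinal signal is
recovered by the spatial-error model in ≈ 97% of seeds (measured over 80
held-out seeds). `planted_driver_config`: 32 bioregions × 10 species;
per-region log birth rate = log 0.12 + 1.2·z(velocity) +
1.2·z(roughness), clipped to [0.02, 3]; recovery of both positive
coefficients measured at ≥ 97% of held-out seeds.

What the worlds do **not** emulate: realistic paleogeography or
niche-driven range dynamics, spatially coherent range movement through
time, taxonomic error or sampling gaps, extinction-rate variation, and
tree-wide topological uncertainty beyond branch-length resimulation.
Passing the planted-effect checks therefore shows that the pipeline
recovers known geographic rate structure through all of its stages — not
that any particular empirical gradient is correct.

## Numerical choices and degenerate inputs

* Distances in decimal degrees of arc (cutoffs are stated in degrees);
  coincident sites are an error naming the pair.
* λ profile tolerance 1e-8; profile optimality is asserted against a
  21-point grid in tests.
* Posterior aggregation requires identical tip sets and reports the
  symmetric difference on mismatch.
* Monomorphic traits, zero-variance correlates, rank-deficient designs,
  all-flat rasters, empty ranges and sub-minimum region counts all raise
  informative errors rather than returning NaNs silently.
* Problem sizes in the acceptance script (100 oracle trees, 200
  calibration trees, 500 type-I replicates with 500 nulls, 100
  spatial-error fits at n = 400, 999 NRI randomisations, 20 seeds per
  planted world) were chosen as the smallest sizes at which the measured
  quantities are stable to well within their stated bands.

## Known limitations

* DR is a speciation proxy, not a net-diversification estimator; no
  model-based (BAMM/ClaDS-style) rates are implemented.
* The spatial model family is the ML error (and lag) SAR only — no GMM,
  no conditional autoregression, no equal-area projection of the grid.
* The FiSSE-style test here is defined by this package (mean inverse
  equal-splits per state, parsimony-calibrated Mk null); it follows the
  published method's spirit but is not a bit-for-bit reimplementation of
  any reference code.
* Grid geometry is unprojected; cell areas enter only through the
  cos-latitude weighting of range midpoints.
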