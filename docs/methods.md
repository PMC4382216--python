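# Methods

This note documents the statistical procedures implemented in
`frugitrack`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices that matter
for reproducibility.

## Triangulation of bearing pairs

A location is estimated as the intersection of the two bearing rays of one
simultaneous observation ("biangulation").  With exactly two coordinated
observers, the multi-bearing maximum-likelihood estimators (e.g. Lenth's)
reduce to this line intersection, so the simpler estimator is used and
error ellipses are out of scope.  Azimuths are degrees clockwise from grid
north; a ray is parameterised forward from its observer with direction
(sin θ, cos θ), and the 2×2 linear system is solved directly.

Filters, applied in order, each tagging rejected pairs with the first
failing rule:

1. **Separation** — bearing separation must lie in **15–165°** (default);
   nearly parallel or anti-parallel sight lines make the intersection
   numerically and physically unreliable.
2. **Behind-observer** — both ray parameters must be non-negative: an
   intersection behind an observer is impossible for a forward bearing.
3. **Range** — the intersection must be within **400 m of each observer**;
   beyond the transmitter range a solution is not credible.  The rule is
   applied to both observers because both radio links are range-limited.

Magnetic declination defaults to 0° (sub-degree declinations are
negligible against ~2° compass noise) but is a config field added to both
azimuths.  Coordinates are planar meters in a user-declared projected
system; the package never reprojects.

**Deduplication.**  A bat perched and feeding yields runs of repeated
positions that would inflate spatial autocorrelation.  Each maximal run of
consecutive fixes within a *stationary radius* of the run's first fix is
collapsed to that first fix.  No canonical distance exists for "the same
place"; the default of **50 m** is on the order of typical biangulation
error at these ranges and is configurable and recorded in the run
manifest.  The operation keeps a subsequence of the input and is
idempotent.

**Session selection for daily ranges.**  A session's contact fraction is
its achieved fix count over the scheduled count (6 h at one fix per
2 min).  The three sessions with the highest contact fractions among those
reaching 85% are retained (ties to the earlier session); if fewer qualify,
all qualifying sessions are kept and the track is flagged, since real
studies retain some animals with only two usable nights.

## Home-range estimation

**Percent MCP.**  The level-% minimum convex polygon retains the
⌈level/100·n⌉ fixes closest to the arithmetic centroid of all fixes and
returns their convex hull.  Peeling is single-pass (distances to the fixed
initial centroid, ties broken by input order), the most common convention
and a deterministic one; iterative re-centroiding is deliberately not
used.  The 95% MCP is the total home range HR_tot, reported in hectares.

**Fixed k-LoCoH.**  One local hull per fix from the fix and its k−1
nearest Euclidean neighbours (k points total; the alternative k-neighbours-
plus-root convention is a config switch, `include_root=False`).  Distance
ties break by input index.  Hulls are sorted by ascending area (ties by
root index) and unioned in order until the union covers the target
fraction of fixes (boundary inclusive); the isopleth is the set of
disjoint polygonal components of that union.  Degenerate neighbourhoods
(duplicate or collinear points) contribute zero-area geometries whose
points still count as covered.  k defaults to round-half-up of √n (floor
via config); fewer than 9 fixes are refused.  With k = n and fraction 1
the estimator provably coincides with the 100% MCP, which the tests
assert, alongside equality with a brute-force reference on small
instances.

**Focus areas** are the strictly disjoint components of the 50% isopleth;
touching polygons merge, and an optional merge radius (default 0) can
coalesce components closer than a threshold.

**Compactness** is the isoperimetric quotient 4πA/P² of the 95% MCP — the
polygon's area over the area of the circle with equal perimeter: 1 for a
circle, small for elongated ranges.  It is scale-invariant, which the
suite checks as a property.

**Daily ranges** are the 95% MCPs of single sessions; sessions with fewer
than three usable fixes are skipped with a warning.

## Habitat availability and selection

Space is classified into five structural categories — natural forest,
degraded forest, farmland, pasture, urban — from either a categorical grid
(cells own the half-open [x, x+c)×[y, y+c) square, making edge
classification deterministic) or labelled polygons (boundary points
resolve to the first-listed feature; points in no feature take a declared
background category).  Region composition is computed by exact geometric
clipping (interior cells counted whole, boundary cells intersected), and
always sums to 1.

Availability for a bat is the composition of a circle centred on its day
roost (mean of roost coordinates when several were used — a
degenerate-hull-safe centre) with radius the maximum distance from the
centre to a vertex of its 95% MCP, clipped to the map extent.  Use is the
per-category count of fixes inside the bat's 50% isopleth components
(a pure-area variant is available via `used_mode="area"`).

**Selection ratios (design III).**  With uᵢⱼ the use count of category i
by bat j, u₊ⱼ the bat total and πᵢⱼ its availability, the pooled ratio is

    wᵢ = Σⱼ uᵢⱼ / Σⱼ u₊ⱼ πᵢⱼ ,

1 meaning no selection.  Its standard error is the ratio-of-totals
estimator treating bats as sampling units,
se² = n/(n−1) · Σⱼ(uᵢⱼ − wᵢ u₊ⱼπᵢⱼ)² / (Σⱼ u₊ⱼπᵢⱼ)².  Simultaneous
(1−α) Bonferroni intervals use the α/(2I) quantile, I being the number of
categories with nonzero availability, with negative lower bounds truncated
to 0.  **Quantile choice:** because the SE is estimated from few animals,
the default quantile is Student t with n−1 degrees of freedom; in null
simulations at 16 bats × 200 fixes the classical normal-z construction
covered wᵢ = 1 simultaneously in only ~87–88% of replicates, while t(15)
restores ~92–93%, against a nominal 95%.  `quantile="normal"` reproduces
the classical large-sample construction used by the standard R
implementations.  The global test is the log-likelihood χ² of observed
versus expected counts, with Σⱼ(Iⱼ−1) degrees of freedom where Iⱼ counts
the categories available to bat j; cells with use but zero availability
are excluded with a warning.  (Published analyses sometimes report smaller
df from pooling; the package reports its own df and does not force a
match.)

**Fisher exact r×c test.**  Exact conditional p-value: total
multivariate-hypergeometric mass of all tables with the observed margins
whose probability does not exceed the observed table's (relative tolerance
1e-7, so boundary ties are counted).  Enumeration is recursive over row
compositions with margin pruning; beyond a configurable budget (default
10⁷ tables) a seeded Monte-Carlo estimate over shuffled category labels is
returned with its standard error.  All-zero rows/columns are dropped
first.

**Sequential Bonferroni** is Holm's step-down: the i-th smallest p-value
is compared with α/(m−i+1) and testing stops at the first retention, so
rejections always form a prefix of the sorted list.

## Daily-range mixed models

The response is ln(daily-range area in m²).  Candidate fixed effects are
the proportion of degraded forest in the daily range (*disturbance*), the
sampling *day*, the illuminated *moon* fraction (a [0, 1] covariate
supplied as input; the pipeline's default, used only when no measurements
are given, is a deterministic synodic-cycle proxy of the sampling day),
and *sex* coded 0/1.  Covariates are mean-centred before fitting, and the
centering means are reported for back-transformation.

**Fitting.**  y = Xβ + b_group + ε with b ~ N(0, σ_b²), ε ~ N(0, σ_e²) is
fitted by maximum likelihood, profiling over λ = σ_b²/σ_e²: at fixed λ the
GLS coefficients and σ_e² are closed-form per group via the Sherman-
Morrison identity (I + λJ)⁻¹ = I − λ/(1+λn_g)·J, leaving a bounded scalar
minimisation over log λ ∈ [−12, 12] (tolerance 1e-10).  A lower-boundary
optimum is refitted at λ = 0 exactly (σ_b² = 0, equivalent to OLS).  ML —
not REML — is used throughout because models differing in fixed effects
are compared; REML likelihoods would not be comparable.  The suite checks
the fit against statsmodels' MixedLM (ML) to ~1e-6.

**Model selection and averaging.**  All 2⁴ subsets are fitted; AICc =
−2ℓ + 2K + 2K(K+1)/(n−K−1) with K = intercept + slopes + 2 variance
parameters (intercept-only model has K = 3).  Akaike weights are
exp(−Δ/2) normalised.  Averaging defaults to the Δ≤2 top set with
*conditional* (natural) averaging — each term averaged over the scoped
models containing it — matching the usual reporting convention; averaging
over all models and *full* (zero-substitution) averaging are config
options, because both conventions appear in the literature.  The
unconditional SE folds between-model spread into the sampling variance,
√(Σw̃(se² + (β−β̄)²)); relative importance is the summed weight of models
containing the term over the full 16-model set regardless of averaging
scope; intervals use a 1.96 multiplier by default (configurable — some
published tables imply a slightly larger, t-like multiplier).

**Conditional R²** is (σ²_f + σ_b²)/(σ²_f + σ_b² + σ_e²) with σ²_f the
sample variance of the fixed-effect predictor Xβ.  **VIF** of a term is
1/(1−R²) from its least-squares regression on the other terms; perfect
collinearity reports +inf with a warning.  The normality screen delegates
to the standard Shapiro–Wilk implementation and is exercised only as a
smoke test.

**Size/shape correlation.**  Pearson r between ln HR_tot and compactness,
with a 95% Fisher-z interval tanh(atanh r ± 1.96/√(n−3)) and a two-sided
t test on n−2 df.  r is invariant to the log base, which a test asserts.

## Synthetic data generator

The generator defines the package's study conditions: a 3 × 3 km grid at
10 m cells with a pasture background, 4 blob-shaped natural patches
(radius 150–350 m) ringed by ~60 m of degraded fringe and linked by 1–2
degraded corridors, rectangular farmland blocks to a 12% target fraction,
and one 80 m urban strip.  Bats follow a goal-biased correlated random
walk at 2-minute steps over six 6-hour sessions: headings are von Mises
draws (κ = 4) around a mix of the previous heading and the bearing to the
current goal, step lengths are gamma(2, scale/2) with a 60 m mean (150 m
while commuting), proposed steps pass habitat-weighted rejection sampling
(attraction weights natural 2.0, degraded 1.0, farmland 0.6, pasture 0.3,
urban 0.05; at most 20 proposals, then forced), and bats perch (stay put)
with per-interval probability ~0.5–0.85, which is what makes stationary
deduplication meaningful.  Commuters launch Poisson(1.5)-many bouts per
session (capped at 2) to a far site 330–1050 m from the roost, placed in
degraded habitat when possible; every session starts and ends at the
roost.  Observers are re-placed per fix at ~200 m (≤350 m) with an
inter-observer separation uniform in 40–140° as seen from the bat, and
azimuths get wrapped-normal noise (default sd 2°).  The field-like preset
generates 16 bats with 5 commuters and leaves roughly one to a few
hundred accepted fixes per bat after filtering and deduplication.

Everything is a pure function of (config, seed).  The model exists to
exercise the estimators — it produces tunable selection, central-place
geometry, optional second focus areas, and a positive disturbance–range
relationship — and deliberately omits energetics, memory, roost
switching, observer path continuity and inter-bat interaction.  Passing
tests therefore demonstrate estimator correctness and calibration under
these mechanisms, not biological realism of any particular field system.

One consequence of central-place geometry is worth stating: resident
bats never leave their roost patch, so their availability circles are
dominated by natural forest and their per-animal use ≈ availability for
that category.  The pooled design-III w for natural forest is then only
modestly above 1 with a wide confidence interval at 16 animals — the
estimated ranking (natural highest, urban lowest) is recovered reliably,
but significance of the natural CI against 1 is not guaranteed, just as
real studies of forest-roosting bats report natural-forest ratios near
1.2–1.3 rather than large ones.

## Problem sizes used by the test suite and acceptance script

Desk statistics run on the bundled 16-bat reference table.  Seeded
simulation sizes were chosen to make each check statistically meaningful
at interactive runtimes: 200 replicates for null-selection CI coverage
and 100 for rank recovery (16 bats × 200 fixes each), 500 replicates of
the 16 × 3 mixed-model recovery design, 50 seeds of paired
commuter/resident studies for range geometry, and ≤12-point instances for
the exhaustive LoCoH oracle.  Fisher-test calibration uses 2×3 tables so
the exact enumeration stays exhaustive.

## Known limitations

- Biangulation reports no per-fix positional covariance; error ellipses
  and multi-bearing MLEs are out of scope.
- Percent-MCP peeling is single-pass; other software may re-centroid
  iteratively and produce slightly different 95% hulls.
- The design-III SE treats animals as independent sampling units; with
  very few animals (< ~6) the t-quantile intervals are still approximate.
- The grid composition is exact for the grid, but a grid is itself a
  discretisation of the landscape; GeoJSON polygon maps avoid this.
- Mixed models support a single random intercept only — no random slopes,
  crossed effects, GLMMs or temporal autocorrelation.
- The moon covariate's default synodic proxy is a stand-in for measured
  illumination fractions and should be replaced by real values when
  modelling lunar effects.
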