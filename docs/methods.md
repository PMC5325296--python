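# Methods

This note records the statistical model behind each stage, the defaults
and why, the numerical conventions the results depend on, and what the
synthetic-data generator does and does not emulate.

## Data model

A `CommunityMatrix` holds integer occurrence counts per (site, species):
the number of sampling units (litter quadrats; `samples_per_site`,
default 20, mirroring a 10-wet + 10-dry-season design) in which the
species was detected.  Counts are bounded by the effort, species absent
everywhere are kept (they change nothing downstream) and logged, and
sites with zero occurrences are rejected by the diversity stages, where
estimators are undefined at n = 0.  Tables are plain CSV/TSV
(delimiter from the extension); orientation is an explicit flag because
published supplementary matrices are usually species-by-site.

## Alpha diversity

Sample coverage uses the singleton/doubleton estimator on the occurrence
vector of a site (or of pooled sites).  Degenerate cases are handled as
limits: no singletons → 100%; a single occurrence (n = 1, f₁ = 1) or an
all-singleton sample → 0% with a warning, the pessimistic limit of an
inventory with no recaptures.

Hill numbers use relative incidence frequencies pᵢ = yᵢ/n
(incidence-frequency mode), matching the occurrence-as-abundance design.
The 95% CIs come from a percentile bootstrap that resamples n occurrences
from a multinomial over p̂ (default 1000 replicates, seeded).  This is a
declared, simple choice; percentile intervals are biased low near the
perfectly-even boundary (resampling can only reduce evenness there), which
is why tests check coverage on uneven vectors.  Point estimates carry no
such caveat.

## Beta diversity and cluster testing

Similarities are reported in percent.  "Sørensen" here is the
*quantitative* (min-sum / Bray–Curtis) form, because the abundance-
weighted index is the one that pairs with order-1 diversity in the
Jaccard → order 0, Sørensen → order 1, Morisita–Horn → order 2 family
(recorded as metadata; no numeric similarity→beta-diversity conversion is
performed).  The incidence Sørensen is available under
`sorensen_incidence`.

UPGMA merges the most similar pair, with between-cluster similarity the
size-weighted mean of member pairwise similarities.  Ties are broken by
the lexicographically smallest pair of leaf-index tuples and children are
ordered canonically, so dendrograms are bit-reproducible.  Newick export
encodes an ultrametric tree with node height (100 − s)/2.

SIMPROF (Type 1) runs top-down on the UPGMA tree.  At a node with ≥ 3
leaves, the statistic is π = Σₖ |s₍ₖ₎ − s̄₍ₖ₎| between the ordered observed
within-group similarity profile and the mean ordered profile over
`n_perm_mean` permutations that shuffle each species independently across
the node's sites; P compares π against `n_perm_null` further permuted
profiles with the (b+1)/(B+1) correction, so P is never 0.  Defaults
1000/999/α = 0.05 follow common practice for similarity-profile testing.
Because observed and permuted profiles are measured against the same mean
profile, the test is exact under exchangeability even at small
`n_perm_mean` — the calibration simulation exploits this with 30/99.

## Collinearity screen

Spearman ρ uses midranks; the two-sided P is an exact full enumeration
for n ≤ 7 (7! orderings) and the t-approximation above that — a cheaper
cut-off than enumerating larger factorials for no practical gain at these
sample sizes.  The screen drops, within each significantly correlated
pair (default P < 0.05; a |ρ| threshold is available instead), the
predictor later in an explicit `keep_priority` list (default: riparian
cover, then native-forest cover, then shape and width, then the remaining
covers in reporting order).  An explicit priority replaces the
unreproducible "most interpretable variable" judgement.  VIF filtering
then iteratively removes the largest-VIF predictor until all are below
the cutoff (default 10, the usual rule of thumb; no stricter value is
implied by the design).

## GLMs and multi-model inference

Gaussian responses are fit by OLS (the exact ML solution; t statistics on
n − p df), Poisson by IRLS (tolerance 1e-8, max 100 iterations; Wald Z).
Parameter counts: Gaussian k includes the residual variance
(k = p + 1), the convention under which AICc values match R's; Poisson
k = p.  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).  For counts, qAICc divides the
log-likelihood by ĉ = Pearson χ²/df of the global (all-predictor) model —
the standard recommendation — counts ĉ as one extra parameter, and floors
ĉ at 1 (no underdispersion correction).

All-subsets enumeration (≤ 12 candidates, intercept-only included, main
effects only) is ranked by the criterion; Akaike weights are
exp(−Δ/2)-normalised.  The 95% confidence set is the smallest ranked
prefix whose cumulative weight exceeds 0.95; the Δ < 2 set is reported
alongside.  Model averaging is *conditional* (over containing models,
weights renormalised): β̄ = Σw′ᵢβᵢ and unconditional variance
[Σw′ᵢ√(var(βᵢ) + (βᵢ−β̄)²)]², the classical multi-model estimator.  The
full-model (zero-substitution) variant was considered and set aside: the
"is the averaged estimate larger than its unconditional variance"
reading only makes sense for the conditional form.  Explained deviance
D² = 1 − deviance/null deviance is reported in percent.

## DistLM

Similarity converts to distance by d = 100 − s (a √d option exists for
non-Euclidean embeddability but is off by default, since the plain
complement is the common convention).  G is the Gower-centred −d²/2
matrix; with the hat matrix H of (intercept + predictors),
pseudo-F = [tr(HGH)/m]/[tr((I−H)G(I−H))/(n−m−1)], which on Euclidean
distances of univariate data is exactly the classical regression/ANOVA F.
Marginal tests permute site labels of G (default 9999, seeded); sequential
tests in multiple models permute reduced-model residuals (Freedman–Lane).
"BEST" selection scores every non-empty subset with the RSS form
AICc = n·ln(SSres/n) + 2v + 2v(v+1)/(n−v−1), v = m + 1, and aggregates
evidence with the same exp(−Δ/2) weights as the GLM stage.

Caveat: strongly non-Euclidean resemblances (Morisita–Horn on
high-turnover communities especially) give G large negative eigenvalues;
the residual trace can then go negative, making pseudo-F sign-unstable
and AICc undefined (reported as NaN).  This is a property of the method,
not a defect; the √d transform or the Sørensen index avoids it.

## Spatial diagnostics

Moran's I uses k-nearest-neighbour, row-standardised weights (default
k = 2 — the smallest neighbourhood that is not a single-link chain at a
dozen sites; configurable), with inference by permuting the residual
vector (default one-sided "greater", the usual screen for positive
autocorrelation; "less" and "two-sided" available).  Residuals tested are
response residuals for Gaussian fits and deviance residuals for Poisson —
a declared choice.  MRM regresses the vectorised lower triangle of the
response distance matrix on predictor distance matrices, permuting
rows/columns of the response only; coefficient P-values compare |b|
against the permutation distribution, the overall P uses R².

## Synthetic generator

A latent gradient g ∈ [0,1] per site (stratified-uniform, so a 12-site
sample spans the gradient as a deliberate site-selection design would)
drives everything:

* **Landscape.** Riparian cover = 6 + 60g (+ N(0,2), clipped), so 12
  sites span roughly 6–66%.  The anthropogenic block (cattle pasture,
  *Pinus* reforestation, settlements) takes a share of the remaining mass
  falling with g in proportion to `cover_correlation` (at the default 1,
  Spearman ρ(riparian, pasture) ≈ −0.9; at 0 only compositional closure
  links them).  Five further classes split the rest by a Dirichlet draw.
  Shape index (≥ 1) and width (> 0) trend mildly upward with g with
  enough independent noise to survive a collinearity screen against
  riparian cover at n = 12.  Coordinates are uniform on a 20-km square
  with 500-m minimum separation.  Covers sum to 100 exactly.

* **Community.** A pool (default 50 species) gets baseline per-quadrat
  detectabilities from a log-series rank-abundance shape (lognormal
  alternative), scaled so that a 20-quadrat inventory yields realistic
  numbers: per-site totals of a few dozen to ~130 occurrences, richness
  ~8–26, per-site coverage mostly above 85% and pooled coverage ~99%.
  60% of species are specialists whose detection log-odds rise by
  `gradient_strength` (default 7) across the gradient; generalists fall
  by half that.  A site-level damping factor 1 + 0.1·strength·(0.5 − g)
  makes total occurrences fall gently with g while richness and evenness
  rise — the classic pattern of a few hyper-abundant generalists at
  degraded sites.  At strength 0 the generator is exactly null (flat
  richness expectation).  Counts are Binomial(`samples_per_site`, p).

What it does **not** emulate: seasonal structure (occurrences are
pooled), spatially autocorrelated gradients (coordinates are independent
of g, which is why residual Moran's I is expected null), taxonomic
structure, and detection correlations between species.  Passing tests on
this generator therefore demonstrate correct statistics and parameter
recovery under a clean gradient, not robustness to spatially confounded
field data.

## Problem sizes

Defaults used by the test suite and acceptance script: 12 sites, 50-species
pool, 20 quadrats/site; calibration simulations use 400–500 replicates
with 99-permutation tests (bands at ±3 binomial SE around the nominal
0.05), recovery simulations 100–200 replicates; the acceptance script uses
the full 1000/999 SIMPROF and 9999 DistLM permutation defaults.  These
sizes keep a complete run on a single CPU in the minutes range while
leaving the binomial error of every calibration check well inside its
acceptance band.

## Known limitations

* Bootstrap CIs for Hill numbers are percentile intervals without
  bias correction; near-boundary (perfectly even) communities get
  conservative lower bounds.
* Coverage in generated inventories (~86–93% per site) runs a few points
  below a carefully designed field inventory; the generator trades some
  completeness for a heavier rare-species tail.
* DistLM on raw Morisita–Horn distances can be indefinite (above); use
  `sqrt_transform=True` when that matters.
* The SIMPROF recursion stops at nodes with fewer than 3 leaves; pairs
  are reported as their own partition blocks without a test.
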