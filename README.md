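# riparia

Statistical analysis of site-by-species **occurrence data** along landscape
gradients, built for the kind of study that asks: *how much does the
surrounding landscape (habitat cover, patch shape, remnant width) explain the
diversity and composition of communities sampled in habitat remnants?*  The
motivating use case is leaf-litter arthropod inventories in riparian forest
remnants — sites sampled with a fixed number of litter quadrats, species
abundances recorded as occurrence counts — but every component is generic.

## What it computes

**Alpha diversity.** Per-site inventory completeness via the
singleton/doubleton sample-coverage estimator

    Ĉn = (1 − (f₁/n)·[(n−1)f₁ / ((n−1)f₁ + 2f₂)]) · 100

and Hill numbers ^qD = (Σᵢ pᵢ^q)^{1/(1−q)} on relative occurrence frequencies
(q = 0 richness, q = 1 exponential Shannon, q = 2 inverse Simpson), with
seeded multinomial-bootstrap 95% CIs, plus Whittaker rank-abundance profiles.

**Beta diversity.** Pairwise Jaccard, quantitative Sørensen (Bray–Curtis) and
Morisita–Horn similarity (percent scale), UPGMA clustering, and SIMPROF
permutation tests (π statistic) deciding which dendrogram splits reflect real
structure.

**Landscape predictors.** Patch shape index SI = P/(2√(πA)), mean remnant
width, Spearman collinearity screening with an explicit retention priority,
and iterative VIF filtering.

**Regression modelling.** Gaussian and Poisson GLMs per response × predictor;
all-subsets model selection by AICc (qAICc with overdispersion ĉ for counts);
Akaike weights wᵢ = exp(−Δᵢ/2)/Σexp(−Δⱼ/2); 95% confidence sets; per-predictor
importance Σwᵢ; model-averaged coefficients with unconditional variance.
Distance-based linear models (DistLM): Gower-centred resemblance matrices,
permutational pseudo-F, and "BEST" all-subsets AICc selection.

**Spatial diagnostics.** Moran's I of model residuals under k-nearest-
neighbour weights, and multiple regression on distance matrices (MRM) with
Mantel-style permutation inference.

**Synthetic data.** A seeded generator producing landscape tables (nine cover
classes summing to 100%, built-in negative riparian–anthropogenic cover
correlation, configuration metrics, coordinates) and community matrices
(binomial occurrence counts whose richness and evenness rise along the
habitat gradient), so the whole pipeline is testable end to end and
parameter recovery can be verified.

## Worked example

```python
from riparia import SynthConfig, generate_landscape, generate_community
from riparia.glm import all_subsets, multimodel_summary
from riparia.landscape import spearman_screen
from riparia.pipeline import DEFAULT_KEEP_PRIORITY, DEFAULT_PREDICTORS

cfg = SynthConfig(seed=42)
landscape = generate_landscape(cfg)
community = generate_community(landscape, cfg)
richness = (community.counts > 0).sum(axis=1).astype(float)

screen = spearman_screen(landscape, list(DEFAULT_PREDICTORS),
                         keep_priority=DEFAULT_KEEP_PRIORITY)
sel = all_subsets(richness, landscape.predictors(screen.retained))
print(multimodel_summary(sel).round(3))
```

prints

```
              importance  beta_avg  unconditional_variance  n_models
predictor
riparian           0.990     0.205                   0.002        16
shrub_crops        0.115    -0.400                   0.239        16
tree_crops         0.092    -0.348                   0.352        16
scrub_fallow       0.089    -0.117                   0.047        16
tmcf               0.078    -0.034                   0.014        16
```

Riparian cover appears in models carrying 99% of the Akaike weight, and its
averaged coefficient (+0.205 species per % cover) dwarfs its unconditional
variance — the generator's built-in richness gradient is recovered.  The
`examples/` directory holds one short script per capability (alpha, beta +
SIMPROF, GLM model selection, DistLM, full pipeline), each printing the
numbers it computes and a line on how to read them.

A thin CLI wraps the pipeline: `riparia simulate --seed 1 --out data/`,
`riparia run --community data/community.csv --landscape data/landscape.csv
--seed 1 --out results/`.

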