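"""Distance-based linear models: composition vs landscape predictors.

Partitions the variation of a Sorensen resemblance matrix over landscape
predictors, tests each marginally with a permutational pseudo-F, and
runs BEST all-subsets selection by AICc.
"""

import pandas as pd

from riparia import SynthConfig, generate_community, generate_landscape
from riparia.beta import similarity_matrix
from riparia.distlm import (
    distance_from_similarity,
    distlm_best,
    distlm_fit,
    distlm_importance,
    gower_center,
)

cfg = SynthConfig(seed=42)
landscape = generate_landscape(cfg)
community = generate_community(landscape, cfg)

sim = similarity_matrix(community, "sorensen_quantitative")
G = gower_center(distance_from_similarity(sim))
X = landscape.predictors(["riparian", "tmcf", "shape_index", "width_m"])

print("marginal tests (each predictor alone):")
rows = []
for name in X.columns:
    res = distlm_fit(G, X[[name]], n_perm=999, seed=42)
    rows.append({"predictor": name, "pseudo_F": res.pseudo_f, "P": res.p_value,
                 "explained_%": 100 * res.explained_prop})
print(pd.DataFrame(rows).set_index("predictor").round(3))

best = distlm_best(G, X)
print("\nBEST selection, top subsets by AICc:")
print(best.assign(predictors=best["predictors"].map("+".join))[
    ["predictors", "aicc", "delta", "weight"]].head(5).round(2))
print("\npredictor importance over all subsets:")
print(distlm_importance(best).round(3))
print("\nA small P with a large explained % marks a predictor that structures"
      "\ncommunity composition; AICc weights aggregate evidence across subsets.")
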