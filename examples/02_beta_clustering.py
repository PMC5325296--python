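"""Beta diversity: similarity matrices, UPGMA dendrogram, SIMPROF test.

Builds the quantitative Sorensen (Bray-Curtis) similarity matrix of a
synthetic community, clusters sites with UPGMA, and asks SIMPROF which
dendrogram splits reflect real structure rather than sampling noise.
"""

from riparia import SynthConfig, generate_community, generate_landscape
from riparia.beta import similarity_matrix, simprof, upgma

cfg = SynthConfig(seed=42)
community = generate_community(generate_landscape(cfg), cfg)

sim = similarity_matrix(community, "sorensen_quantitative")
print("pairwise similarity (%, first 5 sites):")
print(sim.values.iloc[:5, :5].round(1))

tree = upgma(sim)
print(f"\nUPGMA root merge at {tree.root.height:.1f}% similarity")
print("newick:", tree.to_newick()[:90], "...")

result = simprof(community, "sorensen_quantitative", seed=42)
print("\nSIMPROF node tests (pi large + small P = heterogeneous group):")
print(result.to_frame()[["n_sites", "height_similarity", "pi", "p", "decision"]].round(3))
print(f"significant partition: {len(result.partition)} site groups ->",
      result.partition)
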