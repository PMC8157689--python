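"""Simulate a full study dataset: genotypes, expression, environment, map.

Ten populations of 5-12 diploids drift apart under an island model
(drift parameter F = 0.25); the dataset is written as VCF + TSVs exactly as
the analysis pipeline expects.
"""

from popadapt import SimConfig, simulate_dataset

cfg = SimConfig(seed=1)  # defaults mirror the 10-population sampling design
G, truth, E, env, meta = simulate_dataset(cfg, out_dir="scratch/example_data")

print(f"individuals: {G.n_individuals}, SNP loci: {G.n_loci}, "
      f"unigenes with expression: {E.n_genes}")
print(f"populations: {', '.join(meta.populations)}")
print(f"environmental variables: {list(env.columns)}")
# The truth object records the simulated per-population allele frequencies,
# so estimator output can be compared against what was actually generated.
print(f"first locus ancestral frequency: {truth.ancestral_freqs[0]:.3f}")
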