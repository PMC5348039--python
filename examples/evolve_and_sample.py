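"""The two-step sampling pipeline at micro scale: Moran-process discovery
followed by phenotype-preserving random walks.

A small population seeded with a copy-loop replicator evolves under a
merit-proportional scheduler with one point mutation per offspring; every
few updates the distinct phenotypes present are logged.  Discovered
genotypes then seed double-mutant random walks that sample each phenotype's
genotype network, and the resulting panel yields a pooled one-mutant
transition matrix."""

from avidalite import (
    EvolutionConfig,
    build_panel,
    moran_evolve,
    standard_evaluator,
    transition_matrix,
)
from avidalite.micro import copy_loop_replicator

ev = standard_evaluator()
cfg = EvolutionConfig(population_size=15, updates=30, record_interval=10, seed=3)
log = moran_evolve(cfg, copy_loop_replicator(15), ev)
print("cumulative distinct phenotypes:", log.distinct_series)

starts = log.representatives(seed=1)
print("representative genotype per phenotype:", {p: g for p, g in starts.items()})

panel = build_panel({p: [g] for p, g in starts.items()}, ev,
                    per_phenotype=5, steps=20, seed=2)
tm = transition_matrix(panel.genomes(), ev)
for i in tm.phenotypes:
    print(f"phenotype {i}: robustness {float(tm.robustness(i)):.4f}, "
          f"lethality {float(tm.lethality(i)):.4f} "
          f"({int(tm.row_neighbors.at[i])} pooled neighbors)")
print("Each row pools all L*(A-1) one-mutant neighbors of every panel genome;")
print("rows sum to 1 over {inviable} + phenotypes by construction.")
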