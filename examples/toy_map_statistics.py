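"""Exact genotype-phenotype map statistics on a fully enumerated toy map.

A seeded toy map labels every genome of a 4-letter, length-8 space (65,536
genotypes) with one of 4 phenotypes or 'inviable', with skewed target
frequencies.  Because the space is complete, the transition matrix is exact
and the identity p_i->j / p_j->i = N_j / N_i holds in rational arithmetic,
so phenotype frequencies estimated from transition ratios reproduce the
true genotype counts exactly."""

from fractions import Fraction

from avidalite import estimate_frequencies, evolvability, make_toy_map
from avidalite.micro import brute_force_transitions

toy = make_toy_map(length=8, n_letters=4, freqs=[0.4, 0.3, 0.2, 0.05], seed=7)
counts = toy.label_counts()
print("genotypes per label:", counts, " (label -1 = inviable)")

tm, _ = brute_force_transitions(toy)
print("\nrobustness / lethality per phenotype:")
for i in tm.phenotypes:
    print(f"  {i}: p_ii={float(tm.robustness(i)):.4f}  p_i0={float(tm.lethality(i)):.4f}")

freqs = estimate_frequencies(tm, reference=0)
print("\nfrequencies from transition ratios (N_0 = 1):")
for i, est in freqs.items():
    truth = Fraction(counts[i], counts[0])
    print(f"  N_{i} = {float(est.value):.5f} ({est.method}); true ratio {float(truth):.5f}; "
          f"exact match: {est.value == truth}")

print("\nevolvability (4-phenotype space):")
for i in tm.phenotypes:
    e = evolvability(tm, i, freqs[i].value, n_phenotypes=4)
    print(f"  {i}: genotypic={e.genotypic} constrained={e.constrained} "
          f"phenotypic={e.phenotypic:.3f}" if e.phenotypic is not None else
          f"  {i}: genotypic={e.genotypic} constrained={e.constrained}")
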