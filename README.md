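# avidalite

A minimal Avida-style digital-organism virtual machine plus a complete
genotype–phenotype map analysis toolkit, built so that every estimator can be
validated against exhaustive brute-force oracles at desk scale.

**Who it is for.**  Researchers in artificial life and molecular evolution
who want to study genotype–phenotype maps — robustness, genotype networks,
evolvability, transition asymmetries — in a system where the *entire* map can
be enumerated at micro scale and sampled honestly at larger scales.

## The system

A digital organism is a circular genome of `L` instructions over a 26-letter
alphabet, run by a virtual CPU.  It is **viable** if it self-replicates
(allocate → copy → divide, producing an exact copy) within `20·L` executed
instructions.  Its **phenotype** is the subset of nine Boolean logic tasks
(NOT, NAND, AND, OR_N, OR, AND_N, NOR, XOR, EQU) it computes on random
environment inputs before dividing — a 9-bit mask, so the phenotype space has
`2⁹ = 512` members, while the genotype space at `L = 100` has
`26¹⁰⁰ ≈ 3.14·10¹⁴¹`.

Core quantities, for phenotypes *i*, *j* and one-mutant neighborhoods of
size `L(A−1)`:

- transition probability `p_{i→j}`: pooled fraction of one-mutant neighbors
  of phenotype-*i* genotypes with outcome *j*; `p_{i→0}` = inviable fraction
  (lethality), `p_{i→i}` = mutational robustness;
- the exact ratio identity `p_{i→j}/p_{j→i} = N_j/N_i` (substitutions are
  reversible, so complete counts satisfy `n_ij = n_ji`), which turns
  transition ratios into phenotype-frequency estimates `N_i` relative to the
  merely viable phenotype (`N_0 = 1`);
- asymmetry `AS(i,j) = |p_{i→j} − p_{j→i}| / max(p_{i→j}, p_{j→i})`;
- three evolvability variants (genotypic, constrained-to-task-gains,
  phenotypic = reachable fraction × `N_i`);
- task complexity = minimum NAND-gate executions (by exhaustive circuit
  search): 1,1,2,2,3,3,4,4,5 for the nine tasks; phenotype complexity =
  sum over the mask / 25.

Samplers include uniform viability screening, a Moran-process simulator with
merit rewards for tasks, phenotype-preserving double-mutant random walks,
distance-non-increasing connectivity walks (strict and gain-permitting
modes), and greedy minimal-genome reduction with an exhaustive
deletion-criticality certificate.

## Worked example

```bash
python examples/micro_space.py
```

```
space size 81, viable 18 (exact viable fraction 0.2222)
viable replicators: xwvw wxvw wvxw xwwv wxwv xxwv xwvv wxvv wwxv xwxv wvxv wxxv wvwx wwvx xwvx wvvx wxvx wvxx

exact one-mutant outcome fractions for the merely-viable phenotype:
  robustness p_00 = 0.3889
  lethality  p_0->inviable = 0.6111

uniform screening: found 10 viable in 54 draws (estimate 0.185 vs exact 0.222)
```

The 81-genome space over `{h-alloc, h-copy, h-divide}` at `L = 4` is
enumerated exhaustively: 18 genomes are genuine self-replicators, so the true
viable fraction is 2/9.  Pooling all 8 one-mutant neighbors of every viable
genome gives the *exact* transition row for the merely-viable phenotype:
38.9% of mutations preserve viability, 61.1% are lethal.  The last line runs
the same uniform screening used at full scale and shows its estimate landing
near the exact value.

Other examples, one per capability:

- `examples/run_replicator.py` — test-environment evaluation of a
  100-instruction copy-loop replicator (gestation 389 instructions) and its
  NAND-performing variant (phenotype id 2);
- `examples/nand_complexity.py` — derives the nine task complexities by
  NAND-circuit search;
- `examples/toy_map_statistics.py` — exact transition matrix, frequency
  recovery (`N_i` exactly equal to true genotype-count ratios) and
  evolvability on a fully enumerated 65,536-genome toy map;
- `examples/evolve_and_sample.py` — Moran discovery → random-walk panel →
  pooled transition matrix, end to end at micro scale.

A thin CLI mirrors the shell-worthy operations:

```bash
avidalite run-test genomes.txt --seed 42 --out results.tsv
avidalite enumerate --length 4 --alphabet wvx --out space.tsv
avidalite toy-map --length 8 --letters 4 --labels 4 --freqs 0.4,0.3,0.2,0.05 --seed 7 --out tm.tsv
```

## Layout

```
src/avidalite/
  instructions.py  26-letter instruction alphabet
  vm.py            virtual CPU, test environment      docs/instruction_set.md
  logic.py         9 tasks, phenotype masks, complexity
  nandcount.py     NAND-circuit minimum-gate search
  genome.py        genome strings and text I/O
  evaluator.py     genotype -> (viable, phenotype) protocol
  sampling.py      viability screening, walks, panels
  moran.py         Moran-process discovery simulator
  analysis.py      transition matrices, robustness, evolvability,
                   frequencies, connectivity, reduction
  micro.py         micro spaces, planted replicators, toy GP maps
  cli.py           thin command-line surface
docs/methods.md    model assumptions, parameters, limitations
```
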