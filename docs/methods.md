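# Methods

## The model

A digital organism is a genome of `L` instructions over an `A = 26` letter
alphabet, executed circularly by a virtual CPU (registers AX/BX/CX, two
stacks, four heads, two input buffers; see `docs/instruction_set.md`).  The
genotype space has `A^L` members — about `3.14e141` at the standard `L = 100`.
An organism is *viable* if, executing alone in the test environment with no
mutations, it produces a letter-perfect copy of itself within `20 * L`
executed instructions.  The budget exists because viability is undecidable in
general (an organism may loop forever); `20 * L` is the standard cutoff and
is configurable via `VMConfig.limit_factor`.

The *phenotype* is the set of Boolean logic tasks the organism performs
before dividing, out of nine: NOT, NAND, AND, OR_N, OR, AND_N, NOR, XOR, EQU
— a 9-bit mask, hence `2^9 = 512` phenotypes, with mask 0 the merely-viable
(no-trait) phenotype.  A task is credited when an emitted output word equals
that task's result on the two buffered input words at the moment of emission
(unary NOT is tried on each input; the order-sensitive OR_N/AND_N are
accepted in either operand order; emissions before two inputs exist match
nothing).  Credits accumulate over a gestation and each task counts at most
once.  With 32-bit random inputs a spurious match has probability `2^-32`
per task per emission; at reduced micro word widths spurious matches are
correspondingly more common, which is acceptable because micro spaces
validate identities, not magnitudes.

Task complexity is the minimum number of NAND gate executions needed to
compute the task, derived in-package by breadth-first search over
straight-line NAND programs on 4-row truth tables (gate outputs are
reusable; that is why AND costs 2, not the 3 a gate *tree* would need):
NOT 1, NAND 1, AND 2, OR_N 2, OR 3, AND_N 3, NOR 4, XOR 4, EQU 5.
Phenotype complexity is the sum over the mask, normalized by the all-task
total of 25.  Exact shared-circuit minimization for multi-task phenotypes is
out of scope; the sum is the intended approximation.

## Sampling pipeline

1. **Uniform screening** (`sample_random_viable`): i.i.d. uniform genomes
   evaluated for viability until a quota is met, with a draw cap for bounded
   runtime.  At full scale the viable fraction is of order 1e-7, so the
   desk-scale suites exercise this on enumerable micro spaces where the true
   fraction is known exactly.
2. **Moran-process discovery** (`moran_evolve`): a fixed-size population in
   which each legal division places a once-mutated offspring over a
   uniformly chosen victim.  One update dispenses
   `population_size * 30` instruction executions, allotted by a multinomial
   draw proportional to merit; merit multiplies by a per-task reward factor,
   default `2^complexity` (NOT,NAND x2 ... EQU x32), multiplicative across
   tasks.  The reward ladder and its multiplicativity are configuration
   knobs (`EvolutionConfig.reward_multipliers`).  Organisms allotted cycles
   are processed in a random permutation within an update and an offspring
   born mid-update first executes in the next update — a discrete
   approximation of a continuous scheduler that is exact in distribution at
   the update scale used here.  Every `record_interval` updates the log
   stores one random representative genotype per phenotype present.
3. **Double-mutant walks** (`double_mutant_walk`, `build_panel`): from each
   discovered genotype, steps substitute two *distinct* random positions
   with uniform random letters (possibly silently — both choices are the
   conventional reading of "replaced by a random instruction"; the flag
   `allow_silent_substitution` documents the alternative for the Moran
   mutations) and are reverted unless viability and phenotype are preserved;
   after the configured number of accepted steps (1000 at full scale) the
   endpoint joins the phenotype's panel.  A retry cap (default 1e5
   proposals per step) converts a phenotype with no accessible double
   mutants into an explicit error rather than a hang.

## Map statistics

For each phenotype `i`, all `L*(A-1)` one-mutant neighbors of each panel
genome are pooled; the fraction with outcome `j` (a phenotype, or inviable)
is the transition probability `p_i->j`.  Counts are kept as integers and the
denominators explicitly, so probabilities are exact rationals and an entry
below the sampling resolution is exactly zero by construction.  Robustness
is `p_i->i`, lethality `p_i->0`; each row partitions to 1 exactly.

Because every point substitution is reversible, complete counts satisfy
`n_ij = n_ji` and therefore `p_i->j / p_j->i = N_j / N_i` with no
approximation, where `N` counts genotypes per phenotype.  Frequencies are
estimated relative to the merely-viable reference (`N_0 = 1`) as
`N_i = p_0->i / p_i->0-ref`; when a phenotype never borders the reference the
estimate walks the shortest path of reciprocal nonzero transitions and
multiplies the ratios (flagged `indirect` — a generalization of the direct
single-trait estimate; `inestimable` when no such path exists).  Transition
asymmetry is `AS(i,j) = |p_i->j - p_j->i| / max(p_i->j, p_j->i)`.

Evolvability comes in three variants: *genotypic* (distinct phenotypes
`j != i` reached), *constrained* (fraction of strict-superset phenotypes
reached — those computing at least one additional task — undefined for the
all-task phenotype), and *phenotypic* (reached fraction of phenotype space
times `N_i`).

Connectivity walks (`connect_walk`) move one member of a same-phenotype pair
by single substitutions that preserve viability, preserve the phenotype
(strict mode) or allow task gains but never losses (gains/exaptation mode),
and never increase the Hamming distance to the target; moves to *equal*
distance are allowed, since forbidding only increases is the natural reading
and plateaus are what let walks round corners.  Distances are anchored
(no rotational alignment) even though execution is circular — mutation and
distance address positions, not phases; this is deliberate and means a
rotated replicator is a *different* genotype.

Minimal genomes (`reduce_genome`) delete one random position at a time while
viability and phenotype survive; termination is certified exhaustively (the
final pass tries every position), so every single-deletion variant of the
output is broken by construction.

## Synthetic data and what passing tests show

Two stand-ins make everything testable by brute force:

* **Micro VM spaces** (`MicroConfig`, `enumerate_space`): genome lengths of
  4-5 over alphabets of 3-8 instructions (budget-guarded at 1e7
  evaluations), small word widths, evaluated exhaustively.  The default
  test space — `{h-alloc, h-copy, h-divide}` at `L = 4`, 81 genomes —
  contains 18 genuine self-replicators (e.g. `wvvx`), giving exact
  viability fractions, exact neighbor classifications, and exhaustively
  known genotype-network components.
* **Toy genotype-phenotype maps** (`ToyGPMap`): every genome of a small
  space receives a label (phenotype id or inviable) by keyed blake2b
  hashing — a pure function of the seed — with label counts tracking a
  target frequency profile (within ~2% for spaces of 1e5+).  Toy maps
  bypass the VM entirely, so analysis-level oracles cannot be confounded by
  VM semantics.  The exhaustive transition matrix is computed by vectorized
  index arithmetic, an implementation route independent of the
  string-and-evaluator route used by the analysis module; tests require the
  two to agree exactly.

These stand-ins emulate enumerable structure, not full-scale statistics:
micro viability fractions are ~0.2 rather than ~1e-7, toy-map labels have no
epistatic texture, and micro phenotype spaces hold few tasks.  Passing tests
therefore certify the estimators and identities (row partitions, ratio
identity, estimator consistency, walk acceptance rules), not the numerical
values any full-scale screen would produce.

## Problem sizes and numerical choices

The shipped suites use: 81-genome micro spaces; toy maps of 65,536 genomes
(4 letters, length 8) with 4 or 8 labels; sampled panels of 100/1000/10000
genomes per label for the consistency checks (entry errors within 3 binomial
standard errors for at least 99% of entries, pooled across sizes);
Moran populations of 12-20 organisms for tens of updates; and a few hundred
capped draws for full-scale screening mechanics.  Random sources are the
stdlib Mersenne Twister and numpy's PCG64, always explicitly seeded;
environment streams, toy labelings, walks and simulations are bit-reproducible
from their seeds across platforms.  Empty-stack pops yield 0; there is no
division instruction, so no divide-by-zero path exists; word arithmetic wraps
at the configured width.

## Known limitations

* The Moran scheduler's update-granular allotment slightly distorts
  within-update timing relative to a cycle-exact scheduler; at the
  population sizes used the distortion is far below sampling noise.
* `estimate_frequencies`' path-product extension inherits multiplied
  sampling error on long paths; estimates are flagged so users can filter.
* Task detection checks the two most recent inputs only; a variant that
  also checks the third-most-recent input would credit slightly more
  task executions in convoluted genomes.
* Insertion/deletion mutations, resource models, spatial structure and
  multi-environment plasticity are out of scope throughout.
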