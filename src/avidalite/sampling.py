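"""Genotype-space sampling: uniform viability screening, phenotype-preserving
double-mutant random walks, and per-phenotype genotype panels.

The full pipeline mirrors a two-step protocol: random uniform screening
finds merely viable genomes; reward-driven evolution (see
:mod:`avidalite.moran`) discovers the rarer task-performing phenotypes; and
1000-step double-mutant random walks starting from discovered genotypes
produce, for each phenotype, a panel of independently sampled genotypes on
its genotype network.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .evaluator import PhenotypeEvaluator
from .genome import random_genome


@dataclass(frozen=True)
class ViabilitySample:
    genomes: tuple[str, ...]
    n_draws: int
    capped: bool

    @property
    def viable_fraction(self) -> float:
        """Implied viability estimate: viable / total draws."""
        if self.n_draws == 0:
            return 0.0
        return len(self.genomes) / self.n_draws


def sample_random_viable(
    n_viable: int,
    length: int,
    seed: int,
    evaluator: PhenotypeEvaluator,
    max_draws: int | None = None,
) -> ViabilitySample:
    """Draw uniform random genomes until ``n_viable`` viable ones are found.

    Each position is uniform over the evaluator's alphabet.  ``max_draws``
    bounds the runtime; hitting the cap returns fewer genomes with
    ``capped=True``.  Deterministic given the seed.
    """
    rng = random.Random(seed)
    found: list[str] = []
    draws = 0
    while len(found) < n_viable:
        if max_draws is not None and draws >= max_draws:
            return ViabilitySample(tuple(found), draws, True)
        g = random_genome(length, rng, evaluator.alphabet)
        draws += 1
        viable, _ = evaluator.evaluate(g)
        if viable:
            found.append(g)
    return ViabilitySample(tuple(found), draws, False)


class WalkStuckError(RuntimeError):
    def __init__(self, step: int, genome: str):
        super().__init__(
            f"double-mutant walk stuck at step {step}: no accessible double "
            f"mutant within the retry cap"
        )
        self.step = step
        self.genome = genome


def double_mutant_walk(
    start: str,
    steps: int,
    seed: int,
    evaluator: PhenotypeEvaluator,
    retry_cap: int = 100_000,
) -> str:
    """Phenotype-preserving random walk of ``steps`` accepted double
    mutations.

    Each step substitutes two distinct random positions with uniform random
    letters (possibly silently); steps producing an inviable organism or a
    changed phenotype are reverted and retried.  Returns the final genome,
    whose phenotype equals the start phenotype.
    """
    viable, pheno = evaluator.evaluate(start)
    if not viable:
        raise ValueError("start genome must be viable")
    rng = random.Random(seed)
    alphabet = evaluator.alphabet
    current = start
    L = len(start)
    for step_no in range(steps):
        for _ in range(retry_cap):
            p1 = rng.randrange(L)
            p2 = rng.randrange(L - 1)
            if p2 >= p1:
                p2 += 1
            l1, l2 = rng.choice(alphabet), rng.choice(alphabet)
            cand = list(current)
            cand[p1], cand[p2] = l1, l2
            cand = "".join(cand)
            v, p = evaluator.evaluate(cand)
            if v and p == pheno:
                current = cand
                break
        else:
            raise WalkStuckError(step_no, current)
    return current


@dataclass(frozen=True)
class PanelEntry:
    genome: str
    start_genome: str
    walk_seed: int


@dataclass
class PhenotypePanel:
    """phenotype id -> independently sampled genomes with provenance."""

    entries: dict[int, list[PanelEntry]] = field(default_factory=dict)

    def genomes(self) -> dict[int, list[str]]:
        return {p: [e.genome for e in es] for p, es in self.entries.items()}

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (p, e.genome, e.start_genome, e.walk_seed)
            for p, es in sorted(self.entries.items())
            for e in es
        ]
        pd.DataFrame(
            rows, columns=["phenotype_id", "genome", "start_genome", "walk_seed"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypePanel":
        df = pd.read_csv(path, sep="\t")
        panel = cls()
        for row in df.itertuples(index=False):
            panel.entries.setdefault(int(row.phenotype_id), []).append(
                PanelEntry(row.genome, row.start_genome, int(row.walk_seed))
            )
        return panel


def build_panel(
    starts: dict[int, list[str]],
    evaluator: PhenotypeEvaluator,
    per_phenotype: int = 1000,
    steps: int = 1000,
    seed: int = 0,
    retry_cap: int = 100_000,
) -> PhenotypePanel:
    """Run one double-mutant walk per requested sample, cycling over the
    available start genomes of each phenotype.

    Raises if any requested phenotype has no start genome; every panel
    member re-evaluates to its key phenotype.
    """
    if any(isinstance(gs, str) for gs in starts.values()):
        raise TypeError("starts must map phenotype -> list of genomes, not a bare string")
    missing = [p for p, gs in starts.items() if not gs]
    if missing:
        raise ValueError(f"no discovered genomes for phenotypes {missing}")
    panel = PhenotypePanel()
    counter = 0
    for pheno in sorted(starts):
        pool = starts[pheno]
        entries = []
        for k in range(per_phenotype):
            start = pool[k % len(pool)]
            walk_seed = (seed * 1_000_003 + counter) % (2**31)
            counter += 1
            end = double_mutant_walk(start, steps, walk_seed, evaluator, retry_cap)
            entries.append(PanelEntry(end, start, walk_seed))
        panel.entries[pheno] = entries
    return panel
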