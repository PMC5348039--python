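"""Moran-process evolution with CPU-cycle task rewards.

A fixed-size population of digital organisms executes concurrently; whenever
an organism produces a (structurally) legal offspring, the offspring —
carrying a configured number of point mutations — replaces one organism
chosen uniformly at random, so the population size is strictly conserved.
Execution cycles are dispensed in updates: one update hands out
``population_size * instructions_per_update`` instruction executions,
allotted to organisms proportionally to merit.  Performing logic tasks
multiplies an organism's merit by per-task reward factors, which selects for
genomes that compute them.

Every ``record_interval`` updates the simulation records, per distinct
phenotype present, one randomly chosen representative genotype — the
discovery log from which per-phenotype start genomes for the random-walk
sampler are drawn.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import instructions as ins
from .evaluator import VMEvaluator
from .logic import TASK_COMPLEXITY, TASK_NAMES, mask_tasks
from .vm import CpuState, EnvironmentStream, VMConfig, initial_state, step

#: Default merit multiplier per task: 2 ** complexity (NOT,NAND x2; AND,OR_N
#: x4; OR,AND_N x8; NOR,XOR x16; EQU x32), multiplicative across tasks.
DEFAULT_REWARDS = {name: float(2 ** TASK_COMPLEXITY[name]) for name in TASK_NAMES}


@dataclass(frozen=True)
class EvolutionConfig:
    population_size: int = 10_000
    updates: int = 1_000_000
    instructions_per_update: int = 30
    mutations_per_offspring: int = 1
    reward_multipliers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REWARDS))
    record_interval: int = 1000
    seed: int = 0
    allow_silent_substitution: bool = True

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.mutations_per_offspring < 0:
            raise ValueError("mutations_per_offspring must be >= 0")


@dataclass
class DiscoveryLog:
    """Per-interval records of (update, phenotype id, representative genome)
    and the cumulative distinct-phenotype count."""

    records: list[tuple[int, int, str]] = field(default_factory=list)
    distinct_series: list[tuple[int, int]] = field(default_factory=list)

    def phenotypes(self) -> set[int]:
        return {p for _, p, _ in self.records}

    def representatives(self, seed: int = 0) -> dict[int, str]:
        """One genotype per phenotype, chosen at random from those recorded."""
        rng = random.Random(seed)
        by_pheno: dict[int, list[str]] = {}
        for _, p, g in self.records:
            by_pheno.setdefault(p, []).append(g)
        return {p: rng.choice(gs) for p, gs in by_pheno.items()}


class _Organism:
    __slots__ = ("genome", "codes", "state", "env", "merit")

    def __init__(self, genome: str, env_seed: int, width: int, merit: float):
        self.genome = genome
        self.codes = ins.to_codes(genome)
        self.state: CpuState = initial_state(self.codes)
        self.env = EnvironmentStream(env_seed, width)
        self.merit = merit

    def reset(self):
        self.state = initial_state(self.codes)


def moran_evolve(
    config: EvolutionConfig,
    ancestor: str,
    evaluator: VMEvaluator | None = None,
) -> DiscoveryLog:
    """Evolve a population seeded with a viable ancestor; returns the
    phenotype discovery log.  Deterministic given the config seed."""
    evaluator = evaluator or VMEvaluator()
    viable, _ = evaluator.evaluate(ancestor)
    if not viable:
        raise ValueError("ancestor must be viable")

    vm_cfg = evaluator.cfg
    # In-world divisions are structural: offspring legality does not require
    # a faithful copy (mutations are applied on top of whatever was copied).
    rng = random.Random(config.seed)
    width = vm_cfg.word_width
    alphabet = vm_cfg.alphabet

    def merit_of(genome: str) -> float:
        v, mask = evaluator.evaluate(genome)
        m = 1.0
        if v:
            for task in mask_tasks(mask):
                m *= config.reward_multipliers.get(task, 1.0)
        return m

    def phenotype_of(genome: str) -> int:
        v, mask = evaluator.evaluate(genome)
        return mask if v else 0

    pop = [
        _Organism(ancestor, rng.randrange(2**31), width, merit_of(ancestor))
        for _ in range(config.population_size)
    ]
    log = DiscoveryLog()
    seen: set[int] = set()

    def record(update: int):
        present: dict[int, list[int]] = {}
        for i, org in enumerate(pop):
            v, mask = evaluator.evaluate(org.genome)
            if v:
                present.setdefault(mask, []).append(i)
        for pheno, members in sorted(present.items()):
            rep = pop[rng.choice(members)]
            log.records.append((update, pheno, rep.genome))
            seen.add(pheno)
        log.distinct_series.append((update, len(seen)))

    def mutate(codes: list[int]) -> str:
        letters = list(ins.to_letters(codes))
        for _ in range(config.mutations_per_offspring):
            pos = rng.randrange(len(letters))
            while True:
                letter = rng.choice(alphabet)
                if config.allow_silent_substitution or letter != letters[pos]:
                    break
            letters[pos] = letter
        return "".join(letters)

    total_cycles = config.population_size * config.instructions_per_update
    record(0)
    for update in range(1, config.updates + 1):
        merits = [org.merit for org in pop]
        total_merit = sum(merits)
        # Merit-proportional allotment of this update's instruction cycles.
        allotment = _multinomial(rng, total_cycles, merits, total_merit)
        order = list(range(len(pop)))
        rng.shuffle(order)
        for i in order:
            org = pop[i]
            replaced_self = False
            for _ in range(allotment[i]):
                step(org.state, vm_cfg, org.env)
                if org.state.offspring is not None:
                    child_genome = mutate(org.state.offspring)
                    org.reset()
                    victim = rng.randrange(len(pop))
                    pop[victim] = _Organism(
                        child_genome, rng.randrange(2**31), width, merit_of(child_genome)
                    )
                    if victim == i:
                        replaced_self = True
                        break
            if replaced_self:
                continue
        if update % config.record_interval == 0 or update == config.updates:
            record(update)
    return log


def _multinomial(rng: random.Random, n: int, weights: list[float], total: float) -> list[int]:
    """Sequential binomial decomposition of a multinomial draw using the
    stdlib RNG (keeps the whole simulation on one seeded generator)."""
    counts = [0] * len(weights)
    remaining = n
    acc = total
    for i, w in enumerate(weights[:-1]):
        if remaining == 0 or acc <= 0:
            break
        p = min(max(w / acc, 0.0), 1.0)
        c = _binomial(rng, remaining, p)
        counts[i] = c
        remaining -= c
        acc -= w
    counts[-1] += remaining
    return counts


def _binomial(rng: random.Random, n: int, p: float) -> int:
    if p >= 1.0:
        return n
    if p <= 0.0 or n == 0:
        return 0
    # Inversion by waiting times is O(np); fine at micro scale.
    if n * p < 500:
        count = 0
        for _ in range(n):
            if rng.random() < p:
                count += 1
        return count
    # Normal approximation for large n*p keeps updates cheap.
    mu = n * p
    sigma = (n * p * (1 - p)) ** 0.5
    return min(n, max(0, round(rng.gauss(mu, sigma))))
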