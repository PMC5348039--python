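"""Genotype -> (viability, phenotype) evaluation interface.

Every analysis operation (neighbor classification, walks, transition
matrices, genome reduction) is written against this small protocol so the
same code runs on the real virtual machine and on fully enumerated toy
genotype-phenotype maps, which serve as brute-force oracles.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

from .instructions import LETTERS
from .vm import EnvironmentStream, TestResult, VMConfig, run_test


@runtime_checkable
class PhenotypeEvaluator(Protocol):
    """Maps a genome string to (viable, phenotype id), purely."""

    alphabet: str

    def evaluate(self, genome: str) -> tuple[bool, int]: ...


class VMEvaluator:
    """Phenotype evaluation through the virtual-CPU test environment.

    The environment seed is fixed per evaluator so that phenotype is a pure
    function of genotype; results are cached.
    """

    def __init__(self, cfg: VMConfig | None = None, env_seed: int = 42):
        self.cfg = cfg or VMConfig()
        self.env_seed = env_seed
        self.alphabet = self.cfg.alphabet
        self._cache: dict[str, tuple[bool, int]] = {}

    def test(self, genome: str) -> TestResult:
        """Full test-environment result (uncached)."""
        env = EnvironmentStream(self.env_seed, self.cfg.word_width)
        return run_test(genome, env, self.cfg)

    def evaluate(self, genome: str) -> tuple[bool, int]:
        hit = self._cache.get(genome)
        if hit is None:
            res = self.test(genome)
            hit = (res.viable, res.phenotype)
            self._cache[genome] = hit
        return hit

    @property
    def cache_size(self) -> int:
        return len(self._cache)


def standard_evaluator(env_seed: int = 42, **cfg_kwargs) -> VMEvaluator:
    """Evaluator with the standard configuration: 32-bit words, full
    26-letter alphabet, 20xL execution budget, exact-copy fidelity."""
    return VMEvaluator(VMConfig(alphabet=cfg_kwargs.pop("alphabet", LETTERS), **cfg_kwargs), env_seed)
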