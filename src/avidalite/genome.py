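"""Genome representation and text I/O.

A genome is a plain string of lower-case letters a-z, one instruction per
character, executed circularly but indexed positionally (mutation and
distance never consider rotations).  The on-disk format is one genome per
line; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import random
from pathlib import Path

from .instructions import LETTERS


def validate_genome(genome: str, alphabet: str = LETTERS) -> str:
    if len(genome) < 1:
        raise ValueError("genome must have length >= 1")
    bad = set(genome) - set(alphabet)
    if bad:
        raise ValueError(f"genome contains letters outside the alphabet: {sorted(bad)}")
    return genome


def random_genome(length: int, rng: random.Random, alphabet: str = LETTERS) -> str:
    """Uniform random genome: each position independent and uniform over the alphabet."""
    return "".join(rng.choice(alphabet) for _ in range(length))


def substitute(genome: str, position: int, letter: str) -> str:
    return genome[:position] + letter + genome[position + 1:]


def read_genomes(path: str | Path) -> list[str]:
    genomes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genomes.append(validate_genome(line))
    return genomes


def write_genomes(path: str | Path, genomes: list[str], header: str | None = None) -> None:
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    lines.extend(genomes)
    Path(path).write_text("\n".join(lines) + "\n")
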