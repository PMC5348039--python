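"""Enumerable micro-scale spaces, planted replicator fixtures, and toy
genotype-phenotype maps.

The full-scale genotype space (26^100 genotypes at L = 100) is astronomically
large, so every analysis operation here is validated on two kinds of
desk-scale stand-ins:

* micro VM configurations — tiny genome lengths over a restricted instruction
  alphabet whose spaces can be enumerated exhaustively and which contain
  planted self-replicators;
* toy genotype->phenotype maps — seeded, fully enumerated labelings of a
  small sequence space with controllable phenotype frequencies, which bypass
  the VM entirely so analysis-level oracles cannot be confounded by VM
  decisions.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import INVIABLE, TransitionMatrix
from .evaluator import VMEvaluator
from .instructions import LETTERS
from .vm import VMConfig

#: Smallest instruction set supporting replication and task computation
#: under the write-head-at-alloc convention (see docs/instruction_set.md):
#: nop-b, nop-c, h-alloc, h-copy, h-divide, h-search, nand, IO.
MICRO_ALPHABET = "bcwvxzuy"

DEFAULT_ENUMERATION_BUDGET = 10**7


# ---------------------------------------------------------------------------
# planted fixtures

def micro_replicator() -> str:
    """Four-instruction self-replicator ``wvvx`` (h-alloc, h-copy, h-copy,
    h-divide).  It copies its first two instructions, then finishes the copy
    by executing the partially built child, and divides with a faithful
    offspring on the second pass."""
    return "wvvx"


def copy_loop_replicator(length: int = 50) -> str:
    """Canonical copy-loop replicator: allocate, find the end label, position
    the write head, then a tight h-copy loop terminated by if-label /
    h-divide when the trailing label has been copied.  Any length >= 15."""
    if length < 15:
        raise ValueError("copy-loop replicator needs length >= 15")
    return "wzcag" + "c" * (length - 14) + "zvfcaxgab"


def nand_replicator(length: int = 50) -> str:
    """Copy-loop replicator with a NAND task block (IO, swap, IO, nand, IO)
    executed before replication.  The block sits directly before the copy
    loop so its final IO is not followed by a nop (a trailing nop would be
    consumed as a register modifier and redirect the output).  Any length
    >= 20."""
    if length < 20:
        raise ValueError("nand replicator needs length >= 20")
    return "wzcagc" + "c" * (length - 20) + "yryuy" + "zvfcaxgab"


def loop_trap(length: int = 100) -> str:
    """Organism stuck in a 10-position loop until timeout: h-search marks the
    loop start, mov-head jumps back forever.  Executes exactly 10 distinct
    positions."""
    if length < 10:
        raise ValueError("loop trap needs length >= 10")
    return "z" + "c" * 7 + "ga" + "c" * (length - 10)


# ---------------------------------------------------------------------------
# micro VM spaces

@dataclass(frozen=True)
class MicroConfig:
    """Enumerable micro-scale VM configuration."""

    length: int = 4
    alphabet: str = "wvx"
    word_width: int = 8
    limit_factor: int = 20
    fidelity: str = "exact"
    enumeration_budget: int = DEFAULT_ENUMERATION_BUDGET

    def __post_init__(self):
        bad = set(self.alphabet) - set(LETTERS)
        if bad:
            raise ValueError(f"letters outside the 26-instruction set: {sorted(bad)}")

    @property
    def space_size(self) -> int:
        return len(self.alphabet) ** self.length

    def vm_config(self) -> VMConfig:
        return VMConfig(
            word_width=self.word_width,
            limit_factor=self.limit_factor,
            fidelity=self.fidelity,
            alphabet=self.alphabet,
        )

    def evaluator(self, env_seed: int = 42) -> VMEvaluator:
        return VMEvaluator(self.vm_config(), env_seed)


def enumerate_space(cfg: MicroConfig, env_seed: int = 42) -> pd.DataFrame:
    """Evaluate every genome of the micro space in the test environment.

    Returns a DataFrame with columns genome, viable, phenotype_id, in
    enumeration (odometer) order; deterministic given the environment seed.
    """
    if cfg.space_size > cfg.enumeration_budget:
        raise ValueError(
            f"space size {cfg.space_size} exceeds the enumeration budget "
            f"{cfg.enumeration_budget}"
        )
    evaluator = cfg.evaluator(env_seed)
    A, L = len(cfg.alphabet), cfg.length
    rows = []
    for index in range(cfg.space_size):
        digits = []
        x = index
        for _ in range(L):
            digits.append(x % A)
            x //= A
        genome = "".join(cfg.alphabet[d] for d in digits)
        viable, pheno = evaluator.evaluate(genome)
        rows.append((genome, viable, pheno))
    return pd.DataFrame(rows, columns=["genome", "viable", "phenotype_id"])


def write_table(df: pd.DataFrame, path: str | Path, config: dict) -> None:
    """Serialize an enumerated table as TSV plus a JSON sidecar with the
    generating configuration."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(config, indent=2))


# ---------------------------------------------------------------------------
# toy genotype-phenotype maps

@dataclass
class ToyGPMap:
    """Seeded, fully enumerated genotype -> phenotype labeling.

    Genomes are strings of length ``length`` over the first ``n_letters``
    letters of the instruction alphabet.  Each genome receives exactly one
    label — an integer phenotype id, or ``INVIABLE`` (-1) — by keyed hashing
    of its digits, so the labeling is a pure function of the seed and label
    counts track the target frequency profile to within sampling error of
    the hash (within about 2% for spaces of 1e5 genomes or more).
    """

    length: int
    n_letters: int
    labels_profile: dict[int, float]  # phenotype id -> target frequency
    seed: int
    _labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        total = sum(self.labels_profile.values())
        if total > 1 + 1e-12:
            raise ValueError("label frequencies must sum to <= 1")
        if len(self.labels_profile) < 2:
            raise ValueError("need at least 2 labels")
        if any(f < 0 for f in self.labels_profile.values()):
            raise ValueError("frequencies must be non-negative")

    # -- evaluator protocol -------------------------------------------------
    @property
    def alphabet(self) -> str:
        return LETTERS[: self.n_letters]

    def evaluate(self, genome: str) -> tuple[bool, int]:
        label = int(self.labels[self.genome_index(genome)])
        return (label != INVIABLE, label if label != INVIABLE else 0)

    # -- labeling -----------------------------------------------------------
    @property
    def labels(self) -> np.ndarray:
        """Label of every genome, indexed by odometer genome index."""
        if self._labels is None:
            self._labels = self._compute_labels()
        return self._labels

    def _compute_labels(self) -> np.ndarray:
        A, L = self.n_letters, self.length
        n = A**L
        key = self.seed.to_bytes(8, "little", signed=False)
        ids = sorted(self.labels_profile)
        cum = np.cumsum([self.labels_profile[i] for i in ids])
        labels = np.empty(n, dtype=np.int64)
        digits = bytearray(L)
        for index in range(n):
            x = index
            for k in range(L):
                digits[k] = x % A
                x //= A
            h = hashlib.blake2b(bytes(digits), key=key, digest_size=8).digest()
            u = int.from_bytes(h, "little") / 2**64
            j = int(np.searchsorted(cum, u, side="right"))
            labels[index] = ids[j] if j < len(ids) else INVIABLE
        return labels

    # -- indexing -----------------------------------------------------------
    def genome_index(self, genome: str) -> int:
        A = self.n_letters
        index = 0
        for k, ch in enumerate(genome):
            d = ord(ch) - ord("a")
            if not 0 <= d < A:
                raise ValueError(f"letter {ch!r} outside the toy alphabet")
            index += d * A**k
        return index

    def index_to_genome(self, index: int) -> str:
        A, L = self.n_letters, self.length
        out = []
        for _ in range(L):
            out.append(self.alphabet[index % A])
            index //= A
        return "".join(out)

    def label_counts(self) -> dict[int, int]:
        """Exact number of genotypes per label (INVIABLE included)."""
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def genomes_of(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def sample_panel(self, per_label: int, seed: int) -> dict[int, list[str]]:
        """Uniform sample (with replacement) of genomes per viable label."""
        rng = np.random.default_rng(seed)
        panel = {}
        for label in sorted(self.labels_profile):
            idx = self.genomes_of(label)
            if len(idx) == 0:
                continue
            chosen = rng.choice(idx, size=per_label, replace=True)
            panel[label] = [self.index_to_genome(int(i)) for i in chosen]
        return panel

    def digest(self) -> str:
        return hashlib.blake2b(self.labels.tobytes(), digest_size=8).hexdigest()


def make_toy_map(
    length: int,
    n_letters: int,
    n_labels: int | None = None,
    freqs: list[float] | dict[int, float] | None = None,
    seed: int = 0,
) -> ToyGPMap:
    """Build a toy map; ``freqs`` may be a list (labels 0..k-1) or an
    explicit id -> frequency dict; any remainder is inviable."""
    if freqs is None:
        if n_labels is None:
            raise ValueError("give n_labels or freqs")
        freqs = {i: 1.0 / n_labels for i in range(n_labels)}
    elif not isinstance(freqs, dict):
        freqs = {i: f for i, f in enumerate(freqs)}
    return ToyGPMap(length=length, n_letters=n_letters, labels_profile=freqs, seed=seed)


# ---------------------------------------------------------------------------
# brute-force (exhaustive) transition counts

def _neighbor_transition_counts(
    labels: np.ndarray, n_letters: int, length: int, focal: np.ndarray | None = None
) -> tuple[dict[int, dict[int, int]], dict[int, int], dict[int, int]]:
    """Tally label transitions over all L*(A-1) substitutions of each focal
    genome (all viable genomes when ``focal`` is None), fully vectorized in
    genome-index arithmetic."""
    A, L = n_letters, length
    if focal is None:
        idx = np.flatnonzero(labels != INVIABLE)
    else:
        idx = np.asarray(focal, dtype=np.int64)
    src = labels[idx]
    viable_ids = sorted(int(i) for i in np.unique(src))
    id_pos = {lab: k for k, lab in enumerate(viable_ids)}
    all_ids = sorted(int(i) for i in np.unique(labels) if i != INVIABLE)
    col_ids = [INVIABLE] + sorted(set(all_ids) | set(viable_ids))
    col_pos = {lab: k for k, lab in enumerate(col_ids)}
    mat = np.zeros((len(viable_ids), len(col_ids)), dtype=np.int64)
    src_rows = np.array([id_pos[int(s)] for s in src])
    power = 1
    for k in range(L):
        digit = (idx // power) % A
        for delta in range(1, A):
            nidx = idx + (((digit + delta) % A) - digit) * power
            nlab = labels[nidx]
            cols = np.searchsorted(col_ids, nlab)  # col_ids sorted, INVIABLE=-1 first
            np.add.at(mat, (src_rows, cols), 1)
        power *= A
    counts = {
        lab: {col_ids[c]: int(mat[r, c]) for c in range(len(col_ids)) if mat[r, c] > 0}
        for lab, r in id_pos.items()
    }
    row_neighbors = {lab: int(mat[r].sum()) for lab, r in id_pos.items()}
    n_genomes = {lab: int(np.sum(src == lab)) for lab in viable_ids}
    return counts, row_neighbors, n_genomes


def brute_force_transitions(
    toy: ToyGPMap,
) -> tuple[TransitionMatrix, dict[tuple[int, int], int]]:
    """Exact transition matrix over the fully labeled space, plus the raw
    substitution counts n_ij (which satisfy n_ij = n_ji by reversibility)."""
    counts, row_neighbors, n_genomes = _neighbor_transition_counts(
        toy.labels, toy.n_letters, toy.length
    )
    tm = TransitionMatrix.from_count_dicts(counts, row_neighbors, n_genomes)
    n_ij = {
        (i, j): c
        for i, row in counts.items()
        for j, c in row.items()
        if j != INVIABLE
    }
    return tm, n_ij


def transitions_from_table(table: pd.DataFrame, alphabet: str) -> TransitionMatrix:
    """Exact transition matrix from an enumerated VM table (as produced by
    :func:`enumerate_space`, in odometer order)."""
    labels = np.where(
        table["viable"].to_numpy(), table["phenotype_id"].to_numpy(), INVIABLE
    ).astype(np.int64)
    L = len(table["genome"].iat[0])
    counts, row_neighbors, n_genomes = _neighbor_transition_counts(labels, len(alphabet), L)
    return TransitionMatrix.from_count_dicts(counts, row_neighbors, n_genomes)


def sampled_transition_matrix(
    toy: ToyGPMap, per_label: int, seed: int
) -> TransitionMatrix:
    """Transition matrix estimated from a uniform per-label panel of the toy
    map (the sampled counterpart of :func:`brute_force_transitions`)."""
    rng = np.random.default_rng(seed)
    focal = []
    for label in sorted(toy.labels_profile):
        idx = toy.genomes_of(label)
        if len(idx) == 0:
            continue
        focal.append(rng.choice(idx, size=per_label, replace=True))
    counts, row_neighbors, n_genomes = _neighbor_transition_counts(
        toy.labels, toy.n_letters, toy.length, focal=np.concatenate(focal)
    )
    return TransitionMatrix.from_count_dicts(counts, row_neighbors, n_genomes)
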