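"""Genotype-phenotype map statistics.

Computes, from sampled phenotype panels or fully enumerated maps:
one-mutant neighborhoods, pooled phenotype transition matrices, mutational
robustness, lethality, three evolvability variants, transition asymmetry,
relative phenotype frequencies from transition-probability ratios,
genotype-network connectivity walks, minimal genomes, and Hamming distances.

The key identity behind frequency estimation: with complete neighbor counts
the number of i->j substitutions equals the number of j->i substitutions
(every point substitution is reversible), so p_i->j / p_j->i = N_j / N_i
exactly, where N is the number of genotypes per phenotype.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .evaluator import PhenotypeEvaluator

#: Column label used for inviable neighbors in transition matrices.
INVIABLE = -1


# ---------------------------------------------------------------------------
# distances and neighborhoods

def hamming(a: str, b: str) -> int:
    """Anchored positional mismatch count (no rotational alignment)."""
    if len(a) != len(b):
        raise ValueError("genomes must have equal length")
    return sum(x != y for x, y in zip(a, b))


def one_mutant_neighbors(genome: str, alphabet: str) -> list[str]:
    """All L*(A-1) single-substitution neighbors, duplicate-free."""
    out = []
    for pos, cur in enumerate(genome):
        for letter in alphabet:
            if letter != cur:
                out.append(genome[:pos] + letter + genome[pos + 1:])
    return out


@dataclass(frozen=True)
class NeighborClassification:
    n_inviable: int
    n_same_phenotype: int
    novel_counts: dict[int, int]  # phenotype j != i -> count

    @property
    def total(self) -> int:
        return self.n_inviable + self.n_same_phenotype + sum(self.novel_counts.values())


def classify_neighbors(genome: str, evaluator: PhenotypeEvaluator) -> NeighborClassification:
    """Partition the one-mutant neighborhood of a viable genome into
    inviable / same-phenotype / novel-phenotype classes."""
    viable, pheno = evaluator.evaluate(genome)
    if not viable:
        raise ValueError("focal genome is inviable")
    n_inviable = 0
    n_same = 0
    novel: dict[int, int] = {}
    for nb in one_mutant_neighbors(genome, evaluator.alphabet):
        v, p = evaluator.evaluate(nb)
        if not v:
            n_inviable += 1
        elif p == pheno:
            n_same += 1
        else:
            novel[p] = novel.get(p, 0) + 1
    return NeighborClassification(n_inviable, n_same, novel)


# ---------------------------------------------------------------------------
# transition matrices

@dataclass
class TransitionMatrix:
    """Per-phenotype rows of pooled 1-mutant outcome counts.

    ``counts`` is an integer DataFrame: rows are source phenotypes, columns
    are ``INVIABLE`` (-1) plus every phenotype observed; ``row_neighbors``
    is the pooled neighbor total per row (the exact denominator), and
    ``n_genomes`` the number of focal genomes pooled per row.  Probabilities
    are exact rationals ``count / row_neighbors``; an entry smaller than the
    sampling resolution is exactly zero by construction.
    """

    counts: pd.DataFrame
    row_neighbors: pd.Series
    n_genomes: pd.Series

    @property
    def phenotypes(self) -> list[int]:
        return list(self.counts.index)

    def probability(self, i: int, j: int) -> Fraction:
        """Exact transition probability p_i->j (j = INVIABLE for lethality)."""
        c = int(self.counts.at[i, j]) if j in self.counts.columns else 0
        return Fraction(c, int(self.row_neighbors.at[i]))

    def probabilities(self) -> pd.DataFrame:
        return self.counts.div(self.row_neighbors, axis=0)

    def robustness(self, i: int) -> Fraction:
        return self.probability(i, i)

    def lethality(self, i: int) -> Fraction:
        return self.probability(i, INVIABLE)

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "n_genomes", self.n_genomes)
        df.insert(1, "n_neighbors", self.row_neighbors)
        df.index.name = "phenotype_id"
        df.rename(columns={INVIABLE: "inviable"}).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TransitionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        n_genomes = df.pop("n_genomes")
        row_neighbors = df.pop("n_neighbors")
        df = df.rename(columns=lambda c: INVIABLE if c == "inviable" else int(c))
        return cls(df.astype(np.int64), row_neighbors, n_genomes)

    @classmethod
    def from_count_dicts(
        cls,
        counts: dict[int, dict[int, int]],
        row_neighbors: dict[int, int],
        n_genomes: dict[int, int],
    ) -> "TransitionMatrix":
        rows = sorted(counts)
        cols = sorted({j for row in counts.values() for j in row} | set(rows) | {INVIABLE})
        mat = pd.DataFrame(0, index=rows, columns=cols, dtype=np.int64)
        for i, row in counts.items():
            for j, c in row.items():
                mat.at[i, j] = c
        return cls(
            mat,
            pd.Series(row_neighbors).loc[rows],
            pd.Series(n_genomes).loc[rows],
        )


def transition_matrix(
    panel: dict[int, list[str]], evaluator: PhenotypeEvaluator
) -> TransitionMatrix:
    """Pooled neighbor-class fractions over all panel genomes per phenotype.

    Every genome in the panel must re-evaluate to its key phenotype; empty
    rows are omitted.
    """
    counts: dict[int, dict[int, int]] = {}
    row_neighbors: dict[int, int] = {}
    n_genomes: dict[int, int] = {}
    for pheno, genomes in panel.items():
        if not genomes:
            continue
        row: dict[int, int] = {}
        total = 0
        for g in genomes:
            v, p = evaluator.evaluate(g)
            if not v or p != pheno:
                raise ValueError(f"panel genome {g!r} does not map to phenotype {pheno}")
            for nb in one_mutant_neighbors(g, evaluator.alphabet):
                nv, np_ = evaluator.evaluate(nb)
                j = np_ if nv else INVIABLE
                row[j] = row.get(j, 0) + 1
                total += 1
        counts[pheno] = row
        row_neighbors[pheno] = total
        n_genomes[pheno] = len(genomes)
    if not counts:
        raise ValueError("panel is empty")
    return TransitionMatrix.from_count_dicts(counts, row_neighbors, n_genomes)


def asymmetry(p_ij: float, p_ji: float) -> float:
    """AS(i,j) = |p_i->j - p_j->i| / max(p_i->j, p_j->i), in [0, 1]."""
    if p_ij < 0 or p_ji < 0:
        raise ValueError("transition probabilities must be non-negative")
    m = max(p_ij, p_ji)
    if m == 0:
        raise ValueError("asymmetry undefined when both probabilities are zero")
    return abs(p_ij - p_ji) / m


# ---------------------------------------------------------------------------
# phenotype frequencies

@dataclass(frozen=True)
class FrequencyEstimate:
    value: Fraction | None
    method: str  # "reference" | "direct" | "indirect" | "inestimable"
    path: tuple[int, ...] = ()


def estimate_frequencies(
    tm: TransitionMatrix, reference: int = 0
) -> dict[int, FrequencyEstimate]:
    """Relative phenotype frequencies N_i (N_reference = 1) from
    transition-probability ratios: N_i = (p_ref->i / p_i->ref) * N_ref.

    Phenotypes with no direct nonzero reciprocal pair with the reference are
    estimated through the shortest path of reciprocal nonzero transitions
    (path product), flagged ``indirect``; phenotypes with no such path are
    ``inestimable``.
    """
    if reference not in tm.counts.index:
        raise ValueError(f"reference phenotype {reference} not in matrix")
    graph = nx.Graph()
    rows = list(tm.counts.index)
    graph.add_nodes_from(rows)
    for i in rows:
        for j in rows:
            if i < j and int(tm.counts.at[i, j]) > 0 and int(tm.counts.at[j, i]) > 0:
                graph.add_edge(i, j)
    paths = nx.single_source_shortest_path(graph, reference)
    out: dict[int, FrequencyEstimate] = {}
    for i in rows:
        if i == reference:
            out[i] = FrequencyEstimate(Fraction(1), "reference", (reference,))
            continue
        path = paths.get(i)
        if path is None:
            out[i] = FrequencyEstimate(None, "inestimable")
            continue
        value = Fraction(1)
        for u, v in zip(path, path[1:]):
            value *= tm.probability(u, v) / tm.probability(v, u)
        method = "direct" if len(path) == 2 else "indirect"
        out[i] = FrequencyEstimate(value, method, tuple(path))
    return out


# ---------------------------------------------------------------------------
# evolvability and per-phenotype statistics

@dataclass(frozen=True)
class Evolvability:
    genotypic: int
    constrained: float | None  # None for the all-task phenotype
    phenotypic: float | None  # None without a frequency estimate


def _strict_supersets(mask: int, n_phenotypes: int) -> list[int]:
    return [j for j in range(n_phenotypes) if j != mask and (j & mask) == mask]


def evolvability(
    tm: TransitionMatrix,
    i: int,
    frequency: Fraction | float | None = None,
    n_phenotypes: int = 512,
) -> Evolvability:
    """Three evolvability variants for phenotype ``i``.

    genotypic: number of distinct phenotypes j != i reached by one mutation.
    constrained: fraction of strict-superset phenotypes (those computing at
    least one additional task) reached; undefined for the all-task phenotype.
    phenotypic: reachable fraction of phenotype space times the phenotype's
    frequency N_i.
    """
    if i not in tm.counts.index:
        raise ValueError(f"phenotype {i} not in matrix")
    row = tm.counts.loc[i]
    reached = {j for j, c in row.items() if c > 0 and j not in (i, INVIABLE)}
    genotypic = len(reached)
    supersets = _strict_supersets(i, n_phenotypes)
    if supersets:
        constrained = len(reached & set(supersets)) / len(supersets)
    else:
        constrained = None
    phenotypic = None
    if frequency is not None:
        phenotypic = float(Fraction(genotypic, n_phenotypes - 1) * Fraction(frequency))
    return Evolvability(genotypic, constrained, phenotypic)


def phenotype_stats(
    tm: TransitionMatrix,
    reference: int = 0,
    n_phenotypes: int = 512,
    complexity_of=None,
) -> pd.DataFrame:
    """One row per phenotype: robustness, lethality, the three evolvability
    variants, estimated frequency, and (optionally) complexity."""
    freqs = estimate_frequencies(tm, reference)
    rows = []
    for i in tm.phenotypes:
        freq = freqs[i].value
        evo = evolvability(tm, i, freq, n_phenotypes)
        rows.append(
            {
                "phenotype_id": i,
                "robustness": float(tm.robustness(i)),
                "lethality": float(tm.lethality(i)),
                "genotypic_evolvability": evo.genotypic,
                "constrained_evolvability": evo.constrained,
                "phenotypic_evolvability": evo.phenotypic,
                "frequency": float(freq) if freq is not None else np.nan,
                "frequency_method": freqs[i].method,
                "complexity": complexity_of(i) if complexity_of else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("phenotype_id")


# ---------------------------------------------------------------------------
# connectivity walks

@dataclass
class WalkReplicate:
    trace: list[int]
    accepted: int

    @property
    def final_distance(self) -> int:
        return self.trace[-1]


@dataclass
class ConnectivityResult:
    start: str
    target: str
    mode: str
    replicates: list[WalkReplicate] = field(default_factory=list)

    @property
    def min_distance(self) -> int:
        return min(r.final_distance for r in self.replicates)

    @property
    def reached_zero(self) -> bool:
        return self.min_distance == 0


def connect_walk(
    a: str,
    b: str,
    evaluator: PhenotypeEvaluator,
    mode: str = "strict",
    steps: int = 10_000,
    replicates: int = 10,
    seed: int = 0,
    proposal_factor: int = 50,
) -> ConnectivityResult:
    """Distance-non-increasing phenotype-preserving random walk from ``a``
    toward ``b``.

    Single substitutions are proposed uniformly over (position, letter) and
    accepted if the walker stays viable, satisfies the mode's phenotype
    constraint (``strict``: identical task mask; ``gains``: a superset mask
    is acceptable, never a loss), and does not increase the Hamming distance
    to ``b`` (moves to equal distance are allowed).  Each replicate performs
    up to ``steps`` accepted moves within a proposal budget of
    ``steps * proposal_factor``; an entirely stuck walk reports its starting
    distance.
    """
    if mode not in ("strict", "gains"):
        raise ValueError("mode must be 'strict' or 'gains'")
    if len(a) != len(b):
        raise ValueError("genomes must have equal length")
    va, pa = evaluator.evaluate(a)
    vb, pb = evaluator.evaluate(b)
    if not (va and vb) or pa != pb:
        raise ValueError("both genomes must be viable with identical phenotypes")
    rng = random.Random(seed)
    alphabet = evaluator.alphabet
    result = ConnectivityResult(a, b, mode)
    for _ in range(replicates):
        walker = a
        dist = hamming(walker, b)
        trace = [dist]
        accepted = 0
        budget = steps * proposal_factor
        while accepted < steps and budget > 0 and dist > 0:
            budget -= 1
            pos = rng.randrange(len(walker))
            letter = rng.choice(alphabet)
            if letter == walker[pos]:
                continue
            cand = walker[:pos] + letter + walker[pos + 1:]
            d = hamming(cand, b)
            if d > dist:
                continue
            v, p = evaluator.evaluate(cand)
            if not v:
                continue
            if mode == "strict":
                if p != pa:
                    continue
            else:  # gains: never lose a task present at the start
                if (p & pa) != pa:
                    continue
            walker = cand
            dist = d
            accepted += 1
            trace.append(dist)
        result.replicates.append(WalkReplicate(trace, accepted))
    return result


# ---------------------------------------------------------------------------
# minimal genomes

def reduce_genome(genome: str, evaluator: PhenotypeEvaluator, seed: int = 0) -> str:
    """Greedy randomized single-instruction deletion preserving viability and
    phenotype, until no single deletion survives.

    Termination is certified exhaustively: the last pass tries every
    position and all fail, so every single-deletion variant of the returned
    genome breaks viability or phenotype.
    """
    viable, pheno = evaluator.evaluate(genome)
    if not viable:
        raise ValueError("genome is inviable")
    rng = random.Random(seed)
    current = genome
    while len(current) > 1:
        positions = list(range(len(current)))
        rng.shuffle(positions)
        for pos in positions:
            cand = current[:pos] + current[pos + 1:]
            v, p = evaluator.evaluate(cand)
            if v and p == pheno:
                current = cand
                break
        else:
            break
    return current


# ---------------------------------------------------------------------------
# rank correlation

def spearman(xs, ys) -> float:
    """Spearman rank correlation with average ranks for ties."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    if len(xs) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho)
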