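"""Genotype-phenotype map statistics against brute-force oracles."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from avidalite import (
    asymmetry,
    classify_neighbors,
    connect_walk,
    estimate_frequencies,
    evolvability,
    hamming,
    one_mutant_neighbors,
    reduce_genome,
    spearman,
    transition_matrix,
)
from avidalite.analysis import INVIABLE
from avidalite.micro import (
    brute_force_transitions,
    copy_loop_replicator,
    sampled_transition_matrix,
    transitions_from_table,
)


class TestHamming:
    def test_identity_single_sub_and_total_replacement(self):
        g = "w" * 100
        assert hamming(g, g) == 0
        assert hamming(g, "v" + g[1:]) == 1
        assert hamming(g, "v" * 100) == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming("wv", "wvx")


class TestNeighbors:
    def test_counts_follow_l_times_a_minus_1(self):
        assert len(one_mutant_neighbors("w" * 100, "abcdefghijklmnopqrstuvwxyz")) == 2500
        assert len(one_mutant_neighbors("aaa", "ab")) == 3

    def test_no_duplicates_and_all_at_distance_one(self):
        nbs = one_mutant_neighbors("wvvx", "wvx")
        assert len(nbs) == len(set(nbs)) == 4 * 2
        assert all(hamming("wvvx", nb) == 1 for nb in nbs)

    def test_symmetry_of_the_neighbor_relation(self):
        a, b = "wvvx", "wvxx"
        assert b in one_mutant_neighbors(a, "wvx")
        assert a in one_mutant_neighbors(b, "wvx")


class TestClassifyNeighbors:
    def test_classes_partition_the_neighborhood(self, micro_evaluator):
        c = classify_neighbors("wvvx", micro_evaluator)
        assert c.total == 4 * 2

    def test_counts_match_exhaustive_enumeration(self, micro_evaluator, micro_table):
        """Oracle: look each neighbor up in the exhaustively enumerated table."""
        lookup = {g: (v, p) for g, v, p in micro_table.itertuples(index=False)}
        for genome in list(micro_table[micro_table.viable].genome)[:6]:
            c = classify_neighbors(genome, micro_evaluator)
            _, focal = lookup[genome]
            n_inv = n_same = 0
            novel = {}
            for nb in one_mutant_neighbors(genome, micro_evaluator.alphabet):
                v, p = lookup[nb]
                if not v:
                    n_inv += 1
                elif p == focal:
                    n_same += 1
                else:
                    novel[p] = novel.get(p, 0) + 1
            assert (c.n_inviable, c.n_same_phenotype, c.novel_counts) == (n_inv, n_same, novel)

    def test_inviable_focal_genome_rejected(self, micro_evaluator):
        with pytest.raises(ValueError):
            classify_neighbors("www", micro_evaluator)


class TestTransitionMatrix:
    def test_panel_matrix_equals_exhaustive_matrix(self, micro_config, micro_evaluator, micro_table):
        """Pooling every genome of every phenotype must reproduce the
        index-arithmetic brute-force matrix exactly."""
        panel = {}
        for g, v, p in micro_table.itertuples(index=False):
            if v:
                panel.setdefault(p, []).append(g)
        tm = transition_matrix(panel, micro_evaluator)
        tm_ex = transitions_from_table(micro_table, micro_config.alphabet)
        assert tm.counts.equals(tm_ex.counts)
        assert tm.row_neighbors.equals(tm_ex.row_neighbors)

    def test_rows_sum_to_one_in_exact_arithmetic(self, toy_map):
        tm, _ = brute_force_transitions(toy_map)
        for i in tm.phenotypes:
            assert sum(tm.probability(i, j) for j in tm.counts.columns) == 1

    def test_mismatched_panel_genome_rejected(self, micro_evaluator):
        with pytest.raises(ValueError):
            transition_matrix({3: ["wvvx"]}, micro_evaluator)

    def test_tsv_roundtrip(self, toy_map, tmp_path):
        tm, _ = brute_force_transitions(toy_map)
        path = tmp_path / "tm.tsv"
        tm.to_tsv(path)
        back = type(tm).from_tsv(path)
        assert back.counts.equals(tm.counts)
        assert back.row_neighbors.equals(tm.row_neighbors)


class TestAsymmetry:
    def test_basic_values_and_bounds(self):
        assert asymmetry(0.1, 0.1) == 0
        assert asymmetry(0.2, 0.1) == pytest.approx(0.5)
        assert asymmetry(0.3, 0.0) == 1
        assert asymmetry(0.0, 0.3) == 1

    def test_symmetric_in_its_arguments(self, toy_map):
        tm, _ = brute_force_transitions(toy_map)
        P = tm.probabilities()
        for i in tm.phenotypes:
            for j in tm.phenotypes:
                if i < j and (P.at[i, j] > 0 or P.at[j, i] > 0):
                    a = asymmetry(P.at[i, j], P.at[j, i])
                    assert 0 <= a <= 1
                    assert a == asymmetry(P.at[j, i], P.at[i, j])

    def test_undefined_for_double_zero(self):
        with pytest.raises(ValueError):
            asymmetry(0.0, 0.0)


class TestFrequencies:
    def test_exact_ratio_identity_on_complete_counts(self, toy_map):
        """p_i->j / p_j->i = N_j / N_i in exact rational arithmetic."""
        tm, _ = brute_force_transitions(toy_map)
        counts = toy_map.label_counts()
        for i in tm.phenotypes:
            for j in tm.phenotypes:
                if i != j and tm.counts.at[i, j] > 0:
                    assert tm.counts.at[j, i] > 0  # reversibility
                    ratio = tm.probability(i, j) / tm.probability(j, i)
                    assert ratio == Fraction(counts[j], counts[i])

    def test_estimates_recover_true_genotype_count_ratios_exactly(self, toy_map):
        tm, _ = brute_force_transitions(toy_map)
        counts = toy_map.label_counts()
        freqs = estimate_frequencies(tm, reference=0)
        assert freqs[0].value == 1 and freqs[0].method == "reference"
        for i in tm.phenotypes:
            assert freqs[i].value == Fraction(counts[i], counts[0])

    def test_sampled_estimates_converge_with_panel_size(self, toy_map):
        """Consistency: max relative error of N_i shrinks from panels of
        100 to 10000 genomes per label."""
        counts = toy_map.label_counts()
        errors = []
        for size in (100, 1000, 10000):
            stm = sampled_transition_matrix(toy_map, size, seed=500 + size)
            freqs = estimate_frequencies(stm, reference=0)
            errs = [
                abs(float(freqs[i].value) - counts[i] / counts[0]) / (counts[i] / counts[0])
                for i in stm.phenotypes
                if i != 0 and freqs[i].value is not None
            ]
            errors.append(max(errs))
        assert errors[2] < errors[0]
        assert errors[2] < 0.1

    def test_missing_reference_rejected(self, toy_map):
        tm, _ = brute_force_transitions(toy_map)
        with pytest.raises(ValueError):
            estimate_frequencies(tm, reference=99)


class TestEvolvability:
    def _oracle(self, toy_map, label, n_phenotypes):
        """Independent string-based oracle: walk every genome of the label,
        enumerate its neighbors, collect distinct novel labels."""
        reached = set()
        for idx in toy_map.genomes_of(label):
            g = toy_map.index_to_genome(int(idx))
            for nb in one_mutant_neighbors(g, toy_map.alphabet):
                v, p = toy_map.evaluate(nb)
                if v and p != label:
                    reached.add(p)
        supersets = [j for j in range(n_phenotypes) if j != label and (j & label) == label]
        genotypic = len(reached)
        constrained = len(reached & set(supersets)) / len(supersets) if supersets else None
        return genotypic, constrained

    def test_all_three_variants_match_bruteforce_oracle(self, toy_map):
        tm, _ = brute_force_transitions(toy_map)
        counts = toy_map.label_counts()
        n_ph = 4
        freqs = estimate_frequencies(tm, reference=0)
        for label in tm.phenotypes:
            evo = evolvability(tm, label, freqs[label].value, n_phenotypes=n_ph)
            genotypic, constrained = self._oracle(toy_map, label, n_ph)
            assert evo.genotypic == genotypic
            assert evo.constrained == constrained
            expected_ph = genotypic / (n_ph - 1) * (counts[label] / counts[0])
            assert evo.phenotypic == pytest.approx(expected_ph)

    def test_constrained_undefined_for_all_task_phenotype(self, toy_map):
        tm, _ = brute_force_transitions(toy_map)
        evo = evolvability(tm, 3, None, n_phenotypes=4)  # 3 = both bits set
        assert evo.constrained is None
        assert evo.phenotypic is None

    def test_genotypic_bounded_by_phenotype_space(self, toy_map):
        tm, _ = brute_force_transitions(toy_map)
        for label in tm.phenotypes:
            evo = evolvability(tm, label, None, n_phenotypes=4)
            assert evo.genotypic <= 3


def _viable_component_pairs(micro_table):
    """Exhaustive genotype-network components of the micro space under
    single neutral substitutions."""
    viable = micro_table[micro_table.viable]
    by_pheno = {}
    for g, _, p in viable.itertuples(index=False):
        by_pheno.setdefault(p, []).append(g)
    graphs = {}
    for p, genomes in by_pheno.items():
        G = nx.Graph()
        G.add_nodes_from(genomes)
        for a in genomes:
            for b in genomes:
                if a < b and hamming(a, b) == 1:
                    G.add_edge(a, b)
        graphs[p] = G
    return graphs


class TestConnectWalk:
    def test_identical_genomes_reach_zero_immediately(self, micro_evaluator):
        res = connect_walk("wvvx", "wvvx", micro_evaluator, steps=10, replicates=2, seed=0)
        assert res.min_distance == 0

    def test_distance_traces_never_increase(self, micro_evaluator, micro_table):
        graphs = _viable_component_pairs(micro_table)
        comp = max(nx.connected_components(graphs[0]), key=len)
        comp = sorted(comp)
        res = connect_walk(comp[0], comp[-1], micro_evaluator, steps=50, replicates=5, seed=1)
        for rep in res.replicates:
            assert all(a >= b for a, b in zip(rep.trace, rep.trace[1:]))

    def test_same_component_pairs_connect(self, micro_evaluator, micro_table):
        """Pairs verified (by exhaustive network analysis) to share a
        connected component must be joined by at least one of 10 walks."""
        graphs = _viable_component_pairs(micro_table)
        comp = max(nx.connected_components(graphs[0]), key=len)
        assert len(comp) >= 2
        comp = sorted(comp)
        pair = (comp[0], comp[-1])
        res = connect_walk(pair[0], pair[1], micro_evaluator, steps=100, replicates=10, seed=3)
        assert res.reached_zero

    def test_gains_mode_accepts_a_superset_of_strict_moves(self, micro_evaluator, micro_table):
        graphs = _viable_component_pairs(micro_table)
        comp = sorted(max(nx.connected_components(graphs[0]), key=len))
        a, b = comp[0], comp[-1]
        strict = connect_walk(a, b, micro_evaluator, mode="strict", steps=100, replicates=5, seed=9)
        gains = connect_walk(a, b, micro_evaluator, mode="gains", steps=100, replicates=5, seed=9)
        assert gains.min_distance <= strict.min_distance

    def test_phenotype_mismatch_rejected(self, micro_evaluator):
        with pytest.raises(ValueError):
            connect_walk("wvvx", "wwww", micro_evaluator, steps=5, replicates=1, seed=0)


class TestReduceGenome:
    def test_output_is_viable_with_unchanged_phenotype_and_shorter(self, std_evaluator):
        start = copy_loop_replicator(30)
        reduced = reduce_genome(start, std_evaluator, seed=1)
        assert len(reduced) <= len(start)
        v, p = std_evaluator.evaluate(reduced)
        assert v and p == std_evaluator.evaluate(start)[1]

    def test_termination_certificate_every_deletion_breaks(self, std_evaluator):
        reduced = reduce_genome(copy_loop_replicator(25), std_evaluator, seed=2)
        _, pheno = std_evaluator.evaluate(reduced)
        for pos in range(len(reduced)):
            cand = reduced[:pos] + reduced[pos + 1:]
            v, p = std_evaluator.evaluate(cand)
            assert not (v and p == pheno)

    def test_deletion_critical_genome_returned_unchanged(self, std_evaluator):
        """A genome verified deletion-critical by simulation is a fixed
        point of the reduction."""
        minimal = reduce_genome(copy_loop_replicator(20), std_evaluator, seed=3)
        _, pheno = std_evaluator.evaluate(minimal)
        for pos in range(len(minimal)):  # independent verification
            cand = minimal[:pos] + minimal[pos + 1:]
            v, p = std_evaluator.evaluate(cand)
            assert not (v and p == pheno)
        assert reduce_genome(minimal, std_evaluator, seed=99) == minimal

    def test_inviable_input_rejected(self, std_evaluator):
        with pytest.raises(ValueError):
            reduce_genome("b" * 20, std_evaluator)


class TestSpearman:
    def test_perfect_monotone_relations(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_example_against_direct_rank_formula(self):
        xs = [1.0, 2.0, 2.0, 4.0, 5.0]
        ys = [2.0, 1.0, 3.0, 4.0, 4.0]

        def avg_ranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            ranks = [0.0] * len(v)
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                for k in range(i, j + 1):
                    ranks[order[k]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = avg_ranks(xs), avg_ranks(ys)
        mx, my = sum(rx) / 5, sum(ry) / 5
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
        assert spearman(xs, ys) == pytest.approx(num / den)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])
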