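"""Adjacency extraction and conservation counts on signed gene orders."""

import numpy as np
import pytest
from collections import Counter
from hypothesis import given, settings, strategies as st

from gapadj.genome_model import (Chromosome, Genome, O_GENE, SignedGene,
                                 adj_cons_gene, adj_cons_genomes,
                                 alpha_adjacencies, genome, marker_sequence,
                                 multiset_intersection_size, sg)

from conftest import oracle_multiset, rand_genome


def counts(ms):
    return {str(g): c for g, c in ms.counts.items() if c}


class TestMarkerSequence:
    @pytest.mark.parametrize("genes,circular,expected", [
        (["a"], False, ("a^t", "a^h", "O^t", "O^h")),
        (["+1", "-2"], False, ("1^t", "1^h", "2^h", "2^t", "O^t", "O^h")),
        (["a", "b"], True, ("a^t", "a^h", "b^t", "b^h")),
    ])
    def test_expansion(self, genes, circular, expected):
        chrom = Chromosome(tuple(sg(t) for t in genes), circular)
        assert marker_sequence(chrom) == expected

    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError):
            Chromosome(())


class TestAlphaAdjacencies:
    def test_multicopy_left_direct(self):
        # chromosome (a a b a a c): each copy of a sees its left neighbour
        g = genome("G", ["a", "a", "b", "a", "a", "c"])
        assert counts(alpha_adjacencies(g, "a", "left", 1)) == \
            {"O": 1, "a": 2, "b": 1}

    def test_multicopy_right_gap2(self):
        # at gap 2 each neighbouring gene contributes both orientations
        g = genome("G", ["a", "a", "b", "a", "a", "c"])
        ms = alpha_adjacencies(g, "a", "right", 2)
        assert counts(ms) == {"a": 2, "-a": 2, "b": 1, "-b": 1,
                              "c": 1, "-c": 1}
        assert len(ms) == 8

    def test_signed_neighbours(self):
        g = genome("G", ["1", "-2", "3", "-4"])
        assert counts(alpha_adjacencies(g, "1", "right", 1)) == {"-2": 1}
        assert counts(alpha_adjacencies(g, "3", "left", 1)) == {"-2": 1}
        assert counts(alpha_adjacencies(g, "2", "right", 1)) == {"-1": 1}
        assert counts(alpha_adjacencies(g, "2", "left", 1)) == {"-3": 1}

    def test_single_gene_sees_telomere(self):
        g = genome("G", ["g"])
        for side in ("left", "right"):
            assert counts(alpha_adjacencies(g, "g", side, 1)) == {"O": 1}

    def test_window_stops_at_telomere(self):
        # a short chromosome is never re-read around its telomere
        g = genome("G", ["a", "b"])
        ms = alpha_adjacencies(g, "a", "left", 10)
        assert counts(ms) == {"O": 1}

    def test_errors(self):
        g = genome("G", ["a", "b"])
        with pytest.raises(KeyError):
            alpha_adjacencies(g, "z", "left", 1)
        with pytest.raises(ValueError):
            alpha_adjacencies(g, "a", "left", 0)


genomes_st = st.builds(
    lambda seed, n_sym, dup, nc: rand_genome(
        np.random.default_rng(seed), "G",
        [chr(ord("a") + i) for i in range(n_sym)], dup=dup, n_chrom=nc),
    st.integers(0, 10_000), st.integers(2, 8), st.booleans(), st.integers(1, 2))


class TestAdjacencyProperties:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(genomes_st, st.integers(1, 5),
           st.sampled_from(["left", "right"]), st.booleans())
    def test_marker_walk_oracle_equivalence(self, g, alpha, side, strict):
        for gene in sorted(g.gene_set):
            got = alpha_adjacencies(g, gene, side, alpha, strict).counts
            want = oracle_multiset(g, gene, side, alpha, strict)
            assert got == want, (str(g.chromosomes), gene, side, alpha, strict)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(genomes_st, st.integers(1, 4), st.sampled_from(["left", "right"]))
    def test_monotone_in_alpha(self, g, alpha, side):
        for gene in sorted(g.gene_set):
            small = alpha_adjacencies(g, gene, side, alpha).counts
            big = alpha_adjacencies(g, gene, side, alpha + 1).counts
            assert all(big[k] >= c for k, c in small.items())

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(genomes_st, st.integers(1, 4))
    def test_reversal_invariance(self, g, alpha):
        # extraction reads each occurrence in its own orientation, so
        # reversing chromosomes changes neither LA nor RA of ordinary genes
        # (the telomere's multisets mirror instead: its sign is pinned)
        rev = g.reversed()
        for gene in sorted(g.gene_set - {"O"}):
            for side in ("left", "right"):
                assert (alpha_adjacencies(g, gene, side, alpha).counts
                        == alpha_adjacencies(rev, gene, side, alpha).counts)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(genomes_st, st.integers(1, 4))
    def test_negation_swaps_sides(self, g, alpha):
        # flipping every sign in place mirrors each occurrence, so left and
        # right adjacency multisets trade places
        neg = Genome(g.name, tuple(
            Chromosome(tuple(-x for x in c.genes), c.circular)
            for c in g.chromosomes))
        for gene in sorted(g.gene_set - {"O"}):
            assert (alpha_adjacencies(g, gene, "left", alpha).counts
                    == alpha_adjacencies(neg, gene, "right", alpha).counts)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(2, 8))
    def test_direct_conservation_is_even(self, sa, sb, n_sym):
        # every conserved physical junction is counted from both flanks;
        # exact on circular genomes (telomere junctions depend on the
        # arbitrary orientation of O, so linear ends may count once)
        syms = [chr(ord("a") + i) for i in range(n_sym)]
        ga = rand_genome(np.random.default_rng(sa), "A", syms, circular=True)
        gb = rand_genome(np.random.default_rng(sb), "B", syms, circular=True)
        assert adj_cons_genomes(1, ga, gb) % 2 == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(genomes_st, st.integers(1, 3))
    def test_self_conservation_is_even(self, g, alpha):
        assert adj_cons_genomes(alpha, g, g) % 2 == 0

    def test_size_law(self):
        g = genome("G", [str(i) for i in range(1, 21)])
        for alpha in (1, 3, 6):
            ms = alpha_adjacencies(g, "10", "left", alpha,
                                   strict_gap_exclusion=False)
            assert len(ms) == alpha * g.mult("10")


class TestConservation:
    def test_multiset_intersection(self):
        a = Counter({sg("a"): 2, sg("b"): 1})
        b = Counter({sg("a"): 1, sg("b"): 2})
        assert multiset_intersection_size(a, b) == 2
        assert multiset_intersection_size(a, a) == 3
        assert multiset_intersection_size(
            Counter({sg("a"): 1}), Counter({sg("-a"): 1})) == 0

    def test_adj_cons_gene(self):
        ab = genome("u", ["a", "b"])
        ba = genome("v", ["b", "a"])
        assert adj_cons_gene("a", 1, ab, ab) == 2
        assert adj_cons_gene("a", 1, ab, ba) == 0
        assert adj_cons_gene("z", 1, ab, ba) == 0

    def test_adj_cons_genomes(self):
        ab = genome("u", ["a", "b"])
        assert adj_cons_genomes(1, ab, ab) == 6  # 2 per gene incl. O
        other = genome("v", ["x", "y"])
        assert adj_cons_genomes(1, ab, other) == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(genomes_st, genomes_st, st.integers(1, 3))
    def test_symmetry(self, ga, gb, alpha):
        assert adj_cons_genomes(alpha, ga, gb) == adj_cons_genomes(alpha, gb, ga)

    def test_self_intersection_doubles_multiset(self):
        g = genome("G", ["a", "b", "c", "a"])
        for gene in ("a", "b"):
            la = alpha_adjacencies(g, gene, "left", 2)
            ra = alpha_adjacencies(g, gene, "right", 2)
            assert adj_cons_gene(gene, 2, g, g) == len(la) + len(ra)
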