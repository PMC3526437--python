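"""Junction graph construction, TSP assembly, threshold cutting, main loop."""

import numpy as np
import pytest

from gapadj.assembly import (CAR, JunctionGraph, build_junction_graph,
                             cars_to_genome, cut_tour, gapadj, junction_score,
                             singleton_cars, solve_tsp, tour_weight,
                             _greedy_tour, _solve_exact, _two_opt)
from gapadj.genome_model import Chromosome, Genome, SignedGene, genome, sg
from gapadj.phylogeny import assign_gene_content, read_tree
from gapadj.scoring import MultiplicityError, score_tables_at_node


class StubScores:
    """Score maps driven by an explicit table of direct adjacencies."""

    def __init__(self, left=None, right=None, default=0):
        self.left = left or {}
        self.right = right or {}
        self.default = default

    def L(self, g, h):
        return self.left.get((g, h), self.default)

    def R(self, g, h):
        return self.right.get((g, h), self.default)


class TestJunctionGraph:
    def test_weight_formula(self):
        cars = singleton_cars(["g", "h"])
        scores = StubScores(default=4)
        graph = build_junction_graph(cars, scores, {"g": 5, "h": 5, "O": 5})
        # right end of CAR g against left end of CAR h: (4 + 4) / (5 + 5)
        assert graph.weights[1, 2] == pytest.approx(0.8)
        assert np.allclose(graph.weights, graph.weights.T)

    def test_never_adjacent_pair_weighs_zero(self):
        cars = singleton_cars(["g", "h"])
        graph = build_junction_graph(cars, StubScores(), {"g": 5, "h": 5, "O": 5})
        assert graph.weights[1, 2] == 0

    def test_single_car_plus_telomere(self):
        cars = singleton_cars(["g"])
        graph = build_junction_graph(cars, StubScores(default=1),
                                     {"g": 2, "O": 2})
        assert graph.n_items == 2
        assert graph.weights.shape == (4, 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_junction_graph([], StubScores(), {})

    def test_orientation_uses_signed_scores(self):
        # junction score of "u v" consults L of the right gene and R of the
        # left gene, with signs resolved through each gene's own orientation
        scores = StubScores(left={("v", sg("u")): 3},
                            right={("u", sg("v")): 2})
        assert junction_score(sg("u"), sg("v"), scores) == 5
        # a flipped right gene reads its left side as a right-side query of
        # the mirrored left gene; the left gene queries the flipped candidate
        scores2 = StubScores(right={("v", sg("-u")): 3, ("u", sg("-v")): 2})
        assert junction_score(sg("u"), sg("-v"), scores2) == 3 + 2


def random_graph(seed, n_cars, sparse=0.6):
    rng = np.random.default_rng(seed)
    cars = singleton_cars([f"g{i}" for i in range(n_cars)])
    n_ports = 2 * n_cars + 2
    w = rng.random((n_ports, n_ports))
    w[rng.random((n_ports, n_ports)) < sparse] = 0.0
    w = np.triu(w, 1)
    w = w + w.T
    for i in range(n_cars + 1):
        w[2 * i:2 * i + 2, 2 * i:2 * i + 2] = 0.0
    return JunctionGraph(cars, w)


class TestTsp:
    @pytest.mark.parametrize("seed", range(10))
    def test_heuristic_matches_exact_on_small_instances(self, seed):
        graph = random_graph(seed, n_cars=4)
        exact = _solve_exact(graph)
        # force the heuristic path (production would solve this exactly)
        heur = solve_tsp(graph, np.random.default_rng(seed), exact_max_items=0)
        we = tour_weight(exact, graph.weights)
        wh = tour_weight(heur, graph.weights)
        assert wh <= we + 1e-9
        assert wh >= we - 1e-9, f"2-opt left a gap: {wh} < {we}"

    @pytest.mark.parametrize("seed", range(5))
    def test_two_opt_never_worsens_greedy(self, seed):
        graph = random_graph(seed, n_cars=9, sparse=0.4)
        greedy = _greedy_tour(graph, np.random.default_rng(seed))
        improved = _two_opt(list(greedy), graph.weights)
        assert (tour_weight(improved, graph.weights)
                >= tour_weight(greedy, graph.weights) - 1e-12)

    def test_tour_is_a_permutation(self):
        graph = random_graph(3, n_cars=9)
        tour = solve_tsp(graph, np.random.default_rng(0))
        assert sorted(it for it, _ in tour) == list(range(graph.n_items))

    def test_uniform_weights_total(self):
        cars = singleton_cars(["a", "b", "c"])
        n_ports = 8
        w = np.full((n_ports, n_ports), 0.5)
        for i in range(4):
            w[2 * i:2 * i + 2, 2 * i:2 * i + 2] = 0.0
        graph = JunctionGraph(cars, w)
        tour = solve_tsp(graph)
        assert tour_weight(tour, w) == pytest.approx(0.5 * 4)


class TestCutTour:
    def make_graph(self, weights_by_ports, n_cars, genes=None):
        cars = (singleton_cars([f"g{i}" for i in range(n_cars)])
                if genes is None else
                [CAR(tuple(sg(t) for t in gs), i) for i, gs in enumerate(genes)])
        n_ports = 2 * len(cars) + 2
        w = np.zeros((n_ports, n_ports))
        for (p, q), val in weights_by_ports.items():
            w[p, q] = w[q, p] = val
        return JunctionGraph(cars, w)

    def test_all_weak_junctions_leave_cars_unchanged(self):
        graph = self.make_graph({}, 3)
        tour = [(3, 0), (0, 0), (1, 0), (2, 0)]  # item 3 is the telomere
        cars, kept = cut_tour(tour, graph, tau=0.7)
        assert [str(c) for c in cars] == ["g0", "g1", "g2"]
        assert kept == []

    def test_all_strong_junctions_give_single_car(self):
        # 0:(g0 ports 0,1) 1:(g1 ports 2,3) 2:(g2 ports 4,5), O ports 6,7
        graph = self.make_graph({(1, 2): 0.9, (3, 4): 0.9}, 3)
        tour = [(3, 0), (0, 0), (1, 0), (2, 0)]
        cars, kept = cut_tour(tour, graph, tau=0.7)
        assert [str(c) for c in cars] == ["g0 g1 g2"]
        assert len(kept) == 2

    def test_concatenation_flips_reversed_cars(self):
        graph = self.make_graph({(1, 3): 0.9}, 2, genes=[["a", "b"], ["c"]])
        # traverse CAR 1 flipped: its genes are negated and reversed
        tour = [(2, 0), (0, 0), (1, 1)]
        cars, _ = cut_tour(tour, graph, tau=0.7)
        assert [str(c) for c in cars] == ["a b -c"]

    def test_telomere_always_cut(self):
        # two CARs (ports 0-3) plus the telomere item (ports 4-5); even
        # maximal-weight junctions into the telomere are severed
        graph = self.make_graph({(1, 2): 0.9, (3, 4): 0.99, (5, 0): 0.99}, 2)
        tour = [(2, 0), (0, 0), (1, 0)]
        cars, _ = cut_tour(tour, graph, tau=0.7)
        assert [str(c) for c in cars] == ["g0 g1"]


class TestGapAdj:
    def test_identical_leaves_recover_chromosomes(self, identical_tree):
        res = gapadj(identical_tree, identical_tree.node("X"), max_alpha=1)
        got = sorted(min(str(c), str(CAR(c.reversed_genes())))
                     for c in res.cars)
        assert got == [min("1 2 3 4", "-4 -3 -2 -1"), min("5 6", "-6 -5")]

    def test_car_count_monotone(self, identical_tree):
        res = gapadj(identical_tree, identical_tree.node("R"), max_alpha=6,
                     keep_snapshots=True)
        counts = [n for _, n in res.history]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_surviving_junctions_at_least_tau(self, identical_tree):
        res = gapadj(identical_tree, identical_tree.node("X"), tau=0.7,
                     max_alpha=3)
        assert all(row["weight"] >= 0.7 for row in res.junctions)

    def test_multiplicity_at_node_checked(self):
        gs = [genome("A", ["1", "1", "2"]), genome("B", ["1", "1", "2"])]
        t = assign_gene_content(read_tree("(A,B)WGD_R;", gs))
        post = t.root.children[0]
        with pytest.raises(MultiplicityError):
            gapadj(t, post, max_alpha=1)

    def test_deterministic(self, identical_tree):
        a = gapadj(identical_tree, identical_tree.node("X"), seed=7, max_alpha=2)
        b = gapadj(identical_tree, identical_tree.node("X"), seed=7, max_alpha=2)
        assert [c.genes for c in a.cars] == [c.genes for c in b.cars]

    def test_flip_invariance(self):
        from gapadj.simulator import SIX_LEAF_NEWICK, SimConfig, simulate
        cfg = SimConfig(n_genes=40, n_chromosomes=1, rmax=4, op_mix=(1, 0, 0))
        tree = simulate(SIX_LEAF_NEWICK, cfg, seed=5)
        assign_gene_content(tree)
        res = gapadj(tree, tree.node("sigma"), max_alpha=8, seed=5)

        tree2 = simulate(SIX_LEAF_NEWICK, cfg, seed=5)
        for leaf in tree2.leaves:
            leaf.genome = leaf.genome.reversed()
            leaf.content = dict(leaf.genome.gene_counts)
        assign_gene_content(tree2)
        res2 = gapadj(tree2, tree2.node("sigma"), max_alpha=8, seed=5)

        canon = lambda cars: sorted(
            min(str(c), str(CAR(c.reversed_genes()))) for c in cars)
        assert canon(res.cars) == canon(res2.cars)
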