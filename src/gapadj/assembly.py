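"""Iterative assembly of Contiguous Ancestral Regions (CARs).

Each iteration ``alpha = 1..MAX_alpha`` scores candidate junctions between
the extremity genes of the current CARs, solves a heaviest-Hamiltonian-cycle
instance over CAR extremities (each CAR entered at one end must be exited at
the other; a single telomere vertex ``O`` closes the cycle), and then cuts
every junction whose weight falls below the threshold ``tau`` as well as the
two junctions at ``O``.  Surviving runs concatenate into longer CARs, so the
CAR count never increases with ``alpha``.

A junction placing gene ``h`` directly left of gene ``g`` is weighted
``(L(g,h) + R(h,g)) / (MaxAdj(g,S) + MaxAdj(h,S))`` where L/R are the
tree-wide conservation scores and ``MaxAdj`` is the gene's copy count summed
over tree nodes (the node count, in the absence of duplications).  Dividing
by the two genes' copy counts corrects for genes lost in parts of the tree
without favouring high-multiplicity genes, keeps weights in [0, 1]
symmetrically, and makes ``tau`` read (up to the node/branch count
difference) as a branch-conservation fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product

import numpy as np

from .genome_model import Chromosome, Genome, O_GENE, SignedGene, TELOMERE
from .phylogeny import SpeciesTree, TreeNode, max_adj_copies
from .scoring import MultiplicityError, NodeScores, score_tables_at_node


@dataclass(frozen=True)
class CAR:
    """A contiguous ancestral region: an ordered run of signed genes."""

    genes: tuple[SignedGene, ...]
    id: int = 0

    def __post_init__(self):
        if not self.genes:
            raise ValueError("CAR must be non-empty")
        if any(g.symbol == TELOMERE for g in self.genes):
            raise ValueError("CAR may not contain the telomere gene")

    def reversed_genes(self) -> tuple[SignedGene, ...]:
        return tuple(-g for g in reversed(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __str__(self) -> str:
        return " ".join(str(g) for g in self.genes)


def cars_to_genome(cars: list[CAR], name: str = "inferred") -> Genome:
    """View a CAR set as a genome of linear chromosomes."""
    return Genome(name, tuple(Chromosome(c.genes) for c in cars))


def singleton_cars(genes: list[str]) -> list[CAR]:
    return [CAR((SignedGene(g, 1),), i) for i, g in enumerate(genes)]


@dataclass
class JunctionGraph:
    """Weighted junction graph over CAR extremities plus one ``O`` vertex.

    Each CAR ``i`` owns ports ``2i`` (left end) and ``2i+1`` (right end); the
    telomere item owns the last two ports.  ``weights[p, q]`` is the junction
    weight obtained by placing the port-``p`` extremity against the
    port-``q`` extremity; it is symmetric.
    """

    cars: list[CAR]
    weights: np.ndarray

    @property
    def n_items(self) -> int:
        return len(self.cars) + 1

    @property
    def o_item(self) -> int:
        return len(self.cars)

    def facing(self, port: int, boundary: str) -> SignedGene:
        """Signed gene exposed at a port when the port sits on a junction.

        ``boundary='right'``: the item is oriented with this port rightmost
        (the exposed gene closes the item); ``'left'``: leftmost.
        """
        item, end = divmod(port, 2)
        if item == self.o_item:
            return O_GENE
        genes = self.cars[item].genes
        if boundary == "right":
            return genes[-1] if end == 1 else -genes[0]
        return genes[0] if end == 0 else -genes[-1]


def junction_score(u: SignedGene, v: SignedGene, scores: NodeScores) -> int:
    """Raw conservation score of the junction ``... u v ...`` (u left of v)."""
    s = 0
    if v.symbol != TELOMERE:
        s += scores.L(v.symbol, u) if v.sign > 0 else scores.R(v.symbol, -u)
    if u.symbol != TELOMERE:
        s += scores.R(u.symbol, v) if u.sign > 0 else scores.L(u.symbol, -v)
    return s


def build_junction_graph(
    cars: list[CAR],
    scores: NodeScores,
    maxadj: dict[str, int],
    literal_normalization: bool = False,
) -> JunctionGraph:
    """Weight all candidate junctions between CAR extremities (and ``O``).

    With ``literal_normalization`` the weight divides by ``MaxAdj`` of the
    right-hand gene only, as in the original asymmetric ratio; the default
    divides by the sum for both flanking genes, keeping weights in [0, 1].
    """
    if not cars:
        raise ValueError("empty CAR set")
    n_ports = 2 * len(cars) + 2
    w = np.zeros((n_ports, n_ports), dtype=float)
    graph = JunctionGraph(cars, w)
    right_face = [graph.facing(p, "right") for p in range(n_ports)]
    left_face = [graph.facing(p, "left") for p in range(n_ports)]
    for p in range(n_ports):
        u = right_face[p]
        for q in range(p + 1, n_ports):
            if q // 2 == p // 2:
                continue
            v = left_face[q]
            s = junction_score(u, v, scores)
            if s == 0:
                continue
            if literal_normalization:
                den = maxadj[v.symbol if v.symbol != TELOMERE else u.symbol]
            else:
                den = maxadj[u.symbol] + maxadj[v.symbol]
            w[p, q] = w[q, p] = s / den
    return graph


# ---------------------------------------------------------------------------
# TSP over oriented items

def _entry(item: int, flip: int) -> int:
    return 2 * item + flip


def _exit(item: int, flip: int) -> int:
    return 2 * item + 1 - flip


def tour_weight(tour: list[tuple[int, int]], w: np.ndarray) -> float:
    m = len(tour)
    return sum(
        w[_exit(*tour[k]), _entry(*tour[(k + 1) % m])] for k in range(m))


def _solve_exact(graph: JunctionGraph) -> list[tuple[int, int]]:
    """Exhaustive optimum over item orders and orientations (small instances)."""
    n = graph.n_items
    items = [i for i in range(n) if i != graph.o_item]
    best, best_tour = -1.0, None
    for perm in permutations(items):
        for flips in product((0, 1), repeat=len(items)):
            tour = [(graph.o_item, 0)] + list(zip(perm, flips))
            tw = tour_weight(tour, graph.weights)
            if tw > best + 1e-12:
                best, best_tour = tw, tour
    return best_tour


def _greedy_tour(graph: JunctionGraph, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Fragment-merging greedy construction over positive-weight junctions."""
    w = graph.weights
    n = graph.n_items
    partner: dict[int, int] = {}
    frag_root = list(range(n))  # union-find over items

    def find(i: int) -> int:
        while frag_root[i] != i:
            frag_root[i] = frag_root[frag_root[i]]
            i = frag_root[i]
        return i

    # free end-ports of each fragment
    ends: dict[int, list[int]] = {i: [2 * i, 2 * i + 1] for i in range(n)}

    def connect(p: int, q: int) -> None:
        a, b = find(p // 2), find(q // 2)
        partner[p] = q
        partner[q] = p
        ea = [x for x in ends.pop(a) if x != p]
        eb = [x for x in ends.pop(b) if x != q]
        frag_root[b] = a
        ends[find(a)] = ea + eb

    pp, qq = np.nonzero(np.triu(w, 1) > 0)
    order = np.argsort(-w[pp, qq], kind="stable")
    for idx in order:
        p, q = int(pp[idx]), int(qq[idx])
        if p in partner or q in partner or p // 2 == q // 2:
            continue
        if find(p // 2) == find(q // 2):
            continue
        connect(p, q)

    # join remaining fragments (zero-weight junctions), deterministic per seed
    while len(ends) > 1:
        roots = sorted(ends)
        a = roots[0]
        # best available continuation among other fragments
        best = None
        for b in roots[1:]:
            for p in ends[a]:
                for q in ends[b]:
                    key = (w[p, q], -p, -q)
                    if best is None or key > best[0]:
                        best = (key, p, q)
        connect(best[1], best[2])
    # close the cycle
    last = next(iter(ends.values()))
    partner[last[0]] = last[1]
    partner[last[1]] = last[0]

    # walk the cycle starting at the telomere item
    tour: list[tuple[int, int]] = []
    entry_port = 2 * graph.o_item
    for _ in range(n):
        item, f = divmod(entry_port, 2)
        tour.append((item, f))
        entry_port = partner[_exit(item, f)]
    return tour


def _two_opt(tour: list[tuple[int, int]], w: np.ndarray,
             max_sweeps: int = 40) -> list[tuple[int, int]]:
    """First-improvement 2-opt with segment reversal (orientations flip)."""
    m = len(tour)
    if m < 3:
        return tour
    tour = list(tour)
    for _ in range(max_sweeps):
        improved = False
        for i in range(m - 1):
            ei = _exit(*tour[i])
            for j in range(i + 1, m):
                if i == 0 and j == m - 1:
                    continue
                jn = (j + 1) % m
                delta = (
                    w[ei, _exit(*tour[j])]
                    + w[_entry(*tour[i + 1]), _entry(*tour[jn])]
                    - w[ei, _entry(*tour[i + 1])]
                    - w[_exit(*tour[j]), _entry(*tour[jn])]
                )
                if delta > 1e-12:
                    tour[i + 1:j + 1] = [(it, 1 - f)
                                         for it, f in reversed(tour[i + 1:j + 1])]
                    improved = True
                    ei = _exit(*tour[i])
        if not improved:
            break
    return tour


def _or_opt(tour: list[tuple[int, int]], w: np.ndarray,
            max_sweeps: int = 20) -> list[tuple[int, int]]:
    """Relocate short segments (length 1-3), optionally flipped."""
    tour = list(tour)
    for _ in range(max_sweeps):
        m = len(tour)
        improved = False
        for seg_len in (1, 2, 3):
            if m < seg_len + 3:
                continue
            i = 0
            while i < m:
                seg = [tour[(i + k) % m] for k in range(seg_len)]
                pre = tour[(i - 1) % m]
                post = tour[(i + seg_len) % m]
                removed = (w[_exit(*pre), _entry(*seg[0])]
                           + w[_exit(*seg[-1]), _entry(*post)])
                closed = w[_exit(*pre), _entry(*post)]
                rest = [tour[(i + seg_len + k) % m]
                        for k in range(m - seg_len)]
                best = None
                for pos in range(1, len(rest)):
                    a, b = rest[pos - 1], rest[pos]
                    base = w[_exit(*a), _entry(*b)]
                    for flip in (False, True):
                        s = ([(it, 1 - f) for it, f in reversed(seg)]
                             if flip else seg)
                        gain = (closed + w[_exit(*a), _entry(*s[0])]
                                + w[_exit(*s[-1]), _entry(*b)]
                                - base - removed)
                        if gain > 1e-12 and (best is None or gain > best[0]):
                            best = (gain, pos, s)
                if best is not None:
                    _, pos, s = best
                    tour = rest[:pos] + s + rest[pos:]
                    m = len(tour)
                    improved = True
                i += 1
        if not improved:
            break
    return tour


def _local_search(tour, w):
    while True:
        before = tour_weight(tour, w)
        tour = _or_opt(_two_opt(tour, w), w)
        if tour_weight(tour, w) <= before + 1e-12:
            return tour


def _double_bridge(tour, rng):
    m = len(tour)
    if m < 5:
        perm = rng.permutation(m)
        return [tour[int(i)] for i in perm]
    cuts = sorted(rng.choice(np.arange(1, m), size=3, replace=False))
    a, b, c = map(int, cuts)
    return tour[:a] + tour[b:c] + tour[a:b] + tour[c:]


def solve_tsp(graph: JunctionGraph, rng: np.random.Generator | None = None,
              exact_max_items: int = 6) -> list[tuple[int, int]]:
    """Heaviest Hamiltonian cycle over oriented CARs plus the telomere item.

    Instances with at most ``exact_max_items`` items (12 ports) are solved by
    exhaustive search; larger ones by greedy construction plus 2-opt.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if graph.n_items <= exact_max_items:
        return _solve_exact(graph)
    w = graph.weights
    n = graph.n_items
    best = _local_search(_greedy_tour(graph, rng), w)
    best_w = tour_weight(best, w)
    # small instances: seeded random restarts explore orientation basins that
    # segment moves cannot leave; large (sparse, chain-like) instances keep
    # the greedy backbone and only perturb it
    restarts = 12 if n <= 16 else 0
    kicks = 4 if n <= 60 else 2
    for k in range(restarts + kicks):
        if k < restarts:
            perm = rng.permutation(n)
            flips = rng.integers(0, 2, size=n)
            start = [(int(i), int(f)) for i, f in zip(perm, flips)]
        else:
            start = _double_bridge(best, rng)
        cand = _local_search(start, w)
        cw = tour_weight(cand, w)
        if cw > best_w + 1e-12:
            best, best_w = cand, cw
    return best


def cut_tour(tour: list[tuple[int, int]], graph: JunctionGraph,
             tau: float) -> tuple[list[CAR], list[dict]]:
    """Cut the telomere junctions and all junctions below ``tau``; concatenate.

    Returns the new CAR set and a report of the surviving junctions.
    """
    w = graph.weights
    m = len(tour)
    start = next(k for k, (it, _) in enumerate(tour) if it == graph.o_item)
    linear = [tour[(start + 1 + k) % m] for k in range(m - 1)]
    runs: list[list[tuple[int, int]]] = [[linear[0]]] if linear else []
    kept: list[dict] = []
    for k in range(1, len(linear)):
        weight = w[_exit(*linear[k - 1]), _entry(*linear[k])]
        if weight < tau:
            runs.append([linear[k]])
        else:
            kept.append({
                "left_car": graph.cars[linear[k - 1][0]].id,
                "right_car": graph.cars[linear[k][0]].id,
                "weight": float(weight),
            })
            runs[-1].append(linear[k])
    new_cars = []
    for i, run in enumerate(runs):
        genes: list[SignedGene] = []
        for item, f in run:
            car = graph.cars[item]
            genes.extend(car.genes if f == 0 else car.reversed_genes())
        new_cars.append(CAR(tuple(genes), i))
    return new_cars, kept


@dataclass
class GapAdjResult:
    cars: list[CAR]
    #: (alpha, number of CARs after the iteration)
    history: list[tuple[int, int]]
    #: surviving-junction report rows: alpha, car ids, weight
    junctions: list[dict] = field(default_factory=list)
    #: CAR sets after each iteration, when recording was requested
    snapshots: list[list[CAR]] = field(default_factory=list)


def gapadj(
    tree: SpeciesTree,
    nu: TreeNode,
    tau: float = 0.70,
    max_alpha: int = 50,
    seed: int = 0,
    strict_gap_exclusion: bool = True,
    wgd_double_match: bool = True,
    literal_normalization: bool = False,
    mult_cap: int = 4,
    keep_snapshots: bool = False,
) -> GapAdjResult:
    """Infer the ancestral CAR set at node ``nu`` by iterating over gaps.

    CARs start as the single genes of the assigned content at ``nu`` (which
    must be single-copy: ``nu`` precedes every duplication).  Each iteration
    re-scores junctions between the current CAR extremities at gap ``alpha``,
    assembles by TSP and cuts at ``tau``; the loop stops at ``max_alpha`` or
    as soon as a single CAR remains.
    """
    genes = sorted(g for g in nu.content if g != TELOMERE)
    if not genes:
        raise ValueError(f"no genes assigned at node {nu.name}")
    bad = [g for g in genes if nu.mult(g) != 1]
    if bad:
        raise MultiplicityError(
            f"{len(bad)} genes have multiplicity != 1 at {nu.name} "
            f"(e.g. {bad[:5]}); pick a node preceding all duplications")
    maxadj = {g: max_adj_copies(g, tree) for g in genes}
    maxadj[TELOMERE] = max_adj_copies(TELOMERE, tree)

    rng = np.random.default_rng(seed)
    cars = singleton_cars(genes)
    result = GapAdjResult(cars, [])
    for alpha in range(1, max_alpha + 1):
        ext = sorted({c.genes[0].symbol for c in cars}
                     | {c.genes[-1].symbol for c in cars})
        scores = score_tables_at_node(
            nu, alpha, ext, tree, strict_gap_exclusion, wgd_double_match,
            mult_cap)
        graph = build_junction_graph(cars, scores, maxadj, literal_normalization)
        tour = solve_tsp(graph, rng)
        new_cars, kept = cut_tour(tour, graph, tau)
        if len(new_cars) > len(cars):
            raise AssertionError("CAR count increased within an iteration")
        cars = new_cars
        for row in kept:
            row["alpha"] = alpha
        result.junctions.extend(kept)
        result.history.append((alpha, len(cars)))
        if keep_snapshots:
            result.snapshots.append(list(cars))
        if len(cars) == 1:
            break
    result.cars = cars
    return result
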