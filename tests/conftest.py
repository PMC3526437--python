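"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities from first principles
(marker walks on the circularised marker sequence; exhaustive maximisation
over joint candidate assignments) so that the fast implementations are
checked against independent code paths.
"""

from __future__ import annotations

import itertools
from collections import Counter

import pytest

from gapadj.genome_model import (Chromosome, Genome, O_GENE, SignedGene,
                                 TELOMERE)
from gapadj.phylogeny import SpeciesTree, TreeNode
from gapadj.scoring import BOTTOM, candidate_alphabet


# ---------------------------------------------------------------------------
# marker-walk adjacency oracle

def oracle_adjacency_items(genome: Genome, gene: str, side: str, alpha: int,
                           strict: bool = True):
    """Adjacency multiset derived by walking the literal marker sequence.

    For each occurrence of the focal gene, walk marker by marker away from
    the focal tail (left side) or head (right side); a marker ``c^h``/``c^t``
    reached with ``gap`` markers strictly in between contributes ``+c``/``-c``
    for a left scan (mirrored for right scans) whenever ``gap < alpha``.
    Walks stop at the focal gene's other marker and do not continue past the
    telomere's near marker.
    """
    items = []
    for chrom in genome.chromosomes:
        ring = chrom.ring()
        markers = []  # (symbol, kind) with kind in {t, h}
        for g in ring:
            pair = [(g.symbol, "t"), (g.symbol, "h")]
            markers.extend(pair if g.sign > 0 else pair[::-1])
        n = len(markers)
        for gi, g in enumerate(ring):
            if g.symbol != gene:
                continue
            # positions of this occurrence's markers
            p0, p1 = 2 * gi, 2 * gi + 1
            tail = p0 if g.sign > 0 else p1
            head = p1 if g.sign > 0 else p0
            # walk away from the focal gene: out of the tail for a left scan,
            # out of the head for a right scan, on the side not occupied by
            # the occurrence's other marker
            if side == "left":
                start, step, stop = tail, (1 if g.sign < 0 else -1), head
            else:
                start, step, stop = head, (-1 if g.sign < 0 else 1), tail
            between: list[int] = []  # marker positions strictly between
            pos = start
            for gap in range(alpha):
                pos = (pos + step) % n
                if pos == stop % n:
                    break
                sym, kind = markers[pos]
                if side == "left":
                    el = SignedGene(sym, 1) if kind == "h" else SignedGene(sym, -1)
                else:
                    el = SignedGene(sym, 1) if kind == "t" else SignedGene(sym, -1)
                if el.symbol == TELOMERE:
                    el = O_GENE
                # genes strictly inside the gap: both markers in `between`
                occ_count = Counter(p // 2 for p in between)
                full = {markers[2 * occ][0]
                        for occ, c in occ_count.items() if c == 2}
                if not (strict and (gene in full or el.symbol in full)):
                    items.append((el, gap))
                if sym == TELOMERE:
                    break  # the gap window never crosses a telomere
                between.append(pos)
        # circular chromosomes handled by the same modular walk
    return items


def oracle_multiset(genome, gene, side, alpha, strict=True) -> Counter:
    return Counter(el for el, _ in
                   oracle_adjacency_items(genome, gene, side, alpha, strict))


# ---------------------------------------------------------------------------
# exhaustive score oracle

def _match(x, y, wgd: bool) -> int:
    cx = Counter(g for g in x if g != BOTTOM)
    cy = Counter(g for g in y if g != BOTTOM)
    f = 2 if wgd else 1
    return sum(min(f * c, cy[g]) for g, c in cx.items())


def brute_force_totals(gene: str, side: str, alpha: int, tree: SpeciesTree,
                       node: TreeNode, strict: bool = True,
                       wgd_double: bool = True):
    """Exhaustive maximisation over all joint candidate assignments.

    Returns a map from each candidate multiset at ``node`` to the best
    achievable tree-wide conservation with that multiset clamped.
    """
    from gapadj.genome_model import alpha_adjacencies

    carriers = [n for n in tree.preorder() if n.mult(gene) >= 1]
    cset = set(carriers)
    internal = [n for n in carriers if not n.is_leaf]
    obs = {n: tuple(alpha_adjacencies(n.genome, gene, side, alpha,
                                      strict).counts.elements())
           for n in carriers if n.is_leaf}
    alphabet, _ = candidate_alphabet(gene, side, alpha,
                                     [n for n in carriers if n.is_leaf], strict)

    def cands(m):
        return list(itertools.combinations_with_replacement(alphabet, m))

    others = [n for n in internal if n is not node]
    out = {}
    for x in cands(node.mult(gene)):
        best = -1
        for vals in itertools.product(*[cands(n.mult(gene)) for n in others]):
            asn = dict(zip(others, vals))
            asn[node] = x
            tot = 0
            for u, v in tree.branches():
                if u in cset and v in cset:
                    mu = asn[u] if u in asn else obs[u]
                    mv = asn[v] if v in asn else obs[v]
                    tot += _match(mu, mv, u.is_wgd and wgd_double)
            best = max(best, tot)
        out[x] = best
    return out, alphabet


# ---------------------------------------------------------------------------

def rand_genome(rng, name: str, symbols, *, dup: bool = False,
                n_chrom: int = 1, p_neg: float = 0.3,
                p_loss: float = 0.0, circular: bool = False) -> Genome:
    """Random signed arrangement of the symbols (duplicated when ``dup``)."""
    genes = [SignedGene(s, 1) for s in symbols] * (2 if dup else 1)
    order = rng.permutation(len(genes))
    genes = [genes[i] if rng.random() > p_neg else -genes[i] for i in order]
    keep = [g for g in genes if rng.random() >= p_loss]
    if not keep:
        keep = genes[:1]
    n_chrom = min(n_chrom, len(keep))
    cuts = sorted(rng.choice(range(1, len(keep)), size=n_chrom - 1,
                             replace=False)) if n_chrom > 1 else []
    bounds = [0] + list(cuts) + [len(keep)]
    chroms = tuple(Chromosome(tuple(keep[a:b]), circular)
                   for a, b in zip(bounds[:-1], bounds[1:]) if b > a)
    return Genome(name, chroms)


@pytest.fixture
def identical_tree():
    """Three identical two-chromosome leaf genomes on a 5-node tree."""
    from gapadj.genome_model import genome
    from gapadj.phylogeny import assign_gene_content, read_tree

    make = lambda n: genome(n, ["1", "2", "3", "4"], ["5", "6"])
    tree = read_tree("((A,B)X,C)R;", [make("A"), make("B"), make("C")])
    return assign_gene_content(tree)
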