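"""Tree-wide adjacency-conservation scores for candidate ancestral adjacencies.

For one focal gene ``g``, one side (left/right) and one gap ``alpha``, the
score of clamping the side-``alpha``-adjacency multiset of ``g`` at a node
``u`` to a candidate multiset ``X`` is the maximum, over all assignments of
candidate multisets to the other internal nodes, of the number of conserved
adjacencies summed over the branches of the tree.  Leaves are clamped to the
multisets observed in the extant genomes; a branch whose parent is a WGD node
matches the doubled parent multiset against the child (a duplication doubles
every adjacency).

The maximisation decomposes over the tree and is computed by inside/outside
message passing: an inside table ``D(u, X)`` (best score in the subtree below
``u``) and an outside table ``U(u, X)`` (best score in the rest of the tree),
with ``total = D + U``.  Candidates are drawn from the finite alphabet of
signed genes observed as adjacencies of ``g`` at any leaf, plus the telomere
``O`` and a wildcard standing for any never-observed value, which matches
nothing.

Two engines produce identical tables: a vectorised one for gene
multiplicities up to 2 (the common case: at most one WGD above any node on
the queried path) and a generic multiset engine for higher multiplicities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations_with_replacement, groupby, product
from typing import Iterable, Sequence

import numpy as np

from .genome_model import O_GENE, SignedGene, alpha_adjacencies
from .phylogeny import SpeciesTree, TreeNode

#: wildcard candidate: "some value never observed at any leaf"; matches nothing
BOTTOM = SignedGene("⊥", 1)

_NEG = -(10 ** 9)  # -inf surrogate for integer score arrays


class MultiplicityError(ValueError):
    pass


@dataclass
class ScoreTables:
    """Per-node clamped-adjacency score tables for one (gene, side, alpha)."""

    gene: str
    side: str
    alpha: int
    alphabet: list[SignedGene]
    index: dict[SignedGene, int]
    #: node -> candidate multiset size (= mult(gene, node))
    mult: dict[TreeNode, int]
    #: node -> ndarray of shape (K,)*mult (fast) or dict over index tuples
    totals: dict[TreeNode, object]

    def total(self, node: TreeNode, multiset: Sequence[SignedGene]) -> int:
        key = tuple(sorted(self.index.get(h, self.index[BOTTOM]) for h in multiset))
        if len(key) != self.mult[node]:
            raise ValueError(
                f"multiset size {len(key)} != mult({self.gene},{node.name})="
                f"{self.mult[node]}")
        tab = self.totals[node]
        if isinstance(tab, dict):
            return int(tab[key])
        return int(tab[key])

    def score(self, node: TreeNode, h: SignedGene) -> int:
        """Singleton-clamp score; unobserved candidates fall back to the wildcard."""
        return self.total(node, (h,))


def candidate_alphabet(
    gene: str,
    side: str,
    alpha: int,
    carrier_leaves: Iterable[TreeNode],
    strict_gap_exclusion: bool = True,
) -> tuple[list[SignedGene], dict[TreeNode, Counter]]:
    """Observed adjacency support across leaves, plus ``O`` and the wildcard."""
    observed: dict[TreeNode, Counter] = {}
    support: set[SignedGene] = set()
    for leaf in carrier_leaves:
        ms = alpha_adjacencies(leaf.genome, gene, side, alpha, strict_gap_exclusion)
        observed[leaf] = ms.counts
        support |= ms.support()
    support.add(O_GENE)
    alphabet = sorted(support, key=lambda g: (g.symbol, -g.sign)) + [BOTTOM]
    return alphabet, observed


# ---------------------------------------------------------------------------
# vectorised engine (multiplicity <= 2)

def _leaf_msg(cnt: np.ndarray, parent_dim: int, wgd: bool) -> np.ndarray:
    if parent_dim == 1:
        return np.minimum(cnt, 2 if wgd else 1)
    a = np.minimum(cnt, 2 if wgd else 1)
    m = a[:, None] + a[None, :]
    np.fill_diagonal(m, np.minimum(cnt, 4 if wgd else 2))
    return m


def _inside_msg(d: np.ndarray, child_dim: int, parent_dim: int, wgd: bool,
                bot: int) -> np.ndarray:
    """max over child candidates Y of match(parent X, Y) + D(child, Y)."""
    if child_dim == 1:
        mx = int(d.max())
        d1 = d + 1
        d1[bot] = _NEG
        if parent_dim == 1:
            return np.maximum(mx, d1)
        return np.maximum(mx, np.maximum(d1[:, None], d1[None, :]))
    # child holds two copies: row maxima give the best Y containing an element
    r = d.max(axis=1)
    mx = int(r.max())
    r1 = r + 1
    r1[bot] = _NEG
    diag2 = np.diagonal(d) + 2
    diag2 = diag2.copy()
    diag2[bot] = _NEG
    if parent_dim == 1:
        m = np.maximum(mx, r1)
        if wgd:
            m = np.maximum(m, diag2)
        return m
    m = np.maximum(mx, np.maximum(r1[:, None], r1[None, :]))
    pair2 = d + 2
    pair2[bot, :] = _NEG
    pair2[:, bot] = _NEG
    m = np.maximum(m, pair2)
    if wgd:
        # doubled parent pair {x1,x1,x2,x2} can cover {xi,xi} at the child
        m = np.maximum(m, np.maximum(diag2[:, None], diag2[None, :]))
    return m


def _outside_msg(a: np.ndarray, parent_dim: int, child_dim: int, wgd: bool,
                 bot: int) -> np.ndarray:
    """max over parent candidates X of match(X, child Y) + A(parent, X)."""
    if parent_dim == 1:
        mx = int(a.max())
        a1 = a + 1
        a1[bot] = _NEG
        if child_dim == 1:
            return np.maximum(mx, a1)
        m = np.maximum(mx, np.maximum(a1[:, None], a1[None, :]))
        if wgd:
            d2 = a + 2
            d2[bot] = _NEG
            diag = np.maximum(mx, d2)
            m[np.arange(len(a)), np.arange(len(a))] = diag
        return m
    ra = a.max(axis=1)
    mx = int(ra.max())
    ra1 = ra + 1
    ra1 = ra1.copy()
    ra1[bot] = _NEG
    if child_dim == 1:
        return np.maximum(mx, ra1)
    m = np.maximum(mx, np.maximum(ra1[:, None], ra1[None, :]))
    pair2 = a + 2
    pair2[bot, :] = _NEG
    pair2[:, bot] = _NEG
    m = np.maximum(m, pair2)
    if wgd:
        ra2 = ra + 2
        ra2 = ra2.copy()
        ra2[bot] = _NEG
        idx = np.arange(len(ra))
        m[idx, idx] = np.maximum(mx, ra2)
    return m


def _run_fast(nodes_post, children_in, mult, obs_idx, K, bot, wgd_on):
    shape = {1: (K,), 2: (K, K)}
    d_tab: dict[TreeNode, np.ndarray] = {}
    msgs: dict[TreeNode, np.ndarray] = {}
    for u in nodes_post:
        if u not in children_in:
            continue
        wgd = u.is_wgd and wgd_on
        pd = mult[u]
        acc = np.zeros(shape[pd], dtype=np.int64)
        for v in children_in[u]:
            if v.is_leaf:
                msg = _leaf_msg(obs_idx[v], pd, wgd)
            else:
                msg = _inside_msg(d_tab[v], mult[v], pd, wgd, bot)
            msgs[v] = msg
            acc = acc + msg
        d_tab[u] = acc
    root = nodes_post[-1]
    u_tab: dict[TreeNode, np.ndarray] = {root: np.zeros(shape[mult[root]], dtype=np.int64)}
    for u in reversed(nodes_post):
        if u not in children_in:
            continue
        wgd = u.is_wgd and wgd_on
        internal_kids = [v for v in children_in[u] if not v.is_leaf]
        for v in internal_kids:
            a = u_tab[u].copy()
            for w in children_in[u]:
                if w is not v:
                    a = a + msgs[w]
            u_tab[v] = _outside_msg(a, mult[u], mult[v], wgd, bot)
    return {u: d_tab[u] + u_tab[u] for u in d_tab}


# ---------------------------------------------------------------------------
# generic multiset engine (any multiplicity, dict-based)

def _submultisets(t: tuple[int, ...]):
    items = [(k, len(list(g))) for k, g in groupby(t)]
    for choice in product(*(range(c + 1) for _, c in items)):
        yield tuple(x for (k, _), m in zip(items, choice) for x in [k] * m)


def _strip(t: tuple[int, ...], bot: int) -> tuple[int, ...]:
    return tuple(x for x in t if x != bot)


def _eff(x: tuple[int, ...], wgd: bool, bot: int) -> tuple[int, ...]:
    s = _strip(x, bot)
    return tuple(sorted(s + s)) if wgd else s


def _leaf_match(x: tuple[int, ...], cnt: dict[int, int], wgd: bool, bot: int) -> int:
    cx = Counter(_strip(x, bot))
    f = 2 if wgd else 1
    return sum(min(f * c, cnt.get(k, 0)) for k, c in cx.items())


def _best_over(table: dict, keyset_of, query_subsets) -> dict:
    """best_sup[T] = max over entries whose key set contains T."""
    best: dict[tuple, int] = {}
    for key, val in table.items():
        for t in keyset_of(key):
            if t not in best or val > best[t]:
                best[t] = val
    return best


def _run_generic(nodes_post, children_in, mult, obs_counts, K, bot, wgd_on):
    def candidates(m):
        return list(combinations_with_replacement(range(K), m))

    d_tab: dict[TreeNode, dict] = {}
    msgs: dict[TreeNode, dict] = {}

    def inside_message(v, parent_xs, wgd):
        if v.is_leaf:
            cnt = obs_counts[v]
            return {x: _leaf_match(x, cnt, wgd, bot) for x in parent_xs}
        best = _best_over(d_tab[v], lambda y: _submultisets(_strip(y, bot)), None)
        out = {}
        for x in parent_xs:
            e = _eff(x, wgd, bot)
            out[x] = max(len(t) + best[t]
                         for t in set(_submultisets(e)) if t in best)
        return out

    for u in nodes_post:
        if u not in children_in:
            continue
        wgd = u.is_wgd and wgd_on
        xs = candidates(mult[u])
        acc = {x: 0 for x in xs}
        for v in children_in[u]:
            msg = inside_message(v, xs, wgd)
            msgs[v] = msg
            for x in xs:
                acc[x] += msg[x]
        d_tab[u] = acc

    root = nodes_post[-1]
    u_tab: dict[TreeNode, dict] = {root: {x: 0 for x in candidates(mult[root])}}
    for u in reversed(nodes_post):
        if u not in children_in:
            continue
        wgd = u.is_wgd and wgd_on
        for v in children_in[u]:
            if v.is_leaf:
                continue
            a = {}
            for x in u_tab[u]:
                val = u_tab[u][x]
                for w in children_in[u]:
                    if w is not v:
                        val += msgs[w][x]
                a[x] = val
            best = _best_over(a, lambda x: _submultisets(_eff(x, wgd, bot)), None)
            u_tab[v] = {
                y: max(len(t) + best[t]
                       for t in set(_submultisets(_strip(y, bot))) if t in best)
                for y in candidates(mult[v])
            }
    return {u: {x: d_tab[u][x] + u_tab[u][x] for x in d_tab[u]} for u in d_tab}


# ---------------------------------------------------------------------------

def compute_score_tables(
    gene: str,
    side: str,
    alpha: int,
    tree: SpeciesTree,
    strict_gap_exclusion: bool = True,
    wgd_double_match: bool = True,
    mult_cap: int = 4,
    engine: str = "auto",
) -> ScoreTables:
    """Inside/outside score tables for one gene and side at gap ``alpha``.

    ``engine`` is ``"auto"`` (vectorised when every internal multiplicity is
    at most 2), ``"fast"`` or ``"generic"``.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    carriers = [n for n in tree.preorder() if n.mult(gene) >= 1]
    if not carriers:
        raise KeyError(f"gene {gene!r} carried by no node of the tree")
    carrier_set = set(carriers)
    tops = [n for n in carriers if n.parent not in carrier_set]
    if len(tops) != 1:
        raise ValueError(f"carriers of {gene!r} do not form a connected subtree")

    leaf_carriers = [n for n in carriers if n.is_leaf]
    alphabet, observed = candidate_alphabet(
        gene, side, alpha, leaf_carriers, strict_gap_exclusion)
    K = len(alphabet)
    index = {g: i for i, g in enumerate(alphabet)}
    bot = index[BOTTOM]

    mult = {n: n.mult(gene) for n in carriers}
    internal = [n for n in carriers if not n.is_leaf]
    for n in internal:
        if mult[n] > mult_cap:
            raise MultiplicityError(
                f"mult({gene},{n.name})={mult[n]} exceeds cap {mult_cap}")

    children_in = {
        u: [v for v in u.children if v in carrier_set]
        for u in internal
    }
    # carrier postorder restricted to internal nodes, root last
    order = [n for n in tree.postorder() if n in children_in]

    if not order:
        # gene present at a single leaf only: no internal tables
        return ScoreTables(gene, side, alpha, alphabet, index, mult, {})

    use_fast = engine == "fast" or (
        engine == "auto" and all(mult[n] <= 2 for n in internal))
    if use_fast:
        obs_idx = {}
        for leaf, cnt in observed.items():
            arr = np.zeros(K, dtype=np.int64)
            for g, c in cnt.items():
                arr[index[g]] = c
            obs_idx[leaf] = arr
        totals = _run_fast(order, children_in, mult, obs_idx, K, bot,
                           wgd_double_match)
    else:
        obs_counts = {
            leaf: {index[g]: c for g, c in cnt.items()}
            for leaf, cnt in observed.items()
        }
        totals = _run_generic(order, children_in, mult, obs_counts, K, bot,
                              wgd_double_match)
    return ScoreTables(gene, side, alpha, alphabet, index, mult, totals)


def branch_match(x: Counter, y: Counter, parent_is_wgd: bool = False) -> int:
    """Conserved-adjacency count between candidate multisets on one branch.

    The parent multiset is doubled when the parent is a WGD node; the
    wildcard matches nothing.
    """
    f = 2 if parent_is_wgd else 1
    return sum(min(f * c, y.get(g, 0)) for g, c in x.items() if g != BOTTOM)


@dataclass
class NodeScores:
    """L/R singleton-clamp score maps at a pre-duplication node."""

    node: TreeNode
    alpha: int
    left: dict[str, ScoreTables]
    right: dict[str, ScoreTables]

    def L(self, gene: str, h: SignedGene) -> int:
        """LeftAdj(gene, S | LA(gene, alpha, G(node)) = {h})."""
        return self.left[gene].score(self.node, h)

    def R(self, gene: str, h: SignedGene) -> int:
        return self.right[gene].score(self.node, h)


def score_tables_at_node(
    nu: TreeNode,
    alpha: int,
    genes: Iterable[str],
    tree: SpeciesTree,
    strict_gap_exclusion: bool = True,
    wgd_double_match: bool = True,
    mult_cap: int = 4,
    engine: str = "auto",
) -> NodeScores:
    """Singleton L/R score maps at a node where every queried gene is single-copy."""
    left: dict[str, ScoreTables] = {}
    right: dict[str, ScoreTables] = {}
    for g in genes:
        if nu.mult(g) != 1:
            raise MultiplicityError(
                f"mult({g},{nu.name})={nu.mult(g)}; the queried node must "
                "precede all duplications of the gene")
        left[g] = compute_score_tables(
            g, "left", alpha, tree, strict_gap_exclusion, wgd_double_match,
            mult_cap, engine)
        right[g] = compute_score_tables(
            g, "right", alpha, tree, strict_gap_exclusion, wgd_double_match,
            mult_cap, engine)
    return NodeScores(nu, alpha, left, right)
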