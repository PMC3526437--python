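"""Species trees with speciation and whole-genome-duplication (WGD) nodes.

Speciation nodes are binary; a WGD node has a single child and its label
stands for the genome *just before* the duplication (one copy of each gene).
Gene content and multiplicity at ancestral nodes is assigned by two bottom-up
passes: WGD nodes first receive every gene whose maximum multiplicity among
their direct descendants (nearest WGD-or-leaf below) is at least 2, halved
and rounded up; then every gene is propagated to the nodes lying on a path
from the LCA of its carriers (leaves or WGD carriers) down to a carrying
leaf, taking the maximum multiplicity of the children where not already set.
"""

from __future__ import annotations


import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

from .genome_model import Genome, TELOMERE, adj_cons_genomes

SPECIATION = "speciation"
WGD = "wgd"
LEAF = "leaf"


class TreeError(ValueError):
    pass


@dataclass(eq=False)
class TreeNode:
    name: str
    kind: str = SPECIATION
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)
    #: gene symbol -> multiplicity (content of the genome at this node)
    content: dict[str, int] = field(default_factory=dict)
    #: genome label G(u); set for leaves, and for all nodes in simulations
    genome: Genome | None = None

    @property
    def is_leaf(self) -> bool:
        return self.kind == LEAF

    @property
    def is_wgd(self) -> bool:
        return self.kind == WGD

    def mult(self, gene: str) -> int:
        return self.content.get(gene, 0)

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:
        return f"<TreeNode {self.name} ({self.kind})>"


@dataclass(eq=False)
class SpeciesTree:
    root: TreeNode

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        return reversed(list(self.preorder()))

    @property
    def nodes(self) -> list[TreeNode]:
        return list(self.preorder())

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def node(self, name: str) -> TreeNode:
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}; valid names: "
                       + ", ".join(n.name for n in self.preorder()))

    def branches(self) -> Iterator[tuple[TreeNode, TreeNode]]:
        """All (parent, child) pairs."""
        for u in self.preorder():
            for v in u.children:
                yield u, v

    def n_branches(self) -> int:
        return sum(1 for _ in self.branches())

    def depths(self) -> dict[TreeNode, int]:
        d = {self.root: 0}
        for u, v in self.branches():
            d[v] = d[u] + 1
        return d

    def lca(self, nodes: Iterable[TreeNode]) -> TreeNode:
        nodes = list(nodes)
        if not nodes:
            raise ValueError("lca of empty node set")
        depth = self.depths()
        cur = nodes[0]
        for other in nodes[1:]:
            a, b = cur, other
            while a is not b:
                if depth[a] >= depth[b]:
                    a = a.parent
                else:
                    b = b.parent
            cur = a
        return cur

    def subtree_nodes(self, top: TreeNode) -> list[TreeNode]:
        out, stack = [], [top]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def validate(self) -> None:
        for n in self.preorder():
            if n.is_leaf and n.children:
                raise TreeError(f"leaf {n.name} has children")
            if n.kind == WGD and len(n.children) != 1:
                raise TreeError(f"WGD node {n.name} must have exactly 1 child")
            if n.kind == SPECIATION and len(n.children) != 2:
                raise TreeError(
                    f"speciation node {n.name} must have exactly 2 children, "
                    f"found {len(n.children)}")


# ---------------------------------------------------------------------------
# Newick parsing

def parse_tree_skeleton(newick_text: str) -> SpeciesTree:
    """Parse a Newick tree into a :class:`SpeciesTree` without genomes.

    Internal-node labels containing the token ``WGD`` mark duplication
    events: a one-child node becomes the WGD node itself, while on a
    two-child node a WGD node is spliced in directly above it.
    """
    dtree = dendropy.Tree.get(
        data=newick_text, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True)
    counter = [0]

    def fresh_name() -> str:
        counter[0] += 1
        return f"n{counter[0]}"

    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
        is_leaf = len(dnode.child_nodes()) == 0
        node = TreeNode(name=label or fresh_name(), kind=LEAF if is_leaf else SPECIATION)
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        if not is_leaf and label and "WGD" in label:
            if len(node.children) == 1:
                node.kind = WGD
            else:
                wgd = TreeNode(name=f"{label}", kind=WGD)
                node.name = f"{label}_post"
                wgd.add_child(node)
                node = wgd
        elif not is_leaf and len(node.children) == 1:
            node.kind = WGD  # single-child internal nodes can only be WGDs
        return node

    tree = SpeciesTree(convert(dtree.seed_node))
    tree.validate()
    return tree


def read_tree(newick_text: str, genomes: Iterable[Genome]) -> SpeciesTree:
    """Parse a Newick species tree and attach one genome per leaf by name."""
    tree = parse_tree_skeleton(newick_text)
    by_name = {g.name: g for g in genomes}
    leaves = tree.leaves
    leaf_names = {n.name for n in leaves}
    if leaf_names != set(by_name):
        raise TreeError(
            f"leaf names {sorted(leaf_names)} do not match genome names "
            f"{sorted(by_name)}")
    for leaf in leaves:
        leaf.genome = by_name[leaf.name]
        leaf.content = dict(leaf.genome.gene_counts)
    return tree


def write_newick(tree: SpeciesTree) -> str:
    def fmt(node: TreeNode) -> str:
        label = node.name if not node.is_wgd or "WGD" in node.name \
            else f"{node.name}_WGD"
        if node.is_leaf:
            return label
        return "(" + ",".join(fmt(c) for c in node.children) + ")" + label
    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# WGD placement and gene content

def required_wgd_depth(genome: Genome) -> int:
    """Number of WGDs needed above a leaf: ceil(log2(max multiplicity >= 2))."""
    mx = max((c for g, c in genome.gene_counts.items() if g != TELOMERE),
             default=1)
    return math.ceil(math.log2(mx)) if mx >= 2 else 0


def insert_wgd_nodes(tree: SpeciesTree) -> SpeciesTree:
    """Insert WGD nodes inferred from leaf multiplicities.

    Each shared WGD is placed as high as possible: at every node, as many
    WGD nodes are inserted above it as the minimum still-required count over
    the leaves of its subtree.  A WGD required by every leaf therefore lands
    above the root.
    """
    req: dict[TreeNode, int] = {}
    for leaf in tree.leaves:
        if leaf.genome is None:
            raise TreeError(f"leaf {leaf.name} has no genome attached")
        req[leaf] = required_wgd_depth(leaf.genome)

    def splice_above(node: TreeNode, count: int) -> TreeNode:
        top = node
        for i in range(count):
            wgd = TreeNode(name=f"WGD_{node.name}_{i + 1}", kind=WGD)
            parent = top.parent
            wgd.add_child(top)
            if parent is None:
                tree.root = wgd
            else:
                parent.children[parent.children.index(top)] = wgd
                wgd.parent = parent
            top = wgd
        return top

    def rec(node: TreeNode, inherited: int) -> None:
        leaves = [n for n in tree.subtree_nodes(node) if n.is_leaf]
        need = min(req[l] - inherited for l in leaves)
        if need < 0:
            raise TreeError(
                "inconsistent WGD requirements; annotate WGD nodes explicitly")
        if need:
            splice_above(node, need)
            inherited += need
        if node.is_leaf:
            if req[node] != inherited:
                raise TreeError(
                    "inconsistent WGD requirements; annotate WGD nodes explicitly")
            return
        for c in list(node.children):
            rec(c, inherited)

    rec(tree.root, 0)
    tree.validate()
    return tree


def direct_descendants(node: TreeNode) -> list[TreeNode]:
    """Nearest WGD-or-leaf nodes below a WGD node, no intervening WGD."""
    out: list[TreeNode] = []
    stack = list(node.children)
    while stack:
        n = stack.pop()
        if n.is_leaf or n.is_wgd:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def assign_gene_content(tree: SpeciesTree) -> SpeciesTree:
    """Assign gene content and multiplicity at every internal node (two passes)."""
    for leaf in tree.leaves:
        if leaf.genome is None:
            raise TreeError(f"leaf {leaf.name} has no genome attached")
        leaf.content = dict(leaf.genome.gene_counts)

    post = list(tree.postorder())
    for n in post:
        if not n.is_leaf:
            n.content = {}

    # pass 1: WGD nodes, halving the best direct descendant (bottom-up)
    for n in post:
        if n.is_wgd:
            dd = direct_descendants(n)
            genes = set().union(*(set(d.content) for d in dd)) if dd else set()
            for g in genes:
                mv = max(d.mult(g) for d in dd)
                if mv >= 2:
                    n.content[g] = -(-mv // 2)  # ceil(mv / 2)

    # pass 2: propagate each gene on the paths LCA(carriers) -> carrying leaves
    all_genes: set[str] = set()
    for leaf in tree.leaves:
        all_genes |= set(leaf.content)
    depths = tree.depths()
    for g in all_genes:
        carriers = [n for n in post if (n.is_leaf or n.is_wgd) and g in n.content]
        top = tree.lca(carriers)
        # ancestors-or-self (within the LCA subtree) of carrying leaves
        marked: set[TreeNode] = set()
        for leaf in tree.leaves:
            if g in leaf.content:
                n = leaf
                while n is not None and depths[n] >= depths[top]:
                    marked.add(n)
                    n = n.parent
        for n in post:  # children before parents
            if n in marked and g not in n.content:
                n.content[g] = max((c.mult(g) for c in n.children), default=1)
    return tree


def max_adj(gene: str, tree: SpeciesTree) -> int:
    """Number of tree nodes (of any kind) whose content includes the gene."""
    return sum(1 for n in tree.preorder() if n.mult(gene) >= 1)


def max_adj_copies(gene: str, tree: SpeciesTree) -> int:
    """Total copy number of a gene summed over all tree nodes.

    Equals :func:`max_adj` when the gene is single-copy everywhere; with
    duplications it grows with multiplicity, so that using it to normalise
    conservation scores does not favour high-multiplicity genes (a duplicated
    branch can conserve an adjacency once per copy).
    """
    return sum(n.mult(gene) for n in tree.preorder())


def adj_cons_tree(alpha: int, tree: SpeciesTree,
                  strict_gap_exclusion: bool = True) -> int:
    """Conserved alpha-adjacencies summed over all branches of a labeled tree."""
    total = 0
    for u, v in tree.branches():
        if u.genome is None or v.genome is None:
            raise TreeError(f"branch ({u.name},{v.name}) has an unlabeled node")
        total += adj_cons_genomes(alpha, u.genome, v.genome, strict_gap_exclusion)
    return total


def infer_events(tree: SpeciesTree) -> list[dict]:
    """Per-branch gain and loss counts implied by the assigned gene content.

    On a branch (u, v) the expected copy number arriving at v is
    ``2 * mult(g, u)`` when u is a WGD node and ``mult(g, u)`` otherwise;
    losses are the total shortfall and gains the number of genes appearing
    at v with no copy at u.
    """
    rows = []
    for u, v in tree.branches():
        losses = gains = 0
        for g in set(u.content) | set(v.content):
            e = (2 if u.is_wgd else 1) * u.mult(g)
            losses += max(0, e - v.mult(g))
            if u.mult(g) == 0 and v.mult(g) >= 1:
                gains += 1
        rows.append({"parent": u.name, "child": v.name,
                     "gains": gains, "losses": losses})
    return rows
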