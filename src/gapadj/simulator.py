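"""Genome-evolution simulator: inversions, translocations, fusions, fissions,
gene losses and whole-genome duplications along a species tree.

Every node of the returned tree keeps its true genome so that reconstructions
can be scored against the simulated ancestor.  Branch dynamics: on the branch
from ``u`` to ``v``, if ``u`` is a WGD node the genome is doubled and the
configured number of immediately-post-duplication losses applied; then the
branch's own losses, then ``r`` rearrangements with ``r`` drawn uniformly in
``[ceil(rmax/2), rmax]`` and the operation kind drawn from the configured
Inversion : Translocation : (Fusion+Fission) mix.  Inverted segment lengths
are geometric (default ``p = 0.5``, mean 2), favouring short inversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome_model import Chromosome, Genome, SignedGene
from .phylogeny import SpeciesTree, parse_tree_skeleton


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 200
    n_chromosomes: int = 1
    rmax: int = 20
    geometric_p: float = 0.5
    #: Inversion : Translocation : (Fusion+Fission) ratio
    op_mix: tuple[float, float, float] = (5.0, 4.0, 1.0)
    #: losses per branch: a single count, or a map from child-node name
    branch_losses: int | dict[str, int] = 0
    #: losses applied right after each WGD, before other branch events
    wgd_losses: int = 0

    def __post_init__(self):
        if not (0 < self.geometric_p <= 1):
            raise ValueError("geometric_p must be in (0, 1]")
        if self.n_genes < self.n_chromosomes or self.n_chromosomes < 1:
            raise ValueError("need n_genes >= n_chromosomes >= 1")
        if self.rmax < 0 or self.wgd_losses < 0:
            raise ValueError("counts must be non-negative")

    def losses_for(self, child_name: str) -> int:
        if isinstance(self.branch_losses, dict):
            return self.branch_losses.get(child_name, 0)
        return self.branch_losses


def random_root(n_genes: int, n_chromosomes: int,
                rng: np.random.Generator | None = None) -> Genome:
    """Identity-order genome ``1..n`` split into near-equal linear chromosomes."""
    if n_genes < n_chromosomes or n_chromosomes < 1:
        raise ValueError("need n_genes >= n_chromosomes >= 1")
    bounds = np.linspace(0, n_genes, n_chromosomes + 1).round().astype(int)
    chroms = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        chroms.append(Chromosome(
            tuple(SignedGene(str(i + 1), 1) for i in range(lo, hi))))
    return Genome("root", tuple(chroms))


def _as_lists(genome: Genome) -> list[list[SignedGene]]:
    return [list(c.genes) for c in genome.chromosomes]


def _from_lists(name: str, chroms: list[list[SignedGene]]) -> Genome:
    return Genome(name, tuple(Chromosome(tuple(c)) for c in chroms if c))


def _pick_position(chroms: list[list[SignedGene]], rng) -> tuple[int, int]:
    sizes = np.array([len(c) for c in chroms])
    pos = int(rng.integers(sizes.sum()))
    ci = int(np.searchsorted(sizes.cumsum(), pos, side="right"))
    return ci, pos - int(sizes[:ci].sum())


def apply_inversion(genome: Genome, rng: np.random.Generator,
                    p: float = 0.5) -> Genome:
    """Reverse-and-negate a geometric-length segment at a uniform position."""
    chroms = _as_lists(genome)
    ci, i = _pick_position(chroms, rng)
    length = int(rng.geometric(p))
    return _invert_at(genome, ci, i, length)


def _invert_at(genome: Genome, ci: int, i: int, length: int) -> Genome:
    chroms = _as_lists(genome)
    c = chroms[ci]
    j = min(i + length, len(c))
    c[i:j] = [-g for g in reversed(c[i:j])]
    return _from_lists(genome.name, chroms)


def apply_interchromosomal(genome: Genome, kind: str,
                           rng: np.random.Generator) -> Genome:
    """One translocation (reciprocal suffix swap), fusion or fission."""
    chroms = _as_lists(genome)
    if kind == "translocation":
        if len(chroms) < 2:
            raise ValueError("translocation needs >= 2 chromosomes")
        a, b = rng.choice(len(chroms), size=2, replace=False)
        ca, cb = chroms[int(a)], chroms[int(b)]
        i = int(rng.integers(len(ca) + 1))
        j = int(rng.integers(len(cb) + 1))
        chroms[int(a)], chroms[int(b)] = ca[:i] + cb[j:], cb[:j] + ca[i:]
    elif kind == "fusion":
        if len(chroms) < 2:
            raise ValueError("fusion needs >= 2 chromosomes")
        a, b = rng.choice(len(chroms), size=2, replace=False)
        tail = chroms[int(b)]
        if rng.integers(2):
            tail = [-g for g in reversed(tail)]
        chroms[int(a)] = chroms[int(a)] + tail
        del chroms[int(b)]
    elif kind == "fission":
        eligible = [k for k, c in enumerate(chroms) if len(c) >= 2]
        if not eligible:
            raise ValueError("fission needs a chromosome with >= 2 genes")
        k = int(rng.choice(eligible))
        cut = int(rng.integers(1, len(chroms[k])))
        chroms.append(chroms[k][cut:])
        chroms[k] = chroms[k][:cut]
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return _from_lists(genome.name, chroms)


def apply_loss(genome: Genome, rng: np.random.Generator) -> Genome:
    """Remove one uniformly chosen gene occurrence; drop emptied chromosomes."""
    chroms = _as_lists(genome)
    ci, i = _pick_position(chroms, rng)
    del chroms[ci][i]
    return _from_lists(genome.name, chroms)


def apply_wgd(genome: Genome) -> Genome:
    """Double every chromosome (every multiplicity doubles)."""
    return Genome(genome.name, genome.chromosomes + genome.chromosomes)


def _apply_rearrangement(genome: Genome, config: SimConfig,
                         rng: np.random.Generator) -> Genome:
    mix = np.asarray(config.op_mix, dtype=float)
    probs = mix / mix.sum()
    for _ in range(20):  # resample kind on infeasible preconditions
        k = int(rng.choice(3, p=probs))
        if k == 0:
            return apply_inversion(genome, rng, config.geometric_p)
        if k == 1:
            kind = "translocation"
        else:
            kind = "fusion" if rng.integers(2) else "fission"
        try:
            return apply_interchromosomal(genome, kind, rng)
        except ValueError:
            continue
    return genome


def simulate(
    topology: SpeciesTree | str,
    config: SimConfig,
    seed: int = 0,
) -> SpeciesTree:
    """Evolve a root genome down a species-tree topology; label every node.

    ``topology`` is a :class:`SpeciesTree` skeleton or a Newick string (with
    WGD nodes marked).  The same seed reproduces the tree exactly.
    """
    tree = parse_tree_skeleton(topology) if isinstance(topology, str) else topology
    rng = np.random.default_rng(seed)
    root_genome = random_root(config.n_genes, config.n_chromosomes, rng)
    tree.root.genome = Genome(tree.root.name, root_genome.chromosomes)

    for u in tree.preorder():
        for v in u.children:
            g = Genome(v.name, u.genome.chromosomes)
            if u.is_wgd:
                g = apply_wgd(g)
                for _ in range(config.wgd_losses):
                    if g.chromosomes:
                        g = apply_loss(g, rng)
            for _ in range(config.losses_for(v.name)):
                if g.chromosomes:
                    g = apply_loss(g, rng)
            lo = math.ceil(config.rmax / 2)
            r = int(rng.integers(lo, config.rmax + 1)) if config.rmax else 0
            for _ in range(r):
                g = _apply_rearrangement(g, config, rng)
            v.genome = g
            if v.is_leaf:
                v.content = dict(g.gene_counts)
    return tree


# ---------------------------------------------------------------------------
# fixture topologies used throughout the simulation studies

#: six non-duplicated species; ``sigma`` is the ancestor of A..E, the node
#: reconstructed in the single/multi-chromosome protocols
SIX_LEAF_NEWICK = "((((A,B)n_ab,C)n_abc,(D,E)n_de)sigma,F)rho;"

#: three species descending from one shared WGD; the reconstructed node is
#: the pre-duplication ancestor (the WGD node spliced above the root)
CEREAL_WGD_NEWICK = "((rice,brachypodium)n_rb,sorghum)WGD_cereal;"

#: four post-WGD species plus one outgroup that predates the duplication
YEAST_WGD_NEWICK = "(((scer,cgla)n_sc,(vpol,ndai)n_vn)WGD_yeast,zrou)tau;"
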