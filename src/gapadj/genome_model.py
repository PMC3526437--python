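"""Signed gene-order genomes and gapped-adjacency multisets.

A genome is a set of chromosomes, each a sequence of signed genes.  Linear
chromosomes are closed into rings by appending the artificial telomeric gene
``O``, so that every chromosome can be scanned circularly.  Every gene ``g``
is viewed as an ordered pair of unsigned markers, tail ``g^t`` and head
``g^h`` (``+g`` reads tail-then-head, ``-g`` head-then-tail).

A signed gene ``b`` is a *left alpha-adjacency* of gene ``a`` when the number
of markers strictly between the trailing marker of ``b`` (``b^h`` for ``+b``,
``b^t`` for ``-b``) and ``a^t`` is smaller than ``alpha``; right adjacencies
are defined symmetrically from ``a^h``.  Direct neighbours are the ``alpha=1``
case; larger gaps admit genes further away, each neighbouring gene
contributing through both of its markers (one per sign) as the window grows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, NamedTuple

TELOMERE = "O"


class SignedGene(NamedTuple):
    """A gene symbol with an orientation in {+1, -1}.

    The telomeric gene ``O`` is always positive; negating it is a no-op.
    """

    symbol: str
    sign: int = 1

    def __neg__(self) -> "SignedGene":
        if self.symbol == TELOMERE:
            return self
        return SignedGene(self.symbol, -self.sign)

    def __str__(self) -> str:
        return ("-" if self.sign < 0 else "") + self.symbol


O_GENE = SignedGene(TELOMERE, 1)


def sg(token: str) -> SignedGene:
    """Parse a signed-gene token such as ``"a"``, ``"-a"`` or ``"+12"``."""
    token = token.strip()
    sign = 1
    if token.startswith("-"):
        sign, token = -1, token[1:]
    elif token.startswith("+"):
        token = token[1:]
    if not token:
        raise ValueError("empty gene token")
    if token == TELOMERE:
        sign = 1
    return SignedGene(token, sign)


@dataclass(frozen=True)
class Chromosome:
    """An ordered run of signed genes, linear by default."""

    genes: tuple[SignedGene, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("chromosome must be non-empty")
        if any(g.symbol == TELOMERE for g in self.genes):
            raise ValueError(f"reserved telomere symbol {TELOMERE!r} in chromosome")

    def ring(self) -> tuple[SignedGene, ...]:
        """Circularised view: linear chromosomes get ``O`` appended."""
        return self.genes if self.circular else self.genes + (O_GENE,)

    def reversed(self) -> "Chromosome":
        return Chromosome(tuple(-g for g in reversed(self.genes)), self.circular)

    def __len__(self) -> int:
        return len(self.genes)


def chrom(tokens: Iterable[str | SignedGene], circular: bool = False) -> Chromosome:
    genes = tuple(t if isinstance(t, SignedGene) else sg(t) for t in tokens)
    return Chromosome(genes, circular)


@dataclass(frozen=True)
class Genome:
    """A named set of chromosomes with derived gene content."""

    name: str
    chromosomes: tuple[Chromosome, ...]

    @cached_property
    def rings(self) -> tuple[tuple[SignedGene, ...], ...]:
        return tuple(c.ring() for c in self.chromosomes)

    @cached_property
    def gene_counts(self) -> Counter:
        """Multiplicity of every gene including ``O`` (one per linear chromosome)."""
        counts: Counter = Counter()
        for ring in self.rings:
            counts.update(g.symbol for g in ring)
        return counts

    @cached_property
    def _occurrences(self) -> dict[str, list[tuple[int, int]]]:
        occ: dict[str, list[tuple[int, int]]] = {}
        for ri, ring in enumerate(self.rings):
            for i, g in enumerate(ring):
                occ.setdefault(g.symbol, []).append((ri, i))
        return occ

    @property
    def gene_set(self) -> set[str]:
        return set(self.gene_counts)

    def mult(self, symbol: str) -> int:
        return self.gene_counts.get(symbol, 0)

    def n_genes(self) -> int:
        """Total number of gene occurrences, ``O`` excluded."""
        return sum(len(c.genes) for c in self.chromosomes)

    def reversed(self) -> "Genome":
        return Genome(self.name, tuple(c.reversed() for c in self.chromosomes))

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)


def genome(name: str, *chromosome_specs, circular: bool = False) -> Genome:
    """Convenience constructor: ``genome("A", ["1", "-2"], ["3"])``."""
    return Genome(name, tuple(chrom(spec, circular) for spec in chromosome_specs))


def marker_sequence(chromosome: Chromosome) -> tuple[str, ...]:
    """The circular marker ring of a chromosome.

    ``+g`` expands to ``(g^t, g^h)``, ``-g`` to ``(g^h, g^t)``; linear
    chromosomes contribute the two markers of the appended ``O``.
    """
    markers: list[str] = []
    for g in chromosome.ring():
        t, h = f"{g.symbol}^t", f"{g.symbol}^h"
        markers.extend((t, h) if g.sign > 0 else (h, t))
    return tuple(markers)


@dataclass(frozen=True)
class AdjacencyMultiset:
    """Multiset of signed genes adjacent (at gap ``alpha``) to a focal gene."""

    counts: Counter
    focal: str
    side: str
    gap: int

    def __len__(self) -> int:
        return sum(self.counts.values())

    def support(self) -> set[SignedGene]:
        return {g for g, c in self.counts.items() if c > 0}


def alpha_adjacency_items(
    genome: Genome,
    gene: str,
    side: str,
    alpha: int,
    strict_gap_exclusion: bool = True,
) -> list[tuple[SignedGene, int]]:
    """All (signed gene, marker gap) contributions to ``LA``/``RA`` of a gene.

    Each occurrence of the focal gene is scanned outward on the requested
    side; occurrences carried as ``-g`` are read in reversed orientation with
    all signs flipped.  The gene at ring distance ``k`` contributes its
    scanned sign at marker gap ``2(k-1)`` and the flipped sign at gap
    ``2k-1``, as long as the gap stays below ``alpha``.  The scan never wraps
    past the focal occurrence itself.

    With ``strict_gap_exclusion`` a contribution is suppressed when a copy of
    the focal or of the contributed gene lies strictly inside the gap window.

    Gap windows never extend across a telomere: on a linear chromosome the
    telomere gene contributes through its near marker and the scan stops
    there, so genes of the same chromosome are never re-read "around" the
    artificial circularisation.
    """
    if alpha < 1:
        raise ValueError(f"alpha must be >= 1, got {alpha}")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    occs = genome._occurrences.get(gene)
    if occs is None:
        raise KeyError(f"gene {gene!r} not present in genome {genome.name!r}")

    items: list[tuple[SignedGene, int]] = []
    max_k = (alpha + 1) // 2
    for ri, i in occs:
        ring = genome.rings[ri]
        n = len(ring)
        s = ring[i].sign
        # canonical left side = ring-backwards for +g, ring-forwards for -g
        step = -1 if (side == "left") == (s > 0) else 1
        flip = s < 0
        seen: Counter = Counter()
        for k in range(1, min(max_k, n - 1) + 1):
            b = ring[(i + step * k) % n]
            if flip:
                b = -b
            suppressed = strict_gap_exclusion and (seen[gene] or seen[b.symbol])
            if not suppressed:
                items.append((b, 2 * (k - 1)))
            if b.symbol == TELOMERE:
                break
            if not suppressed and 2 * k - 1 < alpha:
                items.append((-b, 2 * k - 1))
            seen[b.symbol] += 1
    return items


def alpha_adjacencies(
    genome: Genome,
    gene: str,
    side: str,
    alpha: int,
    strict_gap_exclusion: bool = True,
) -> AdjacencyMultiset:
    """``LA(g, alpha, G)`` (side='left') or ``RA(g, alpha, G)`` (side='right')."""
    items = alpha_adjacency_items(genome, gene, side, alpha, strict_gap_exclusion)
    return AdjacencyMultiset(Counter(g for g, _ in items), gene, side, alpha)


def multiset_intersection_size(a: Counter | AdjacencyMultiset, b: Counter | AdjacencyMultiset) -> int:
    """Size of the multiset intersection (sum of per-element min counts)."""
    ca = a.counts if isinstance(a, AdjacencyMultiset) else a
    cb = b.counts if isinstance(b, AdjacencyMultiset) else b
    if len(cb) < len(ca):
        ca, cb = cb, ca
    return sum(min(c, cb[g]) for g, c in ca.items() if g in cb)


def adj_cons_gene(
    gene: str,
    alpha: int,
    gu: Genome,
    gv: Genome,
    strict_gap_exclusion: bool = True,
) -> int:
    """Conserved left+right alpha-adjacencies of one gene between two genomes."""
    if gene not in gu.gene_counts or gene not in gv.gene_counts:
        return 0
    total = 0
    for side in ("left", "right"):
        au = alpha_adjacencies(gu, gene, side, alpha, strict_gap_exclusion)
        av = alpha_adjacencies(gv, gene, side, alpha, strict_gap_exclusion)
        total += multiset_intersection_size(au, av)
    return total


def adj_cons_genomes(
    alpha: int,
    gu: Genome,
    gv: Genome,
    strict_gap_exclusion: bool = True,
) -> int:
    """Conserved alpha-adjacencies summed over the shared gene set (``O`` included).

    Each physically conserved junction is counted twice (once from each of
    its two flanking genes).
    """
    shared = gu.gene_set & gv.gene_set
    return sum(adj_cons_gene(g, alpha, gu, gv, strict_gap_exclusion) for g in shared)
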