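# Methods

## Model and problem

A genome is a set of chromosomes over signed genes drawn from an alphabet Σ.
Linear chromosomes are closed by an artificial telomere gene `O` (always
positive; one copy per linear chromosome) and read circularly. Gene `g`
expands to the marker pair (`g^t`, `g^h`), reversed for `-g`.

Signed gene *b* is a *left α-adjacency* of gene *a* if fewer than α markers
lie strictly between *b*'s trailing marker (`b^h` for `+b`, `b^t` for `-b`)
and `a^t`; right adjacencies mirror this from `a^h`. Occurrences carried as
`-a` are read in reverse with flipped signs, so the multisets `LA(g, α, G)`
and `RA(g, α, G)` are invariant under chromosome reversal. Two conventions
complete the definition where the formal text leaves room:

* **Strict gap exclusion** (default on): a contribution is suppressed when a
  copy of the focal or the contributed gene lies inside the gap window,
  honouring the requirement that the gap consist of *other* genes. The pure
  marker-count variant is available (`strict_gap_exclusion=False`); the two
  differ only when duplicates fall within a window.
* **Telomere stop**: a gap window never crosses `O`. The telomere itself
  contributes (through its near marker) and the scan ends there. Without this
  rule a short CAR, circularised through `O`, re-reads its own content from
  the far side once α exceeds its length, and every such phantom adjacency
  would be scored and counted as an error — at MAX_α = 50 that floods the
  error metric (~50% error for perfectly correct 20-gene CARs) and
  contradicts the intended meaning of a gap as *intra-chromosomal* proximity.

Conservation between genomes is `adjCons(g, α, Gu, Gv) = |LA∩LA| + |RA∩RA|`
(multiset intersections), summed over shared genes and over tree branches.
Each conserved junction between ordinary genes is counted twice (once per
flank); telomere junctions may count once when the flanking gene's
orientation relative to `O` differs between genomes, because `O`'s pinned
sign makes its own multisets orientation-dependent — the property tests
assert exact evenness on circular genomes, where the caveat vanishes.

## Ancestral gene content

WGD nodes have one child and carry the genome immediately before doubling.
Content assignment is two bottom-up passes. First, each WGD node receives
every gene whose maximum multiplicity among its *direct descendants*
(nearest leaf-or-WGD below) is ≥ 2, at ⌈max/2⌉ copies — the ceiling, because
a pre-duplication genome must carry enough copies to explain an odd
descendant count. Second, each gene is assigned along the paths from the LCA
of its carriers (leaves and pass-1 WGD nodes) down to every carrying leaf,
with multiplicity the maximum over children where not already set. Carriers
of every gene then form a connected subtree, and multiplicity never increases
down a branch except across a WGD (at most doubling) or a 0→1 gain.

When the input tree carries no WGD annotation, duplication nodes can be
inferred from leaf multiplicities: a leaf needs ⌈log₂ max-mult⌉ duplications
above it, and shared events are placed as high as possible (greedily, at the
root of every subtree whose leaves all still need one). Explicit `WGD` labels
in the Newick input override this.

## Scoring: clamped conservation maxima

For one gene, side and gap, `LeftAdj(g, α, S | LA(g,α,G(u)) = X)` is the
maximum conservation over all ancestral labelings with the candidate multiset
*X* (of size mult(g, u)) clamped at *u*. Leaves are clamped to the observed
multisets. On a branch out of a WGD node the parent multiset is doubled
before matching (`wgd_double_match`, default on): a duplication doubles every
adjacency, so a single pre-duplication candidate can be conserved once per
copy below.

Candidates are finitised to the signed genes observed as adjacencies of *g*
at any leaf, plus `O`, plus one wildcard ⊥ standing for every never-observed
value. The wildcard matches nothing — a candidate that no leaf exhibits can
only fill multiset slots, never add conservation — so collapsing the infinite
complement onto ⊥ preserves the maxima that drive assembly.

The maximisation decomposes over the tree: an inside table `D(u, X)` (best
conservation strictly below *u*) and an outside table `U(u, X)` (best in the
rest of the tree), combined as `total = D + U`, computed by message passing
restricted to the gene's carrier subtree. Branch maximisations use
sub-multiset dominance (`max_Y match(X, Y) + D(Y)` equals the best over
sub-multisets *T* ⊆ *X* of |T| plus the best table entry whose key contains
*T*). Two engines implement the same contract and are cross-checked against
an exhaustive maximiser over joint assignments in the test suite: a
vectorised engine for multiplicities ≤ 2 (tables are vectors/matrices over
the candidate alphabet; all messages are closed-form numpy expressions) and a
generic dictionary engine up to the complexity cap (multiplicity 4 by
default, guarded by an explicit error). Runtime per gene and side is
O(|S|·K²) for the vectorised path, with K the alphabet size (≤ α · total
leaf multiplicity), matching the published polynomial envelope across the
gap loop.

## Assembly: TSP-τ over CAR extremities

At the query node ν every gene is single-copy (ν precedes all WGDs; enforced
with an explicit error). CARs start as singleton genes. Each iteration α:

* scores are computed for the genes at CAR extremities only — joining deeper
  genes of a CAR is explicitly out of scope for the published loop;
* the junction placing signed gene *u* immediately left of *v* scores
  `L(v,u) + R(u,v)` with signs resolved through each gene's orientation
  (a flipped gene swaps which of its side-tables is consulted and negates the
  candidate), divided by `MaxAdj(u) + MaxAdj(v)`;
* `MaxAdj` here is the gene's copy count summed over tree nodes — identical
  to the node count for single-copy genes, and the scaling that keeps
  weights in [0, 1] when WGD branches can conserve an adjacency once per
  copy, so that high-multiplicity genes are not favoured;
* junctions to the single `O` vertex use the same formula with the telomere
  side contributing zero score;
* a heaviest Hamiltonian cycle over oriented CARs plus `O` is solved exactly
  (exhaustive search) up to 6 items / 12 ports, otherwise by greedy fragment
  merging followed by 2-opt and or-opt local search with seeded random
  restarts (small instances) or double-bridge kicks (large ones); the local
  optimum is verified against the exact solver on randomised instances in
  the tests;
* the tour is cut at `O` and at every junction of weight < τ; surviving runs
  concatenate (flipping CARs traversed backwards). Cutting never splits a
  CAR, so |C_α| ≤ |C_{α−1}|, asserted each iteration. The loop stops at a
  single CAR or at MAX_α.

τ = 0.70 and MAX_α = 50 by default. Sub-τ edges participate in the cycle
search and are cut afterwards; hard-excluding them from the search was
measured to leave assemblies incomplete (the tour fragments on the zero
plateau) and is not used. The literal asymmetric normalisation (divide by the
right gene's MaxAdj only) is available as `literal_normalization`.

## Simulator

`random_root(n_genes, n_chromosomes)` lays out genes 1..n in identity order
over near-equal linear chromosomes. Along each branch, losses are applied
first (order relative to rearrangements is immaterial in expectation; fixed
for reproducibility), then `r` rearrangements with `r` uniform in
[⌈rmax/2⌉, rmax]. Kinds are drawn from the Inversion : Translocation :
(Fusion+Fission) ratio — 5:4:1 in the multichromosomal and WGD protocols,
inversions only in the first protocol — with fusion/fission equiprobable
within their share and infeasible draws resampled. Inversion segment lengths
are geometric (p = 0.5, mean 2: mostly short inversions); translocations
exchange random suffixes; fusions flip one partner with probability ½. A WGD
node doubles every chromosome, followed by the configured burst of losses
(50 by default in the WGD protocol) before the branch's other events. True
genomes are retained at every node.

Fixture topologies: the six-leaf tree `((((A,B),C),(D,E)),F)` whose node
`sigma` (ancestor of A..E) is reconstructed in the non-WGD protocols, a
three-species tree under one shared WGD (the reconstructed node is the
duplication node itself), and a four-species-plus-outgroup WGD tree.

What the simulations do not emulate: gene gains (supported by content
assignment, never generated), unequal branch-specific loss profiles unless
supplied explicitly, incomplete assemblies or missing markers at the leaves,
and orthology errors — passing tests demonstrate recovery under the modeled
processes, not robustness to annotation noise in real gene orders.

## Evaluation

The pooled error rate of an inferred CAR set against a reference ancestor
counts, for every gene, side and α = 1..MAX_α, the inferred α-adjacency
elements absent from the reference's corresponding multiset (multiset
difference), divided by the total number of inferred elements; numerators and
denominators are pooled over α (nested windows weigh short-range adjacencies
at every gap), and a per-α breakdown is reported. Telomere-involving elements
are excluded on both sides: where a CAR ends is an artifact of how far
assembly got, not a prediction of a chromosome end. A junction bridging a
gene absent from the ancestral content therefore counts as an error at small
α and stops counting once the window is wide enough to span the missing gene
— the dominant error source in the WGD protocol, where the post-duplication
loss burst removes ~25% of genes from the reconstructible content.

## Study protocols and problem sizes

The acceptance runs use the published study conditions: 200-gene roots, the
six-leaf tree (single chromosome, inversions only, rmax ∈ {5..25}; or two
chromosomes, 5 losses per branch, 5:4:1 mix, rmax ∈ {5..20}) and the
three-species WGD tree (two pre-duplication chromosomes, 50 post-WGD losses,
5 per branch, rmax = 10), τ = 0.70, MAX_α = 50, at 20 replicates per
condition — enough for the means to stabilise while a full recomputation
stays around ten minutes on one core.

## Known limitations

* Each gene and side is scored independently (the published relaxation);
  cross-gene consistency of the ancestral labeling is not enforced, so
  clamped maxima can overestimate jointly achievable conservation and the
  effective keep/cut decision is sensitive to ±1 changes in integer
  conservation counts. Fragment counts after the first (direct-adjacency)
  iteration run somewhat higher than the original implementation reported,
  whose exact normalisation of τ is not published.
* On the WGD protocol the assembly tends to merge the two pre-duplication
  chromosomes at large α (leaf fusions and translocations create
  cross-chromosome gapped support), finishing slightly *below* the 2–4 CAR
  overshoot band reported for the original.
* The wildcard finitisation assumes conservation must be witnessed at some
  leaf; labelings that share a never-observed adjacency across an internal
  branch are not credited.
* Multiplicities above 4 at internal nodes (three stacked WGDs) are rejected
  rather than computed.
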