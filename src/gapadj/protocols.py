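"""The three simulation study protocols, packaged as replicate runners.

These reproduce the simulation designs used to characterise the method:

* inversion-only: six-species tree, single 200-gene chromosome at the root,
  ``r`` inversions per branch with ``r`` uniform in ``[rmax/2, rmax]`` and
  geometric segment lengths (p = 0.5); the reconstructed node is ``sigma``,
  the ancestor of the five-species ingroup.
* multichromosomal: same tree, two chromosomes, gene losses on every branch
  and a rearrangement mix Inversion : Translocation : (Fusion+Fission) of
  5 : 4 : 1.
* WGD: a three-species tree descending from one whole-genome duplication,
  with a burst of losses right after the duplication; the reconstructed node
  is the pre-duplication ancestor.

Every replicate returns the pooled gapped-adjacency error rate against the
stored true ancestor, together with CAR counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assembly import gapadj
from .evaluation import EvaluationReport, error_rate
from .phylogeny import assign_gene_content
from .simulator import CEREAL_WGD_NEWICK, SIX_LEAF_NEWICK, SimConfig, simulate

EVAL_MAX_ALPHA = 50


@dataclass
class ReplicateResult:
    final: EvaluationReport
    #: evaluation of the ancestor after the first (direct-adjacency) round
    after_alpha1: EvaluationReport | None = None


def _run(newick: str, cfg: SimConfig, node: str, seed: int, tau: float,
         max_alpha: int, record_alpha1: bool) -> ReplicateResult:
    tree = simulate(newick, cfg, seed=seed)
    assign_gene_content(tree)
    nu = tree.node(node)
    truth = nu.genome
    res = gapadj(tree, nu, tau=tau, max_alpha=max_alpha, seed=seed,
                 keep_snapshots=record_alpha1)
    final = error_rate(res.cars, truth, EVAL_MAX_ALPHA)
    first = None
    if record_alpha1 and res.snapshots:
        first = error_rate(res.snapshots[0], truth, EVAL_MAX_ALPHA)
    return ReplicateResult(final, first)


def inversion_only_replicate(rmax: int, seed: int, *, n_genes: int = 200,
                             tau: float = 0.70, max_alpha: int = 50,
                             record_alpha1: bool = False) -> ReplicateResult:
    cfg = SimConfig(n_genes=n_genes, n_chromosomes=1, rmax=rmax,
                    op_mix=(1.0, 0.0, 0.0))
    return _run(SIX_LEAF_NEWICK, cfg, "sigma", seed, tau, max_alpha,
                record_alpha1)


def multichromosomal_replicate(rmax: int, seed: int, *, n_genes: int = 200,
                               branch_losses: int = 5, tau: float = 0.70,
                               max_alpha: int = 50) -> ReplicateResult:
    cfg = SimConfig(n_genes=n_genes, n_chromosomes=2, rmax=rmax,
                    op_mix=(5.0, 4.0, 1.0), branch_losses=branch_losses)
    return _run(SIX_LEAF_NEWICK, cfg, "sigma", seed, tau, max_alpha, False)


def wgd_replicate(seed: int, *, rmax: int = 10, n_genes: int = 200,
                  wgd_losses: int = 50, branch_losses: int = 5,
                  tau: float = 0.70, max_alpha: int = 50) -> ReplicateResult:
    cfg = SimConfig(n_genes=n_genes, n_chromosomes=2, rmax=rmax,
                    op_mix=(5.0, 4.0, 1.0), branch_losses=branch_losses,
                    wgd_losses=wgd_losses)
    return _run(CEREAL_WGD_NEWICK, cfg, "WGD_cereal", seed, tau, max_alpha,
                False)


def mean(xs) -> float:
    xs = list(xs)
    return sum(xs) / len(xs)
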