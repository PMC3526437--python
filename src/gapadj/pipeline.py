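"""End-to-end orchestration: read inputs, place WGDs, assign content, assemble."""

from __future__ import annotations

import logging
from dataclasses import dataclass


from .assembly import GapAdjResult, gapadj
from .evaluation import EvaluationReport, error_rate
from .genome_model import Genome
from .phylogeny import (SpeciesTree, assign_gene_content, insert_wgd_nodes,
                        read_tree)

log = logging.getLogger("gapadj")


@dataclass
class RunConfig:
    """Parameters of one reconstruction run.

    Defaults: ``tau = 0.70`` (junction kept when conserved in roughly 70% of
    the tree) and ``max_alpha = 50`` (gaps up to 49 intervening markers).
    """

    node: str
    tau: float = 0.70
    max_alpha: int = 50
    seed: int = 0
    strict_gap_exclusion: bool = True
    wgd_double_match: bool = True
    literal_normalization: bool = False
    auto_wgd: bool = True
    keep_snapshots: bool = False

    def __post_init__(self):
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must lie in [0, 1]")
        if self.max_alpha < 1:
            raise ValueError("max_alpha must be >= 1")


@dataclass
class InferenceResult:
    tree: SpeciesTree
    result: GapAdjResult
    report: EvaluationReport | None = None

    @property
    def cars(self):
        return self.result.cars


def prepare_tree(newick_text: str, genomes: list[Genome],
                 auto_wgd: bool = True) -> SpeciesTree:
    """Read the tree, place WGD nodes if none are annotated, assign content."""
    tree = read_tree(newick_text, genomes)
    if auto_wgd and not any(n.is_wgd for n in tree.preorder()):
        insert_wgd_nodes(tree)
    assign_gene_content(tree)
    return tree


def run_infer(config: RunConfig, newick_text: str, genomes: list[Genome],
              truth: Genome | None = None) -> InferenceResult:
    """Full reconstruction at the configured node; deterministic per seed."""
    tree = prepare_tree(newick_text, genomes, config.auto_wgd)
    nu = tree.node(config.node)
    log.info("reconstructing %s: tau=%.2f max_alpha=%d seed=%d",
             nu.name, config.tau, config.max_alpha, config.seed)
    result = gapadj(
        tree, nu,
        tau=config.tau,
        max_alpha=config.max_alpha,
        seed=config.seed,
        strict_gap_exclusion=config.strict_gap_exclusion,
        wgd_double_match=config.wgd_double_match,
        literal_normalization=config.literal_normalization,
        keep_snapshots=config.keep_snapshots,
    )
    for alpha, n in result.history:
        log.info("alpha=%d: %d CARs", alpha, n)
    report = None
    if truth is not None:
        report = error_rate(result.cars, truth, config.max_alpha,
                            config.strict_gap_exclusion)
        log.info("error rate vs truth: %.4f over %d adjacencies",
                 report.error_rate, report.total)
    return InferenceResult(tree, result, report)
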