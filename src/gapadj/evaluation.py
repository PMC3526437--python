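"""Error metrics comparing inferred CAR sets with a reference ancestor.

The headline metric is the pooled gapped-adjacency error rate: over all gaps
``alpha = 1..MAX_alpha`` and all genes, the fraction of inferred
side-``alpha``-adjacencies that are absent (as multiset elements) from the
reference genome's corresponding multisets.  Telomere-involving adjacencies
are excluded from both sides: CAR ends are artifacts of where assembly
stopped, not predictions of chromosome ends.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .assembly import CAR, cars_to_genome
from .genome_model import Genome, TELOMERE, alpha_adjacency_items


@dataclass
class EvaluationReport:
    error_rate: float
    n_cars: int
    #: gap -> (errors, total inferred adjacencies) at that gap
    per_alpha: dict[int, tuple[int, int]]
    n_true_chromosomes: int

    @property
    def errors(self) -> int:
        return sum(e for e, _ in self.per_alpha.values())

    @property
    def total(self) -> int:
        return sum(t for _, t in self.per_alpha.values())


def _gap_items(genome: Genome, gene: str, side: str, max_alpha: int,
               strict: bool):
    """Non-telomeric adjacency contributions of a gene, bucketed by gap."""
    by_gap: dict[int, list] = {}
    for el, gap in alpha_adjacency_items(genome, gene, side, max_alpha, strict):
        if el.symbol != TELOMERE:
            by_gap.setdefault(gap, []).append(el)
    return by_gap


def error_rate(
    inferred: list[CAR] | Genome,
    truth: Genome,
    max_alpha: int = 50,
    strict_gap_exclusion: bool = True,
) -> EvaluationReport:
    """Pooled fraction of inferred alpha-adjacencies absent from the truth.

    Numerators and denominators are summed over ``alpha = 1..max_alpha``
    (nested windows, so near adjacencies weigh in at every gap) and over both
    sides of every inferred gene.
    """
    if isinstance(inferred, Genome):
        inf_genome = inferred
        n_cars = len(inferred.chromosomes)
    else:
        if not inferred:
            raise ValueError("empty inferred CAR set")
        inf_genome = cars_to_genome(inferred)
        n_cars = len(inferred)

    # per-alpha error counts |inf_alpha \ true_alpha| and sizes |inf_alpha|,
    # accumulated over genes and sides; window alpha admits gaps < alpha
    errors = np.zeros(max_alpha + 1, dtype=np.int64)
    totals = np.zeros(max_alpha + 1, dtype=np.int64)
    for gene in inf_genome.gene_set - {TELOMERE}:
        for side in ("left", "right"):
            inf_by_gap = _gap_items(inf_genome, gene, side, max_alpha,
                                    strict_gap_exclusion)
            true_by_gap = (
                _gap_items(truth, gene, side, max_alpha, strict_gap_exclusion)
                if gene in truth.gene_counts else {})
            c_inf: Counter = Counter()
            c_true: Counter = Counter()
            surplus = n_inf = 0
            for alpha in range(1, max_alpha + 1):
                gap = alpha - 1
                for el in true_by_gap.get(gap, ()):
                    c_true[el] += 1
                    if c_inf[el] >= c_true[el]:
                        surplus -= 1
                for el in inf_by_gap.get(gap, ()):
                    c_inf[el] += 1
                    n_inf += 1
                    if c_inf[el] > c_true[el]:
                        surplus += 1
                errors[alpha] += surplus
                totals[alpha] += n_inf
    per_alpha = {a: (int(errors[a]), int(totals[a]))
                 for a in range(1, max_alpha + 1)}
    grand_e = int(errors[1:].sum())
    grand_t = int(totals[1:].sum())
    rate = grand_e / grand_t if grand_t else 0.0
    return EvaluationReport(rate, n_cars, per_alpha, len(truth.chromosomes))


def disagreement_fraction(
    cars_a: list[CAR],
    cars_b: list[CAR],
    alpha: int,
    strict_gap_exclusion: bool = True,
) -> float:
    """Fraction of A's alpha-adjacency elements absent from B's (one gap)."""
    ga, gb = cars_to_genome(cars_a, "A"), cars_to_genome(cars_b, "B")
    missing = total = 0
    for gene in ga.gene_set - {TELOMERE}:
        for side in ("left", "right"):
            ca = Counter(el for el, _ in alpha_adjacency_items(
                ga, gene, side, alpha, strict_gap_exclusion)
                if el.symbol != TELOMERE)
            cb = (Counter(el for el, _ in alpha_adjacency_items(
                gb, gene, side, alpha, strict_gap_exclusion)
                if el.symbol != TELOMERE)
                if gene in gb.gene_counts else Counter())
            total += sum(ca.values())
            missing += sum(max(0, c - cb[el]) for el, c in ca.items())
    return missing / total if total else 0.0


def summarize(reports: list[EvaluationReport]):
    """Mean and standard error of the headline metrics across replicates."""
    import pandas as pd

    if not reports:
        raise ValueError("need at least one replicate")
    df = pd.DataFrame({
        "error_rate": [r.error_rate for r in reports],
        "n_cars": [r.n_cars for r in reports],
        "n_true_chromosomes": [r.n_true_chromosomes for r in reports],
    })
    out = df.agg(["mean", "sem"]).T
    out.columns = ["mean", "se"]
    return out.fillna(0.0)
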