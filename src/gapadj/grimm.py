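"""GRIMM-style gene-order files and tabular exports.

Format: a line ``>name`` opens a genome; each following non-empty line is one
chromosome given as whitespace-separated signed gene tokens terminated by
``$`` (linear) or ``@`` (circular).  ``#`` starts a comment.  The token ``O``
is reserved for the artificial telomere and may not appear in input.
"""

from __future__ import annotations

from pathlib import Path

from .assembly import CAR
from .genome_model import Chromosome, Genome, TELOMERE, sg


class FormatError(ValueError):
    pass


def parse_genomes(text: str) -> list[Genome]:
    genomes: list[Genome] = []
    name: str | None = None
    chroms: list[Chromosome] = []
    seen: set[str] = set()

    def flush():
        nonlocal name, chroms
        if name is not None:
            if not chroms:
                raise FormatError(f"genome {name!r} has no chromosomes")
            genomes.append(Genome(name, tuple(chroms)))
        name, chroms = None, []

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise FormatError(f"line {lineno}: empty genome name")
            if name in seen:
                raise FormatError(f"line {lineno}: duplicate genome name {name!r}")
            seen.add(name)
            continue
        if name is None:
            raise FormatError(f"line {lineno}: chromosome before any '>' header")
        tokens = line.split()
        end = tokens[-1]
        if end not in ("$", "@"):
            raise FormatError(f"line {lineno}: chromosome must end with '$' or '@'")
        body = tokens[:-1]
        if not body:
            raise FormatError(f"line {lineno}: empty chromosome")
        genes = []
        for tok in body:
            g = sg(tok)
            if g.symbol == TELOMERE:
                raise FormatError(
                    f"line {lineno}: reserved telomere symbol {TELOMERE!r}")
            genes.append(g)
        chroms.append(Chromosome(tuple(genes), circular=(end == "@")))
    flush()
    return genomes


def read_genomes(path: str | Path) -> list[Genome]:
    return parse_genomes(Path(path).read_text())


def format_genomes(genomes: list[Genome]) -> str:
    lines = []
    for g in genomes:
        lines.append(f">{g.name}")
        for c in g.chromosomes:
            end = "@" if c.circular else "$"
            lines.append(" ".join(str(x) for x in c.genes) + f" {end}")
    return "\n".join(lines) + "\n"


def write_genomes(genomes: list[Genome], path: str | Path) -> None:
    Path(path).write_text(format_genomes(genomes))


def format_cars(cars: list[CAR]) -> str:
    """CARs in the same dialect, one linear chromosome per CAR."""
    lines = [" ".join(str(g) for g in c.genes) + " $" for c in cars]
    return "\n".join(lines) + "\n"


def write_cars(cars: list[CAR], path: str | Path) -> None:
    Path(path).write_text(format_cars(cars))


def parse_cars(text: str) -> list[CAR]:
    g = parse_genomes(">cars\n" + text)[0]
    return [CAR(c.genes, i) for i, c in enumerate(g.chromosomes)]


def read_cars(path: str | Path) -> list[CAR]:
    return parse_cars(Path(path).read_text())
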