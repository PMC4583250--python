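"""Circular mitochondrial genome and gene model.

Coordinates throughout the package are 1-based, fully inclusive, on the
heavy strand of the circular genome (GenBank convention for the rCRS).
A gene whose ``end`` is smaller than its ``start`` spans the replication
origin and wraps around position 1.

Gene lengths come in two flavours that must not be confused:

``printed_length``
    The length carried verbatim in the gene table.  It is the denominator
    of the enrichment statistics and is *never* recomputed from
    coordinates (published per-gene lengths differ slightly from the
    coordinate spans of the standard annotation).
``span_length``
    ``end − start + 1`` with circular wrap-around; used only for interval
    logic and codon arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pandas as pd

from .errors import ParseError, ValidationError

BIOTYPES = ("protein_coding", "Mt_rRNA", "Mt_tRNA", "other")
STRANDS = ("+", "-")

_SEQ_RE = re.compile(r"^[ACGTN]*$")

#: Standard human mitochondrial genome length in bp (rCRS).
RCRS_LENGTH = 16569


@dataclass(frozen=True)
class MitoGenome:
    """A (usually circular) mitochondrial reference genome.

    The nucleotide sequence is optional: coordinate and length logic works
    without it, sequence-dependent annotation (codons, homopolymers)
    requires it.
    """

    name: str
    length: int
    circular: bool = True
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"genome length must be positive, got {self.length}")
        if self.sequence is not None:
            seq = self.sequence.upper()
            object.__setattr__(self, "sequence", seq)
            if len(seq) != self.length:
                raise ValidationError(
                    f"sequence length {len(seq)} != declared length {self.length}"
                )
            if not _SEQ_RE.match(seq):
                raise ValidationError("sequence contains characters outside A/C/G/T/N")

    def base(self, position: int) -> str:
        """Return the heavy-strand base at a 1-based position."""
        if self.sequence is None:
            raise ValidationError(f"genome {self.name!r} carries no sequence")
        self.check_position(position)
        return self.sequence[position - 1]

    def check_position(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise ValidationError(
                f"position {position} outside genome [1, {self.length}]"
            )

    def wrap(self, position: int) -> int:
        """Map any integer offset onto [1, length] (circular arithmetic)."""
        return (position - 1) % self.length + 1


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene on the circular genome.

    ``end < start`` is permitted only for features spanning the origin.
    """

    symbol: str
    biotype: str
    start: int
    end: int
    strand: str
    printed_length: int

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.symbol}: unknown biotype {self.biotype!r}; expected one of {BIOTYPES}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"{self.symbol}: strand must be '+' or '-'")
        if self.printed_length <= 0:
            raise ValidationError(f"{self.symbol}: printed_length must be > 0")
        if self.start <= 0 or self.end <= 0:
            raise ValidationError(f"{self.symbol}: coordinates must be positive")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start

    def span_length(self, genome_length: int) -> int:
        """Coordinate-derived length, respecting circular wrap-around."""
        if self.wraps_origin:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.wraps_origin:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def offset_of(self, position: int, genome_length: int) -> int:
        """0-based heavy-strand offset of ``position`` within the gene."""
        if not self.contains(position):
            raise ValidationError(f"position {position} not inside {self.symbol}")
        if self.wraps_origin and position <= self.end:
            return genome_length - self.start + 1 + position - 1
        return position - self.start

    def position_at(self, offset: int, genome_length: int) -> int:
        """Genomic position of the 0-based heavy-strand offset (inverse of offset_of)."""
        if not 0 <= offset < self.span_length(genome_length):
            raise ValidationError(f"offset {offset} outside {self.symbol}")
        return (self.start - 1 + offset) % genome_length + 1


@dataclass
class MitoGeneModel:
    """An ordered gene annotation over one genome.

    Overlapping genes are expected (mtDNA has overlapping ORFs);
    :meth:`locate` returns *all* genes covering a position.
    """

    genome: MitoGenome
    genes: Sequence[GeneRecord] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        dupes = {s for s in symbols if symbols.count(s) > 1}
        if dupes:
            raise ValidationError(f"duplicate gene symbols: {sorted(dupes)}")
        for g in self.genes:
            for pos in (g.start, g.end):
                if pos > self.genome.length:
                    raise ValidationError(
                        f"{g.symbol}: coordinate {pos} outside genome "
                        f"[1, {self.genome.length}]"
                    )
        self.genes = tuple(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, symbol: str) -> GeneRecord:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    @property
    def symbols(self) -> tuple:
        return tuple(g.symbol for g in self.genes)

    def locate(self, position: int) -> tuple:
        """All genes whose interval covers ``position`` (empty ⇒ intergenic)."""
        self.genome.check_position(position)
        return tuple(g for g in self.genes if g.contains(position))


_REQUIRED_COLUMNS = ("symbol", "biotype", "start", "end", "strand", "length")


def load_gene_model(
    gene_table: Union[str, Path], genome: MitoGenome
) -> MitoGeneModel:
    """Load a gene model from a tab-separated table.

    The table must carry a header with at least the columns
    ``symbol biotype start end strand length``; extra columns are ignored.
    The ``length`` column is taken verbatim as ``printed_length``.
    Lines starting with ``#`` are comments.
    """
    path = Path(gene_table)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse gene table: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    records = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            rec = GeneRecord(
                symbol=str(row["symbol"]).strip(),
                biotype=str(row["biotype"]).strip(),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]).strip(),
                printed_length=int(row["length"]),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}, line {line_no}: malformed row ({exc})") from exc
        records.append(rec)
    return MitoGeneModel(genome=genome, genes=records)


def bundled_gene_model(sequence: Optional[str] = None) -> MitoGeneModel:
    """The packaged 15-gene human mtDNA model (standard rCRS coordinates,
    published per-gene lengths carried verbatim in ``printed_length``)."""
    genome = MitoGenome(name="rCRS", length=RCRS_LENGTH, circular=True, sequence=sequence)
    with resources.as_file(
        resources.files("mitoburden.data") / "gene_model.tsv"
    ) as p:
        return load_gene_model(p, genome)
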