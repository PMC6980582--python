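"""Core domain types shared across the toolkit.

All genomic coordinates are 0-based half-open ``[start, end)``. Conversion
from 1-based inclusive conventions (GFF3, RepeatMasker .out) happens only at
the I/O boundary (:mod:`tegenomics.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = frozenset({"+", "-", "."})


class ParseError(ValueError):
    """A file failed to parse; carries the path and 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class SchemaError(ValueError):
    """A tabular input does not match its declared schema."""


class ConfigError(ValueError):
    """A configuration value is invalid or geometrically unsatisfiable."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("SequenceRecord id must be nonempty")
        if not self.seq:
            raise ValueError(f"SequenceRecord {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene with its span and exon/CDS structure.

    Exons must be sorted and non-overlapping; every CDS segment must lie
    within the union of the exons.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted "
                    f"([{prev.start},{prev.end}) then [{cur.start},{cur.end}))"
                )
        for seg in self.cds:
            if not any(
                seg.start >= e.start and seg.end <= e.end for e in self.exons
            ):
                raise ValueError(
                    f"gene {self.gene_id}: CDS [{seg.start},{seg.end}) "
                    "not contained in any exon"
                )

    @property
    def cds_length(self) -> int:
        return sum(seg.length for seg in self.cds)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons (empty for single-exon genes)."""
        out = []
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start > prev.end:
                out.append(
                    GenomicInterval(
                        self.interval.scaffold, prev.end, cur.start, self.interval.strand
                    )
                )
        return out


@dataclass(frozen=True)
class RepeatHit:
    """One masked repeat interval with family and class labels."""

    interval: GenomicInterval
    family: str
    repeat_class: str = "Unknown"

    def __post_init__(self):
        if not self.family:
            raise ValueError("repeat family must be nonempty")

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def superfamily(self) -> str:
        """Part after '/' in the class label (e.g. 'Gypsy' of 'LTR/Gypsy')."""
        if "/" in self.repeat_class:
            return self.repeat_class.split("/", 1)[1]
        return self.repeat_class
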