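"""Readers and writers for FASTA, GFF3, repeat annotations and typed TSV tables.

Coordinate conventions: GFF3 and RepeatMasker .out files are 1-based
inclusive on disk and converted to 0-based half-open internally; the BED-like
repeat dialect and all internal structures are 0-based half-open.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .models import (
    GeneModel,
    GenomicInterval,
    ParseError,
    RepeatHit,
    SchemaError,
    SequenceRecord,
)

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

# A hand-rolled parser (rather than Bio.SeqIO) so that malformed input can be
# reported with exact line numbers, which the contract requires.


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; whitespace inside sequences is stripped. Raises
    :class:`ParseError` (with line number) on malformed headers or empty
    sequences.
    """
    path = str(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int):
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"record {header!r} has no sequence", path, header_line)
        records.append(SequenceRecord(header, seq))
        header, chunks = None, []

    i = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError("empty FASTA header", path, i)
                header = name
                header_line = i
            else:
                if header is None:
                    raise ParseError("sequence data before any header", path, i)
                chunks.append(re.sub(r"\s+", "", line))
        flush(i)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/exon/CDS subset)
# ---------------------------------------------------------------------------


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    Only ``gene``/``mRNA``/``exon``/``CDS`` features are used; others are
    ignored. 1-based inclusive coordinates are converted to 0-based
    half-open. When a gene has several mRNAs the one with the longest total
    CDS is kept. A gene with CDS but no exons gets its CDS reused as exons.
    """
    path = str(path)
    genes: dict[str, tuple[GenomicInterval, int]] = {}
    mrna_parent: dict[str, str] = {}
    children: dict[str, dict[str, list[GenomicInterval]]] = {}
    order: list[str] = []

    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"expected 9 tab-separated fields, got {len(fields)}", path, i)
            scaffold, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
            if ftype not in ("gene", "mRNA", "exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"non-numeric coordinates {start_s!r}/{end_s!r}", path, i)
            iv = GenomicInterval(scaffold, start1 - 1, end1, strand if strand in "+-" else ".")
            attrs = _parse_gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise ParseError("gene feature without ID attribute", path, i)
                if gid in genes:
                    raise ParseError(f"duplicate gene ID {gid!r}", path, i)
                genes[gid] = (iv, i)
                order.append(gid)
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if not mid or not parent:
                    raise ParseError("mRNA feature missing ID or Parent", path, i)
                mrna_parent[mid] = parent
                children.setdefault(mid, {"exon": [], "CDS": []})
            else:
                parent = attrs.get("Parent")
                if not parent:
                    raise ParseError(f"{ftype} feature without Parent", path, i)
                children.setdefault(parent, {"exon": [], "CDS": []})[ftype].append(iv)

    # resolve parents: children may point at an mRNA or directly at a gene
    per_gene: dict[str, list[dict[str, list[GenomicInterval]]]] = {g: [] for g in genes}
    for parent, feats in children.items():
        gid = mrna_parent.get(parent, parent)
        if gid not in genes:
            raise ParseError(
                f"exon/CDS parent {parent!r} does not resolve to a known gene", path
            )
        per_gene[gid].append(feats)

    models: list[GeneModel] = []
    for gid in order:
        iv, line_no = genes[gid]
        variants = per_gene[gid] or [{"exon": [], "CDS": []}]
        best = max(variants, key=lambda f: sum(s.length for s in f["CDS"]))
        exons = sorted(best["exon"], key=lambda e: e.start)
        cds = sorted(best["CDS"], key=lambda c: c.start)
        if not exons and cds:
            exons = list(cds)
        for prev, cur in zip(exons, exons[1:]):
            if cur.start < prev.end:
                raise ParseError(f"gene {gid!r}: overlapping exons", path, line_no)
        models.append(GeneModel(gid, iv, exons=exons, cds=cds))
    return models


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (one mRNA per gene), 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            strand = iv.strand if iv.strand in "+-" else "."
            base = f"{iv.scaffold}\ttegenomics\t"
            fh.write(f"{base}gene\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{base}mRNA\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\tID={mid};Parent={g.gene_id}\n")
            for e in g.exons:
                fh.write(f"{base}exon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\tParent={mid}\n")
            for c in g.cds:
                fh.write(f"{base}CDS\t{c.start + 1}\t{c.end}\t.\t{strand}\t0\tParent={mid}\n")


# ---------------------------------------------------------------------------
# Repeat annotations: RepeatMasker .out and BED-like TSV dialects
# ---------------------------------------------------------------------------


def read_repeatmasker_out(path: str | Path) -> list[RepeatHit]:
    """Read a standard RepeatMasker ``.out`` file.

    The first three lines (two header lines plus a blank) are skipped;
    1-based inclusive query coordinates become 0-based half-open. A strand
    of ``C`` (complement) maps to ``-``.
    """
    path = str(path)
    hits: list[RepeatHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        first = stripped.split()[0]
        if first in ("SW", "score"):  # header rows
            continue
        fields = stripped.split()
        if len(fields) < 11:
            raise ParseError(f"expected >= 11 columns, got {len(fields)}", path, i)
        try:
            begin1, end1 = int(fields[5]), int(fields[6])
        except ValueError:
            raise ParseError(f"non-numeric begin/end {fields[5]!r}/{fields[6]!r}", path, i)
        strand = "-" if fields[8] == "C" else "+"
        hits.append(
            RepeatHit(
                interval=GenomicInterval(fields[4], begin1 - 1, end1, strand),
                family=fields[9],
                repeat_class=fields[10],
            )
        )
    return hits


def read_repeats_bed(path: str | Path) -> list[RepeatHit]:
    """Read the 6-column BED-like repeat dialect.

    Columns: scaffold, start, end, family, class, strand — 0-based half-open,
    tab-separated, no header.
    """
    path = str(path)
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"expected 6 columns, got {len(fields)}", path, i)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"non-numeric start/end {fields[1]!r}/{fields[2]!r}", path, i)
            hits.append(
                RepeatHit(
                    interval=GenomicInterval(fields[0], start, end, fields[5] or "."),
                    family=fields[3],
                    repeat_class=fields[4],
                )
            )
    return hits


def write_repeats_bed(hits: list[RepeatHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            iv = h.interval
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{h.family}\t{h.repeat_class}\t{iv.strand}\n"
            )


def read_repeats(path: str | Path, dialect: str = "bed") -> list[RepeatHit]:
    """Dispatch on the declared repeat-annotation dialect ('bed' or 'rmout')."""
    if dialect == "bed":
        return read_repeats_bed(path)
    if dialect == "rmout":
        return read_repeatmasker_out(path)
    raise ValueError(f"unknown repeat dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Typed TSV tables
# ---------------------------------------------------------------------------

MISSING = "."


@dataclass(frozen=True)
class Column:
    """One column of a :class:`TableSchema`."""

    name: str
    kind: str = "str"  # str | int | float
    required: bool = True
    default: object = None
    allowed: frozenset | None = None


@dataclass(frozen=True)
class TableSchema:
    columns: tuple[Column, ...]
    key: str = "gene_id"

    def column(self, name: str) -> Column:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)


_CASTERS = {"str": str, "int": int, "float": float}


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a TSV with a header row against *schema*.

    Missing optional columns are filled with their defaults; '.' marks a
    missing value and maps to the column default. Raises
    :class:`SchemaError` on missing mandatory columns, duplicate keys, type
    failures, or disallowed values.
    """
    path = str(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    names = {c.name for c in schema.columns}
    for col in schema.columns:
        if col.name not in df.columns:
            if col.required:
                raise SchemaError(f"{path}: missing mandatory column {col.name!r}")
            df[col.name] = MISSING
    extra = [c for c in df.columns if c not in names]
    if extra:
        df = df.drop(columns=extra)

    for col in schema.columns:
        caster = _CASTERS[col.kind]

        def convert(v, col=col, caster=caster):
            if v == MISSING or v == "":
                if col.default is None and col.required:
                    raise SchemaError(f"{path}: missing value in mandatory column {col.name!r}")
                return col.default
            try:
                out = caster(v)
            except ValueError:
                raise SchemaError(f"{path}: cannot cast {v!r} to {col.kind} in column {col.name!r}")
            if col.allowed is not None and out not in col.allowed:
                raise SchemaError(f"{path}: value {out!r} not allowed in column {col.name!r}")
            return out

        df[col.name] = df[col.name].map(convert)

    if schema.key in df.columns and df[schema.key].duplicated().any():
        dups = df.loc[df[schema.key].duplicated(), schema.key].tolist()
        raise SchemaError(f"{path}: duplicate {schema.key} values: {dups[:5]}")
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)
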