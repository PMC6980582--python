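"""Assembly and gene-model summary statistics.

Covers total length / N50 / GC (overall and coding-vs-noncoding
partition), gene density and percent coding, exon/intron profiles, the
complete-CDS filter (start codon, stop codon, no internal stop) and the
per-gene intergenic-distance profile.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import GeneModel, SequenceRecord
from .reports import pct, round_half_up

STOP_CODONS = {"TAA", "TAG", "TGA"}
_GC = frozenset("GCgc")
_ACGT = frozenset("ACGTacgt")


def _gc_fraction(gc: int, acgt: int) -> float | None:
    return None if acgt == 0 else 100.0 * gc / acgt


@dataclass(frozen=True)
class AssemblyStats:
    total_length: int
    n_sequences: int
    n50: int
    gc_overall: float


@dataclass(frozen=True)
class GeneStats:
    n_genes: int
    gene_density_per_mbp: float
    percent_coding: float
    mean_cds_length: float
    n_exons: int
    n_introns: int
    mean_exon_length: float | None
    mean_intron_length: float | None
    median_exons_per_gene: int
    median_introns_per_gene: int


def n50(lengths: list[int]) -> int:
    """Smallest length L such that sequences >= L cover half the total."""
    if not lengths:
        raise ValueError("n50 of empty length set")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")


def gc_content(sequences: list[SequenceRecord]) -> float | None:
    """GC percentage over A/C/G/T bases only; N and ambiguity codes are
    excluded from the denominator."""
    gc = acgt = 0
    for rec in sequences:
        for ch in rec.seq:
            if ch in _ACGT:
                acgt += 1
                if ch in _GC:
                    gc += 1
    return _gc_fraction(gc, acgt)


def assembly_stats(sequences: list[SequenceRecord]) -> AssemblyStats:
    if not sequences:
        raise ValueError("assembly_stats of empty sequence set")
    lengths = [len(rec) for rec in sequences]
    return AssemblyStats(
        total_length=sum(lengths),
        n_sequences=len(sequences),
        n50=n50(lengths),
        gc_overall=gc_content(sequences),
    )


def partitioned_gc(
    sequences: list[SequenceRecord], genes: list[GeneModel]
) -> tuple[float | None, float | None]:
    """(coding GC%, noncoding GC%) where coding is the union of CDS intervals.

    Either value is None when its partition holds no unambiguous base.
    """
    by_name = {rec.id: rec.seq for rec in sequences}
    masks: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        for seg in g.cds:
            if seg.scaffold not in by_name:
                raise ValueError(f"CDS on unknown scaffold {seg.scaffold!r}")
            if seg.end > len(by_name[seg.scaffold]):
                raise ValueError(
                    f"CDS [{seg.start},{seg.end}) out of bounds on {seg.scaffold!r}"
                )
            masks.setdefault(seg.scaffold, []).append((seg.start, seg.end))

    counts = {"coding": [0, 0], "noncoding": [0, 0]}  # [gc, acgt]
    for name, seq in by_name.items():
        merged = merge_intervals(masks.get(name, []))
        pos = 0
        for start, end in merged + [(len(seq), len(seq))]:
            _tally(seq, pos, start, counts["noncoding"])
            _tally(seq, start, end, counts["coding"])
            pos = end
    return (
        _gc_fraction(*counts["coding"]),
        _gc_fraction(*counts["noncoding"]),
    )


def _tally(seq: str, start: int, end: int, acc: list[int]) -> None:
    for ch in seq[start:end]:
        if ch in _ACGT:
            acc[1] += 1
            if ch in _GC:
                acc[0] += 1


def merge_intervals(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open integer intervals, sorted and non-overlapping."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(pairs):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def _lower_median(values: list[int]) -> int:
    """Median; for even counts the lower of the two central values."""
    if not values:
        return 0
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def gene_stats(genes: list[GeneModel], total_length: int) -> GeneStats:
    """Gene-model summary against an assembly of *total_length* bp.

    percent_coding uses the union of all CDS intervals so that a base
    covered by two genes counts once; mean_cds_length is the per-gene mean
    of summed CDS segments.
    """
    n_genes = len(genes)
    cds_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        for seg in g.cds:
            cds_by_scaffold.setdefault(seg.scaffold, []).append((seg.start, seg.end))
    coding_bp = sum(
        end - start
        for pairs in cds_by_scaffold.values()
        for start, end in merge_intervals(pairs)
    )

    exon_lengths = [e.length for g in genes for e in g.exons]
    intron_lengths = [i.length for g in genes for i in g.introns]
    cds_lengths = [g.cds_length for g in genes]

    return GeneStats(
        n_genes=n_genes,
        gene_density_per_mbp=n_genes / (total_length / 1e6) if total_length else 0.0,
        percent_coding=pct(coding_bp, total_length, ndigits=2) if total_length else 0.0,
        mean_cds_length=(sum(cds_lengths) / n_genes) if n_genes else 0.0,
        n_exons=len(exon_lengths),
        n_introns=len(intron_lengths),
        mean_exon_length=(sum(exon_lengths) / len(exon_lengths)) if exon_lengths else None,
        mean_intron_length=(sum(intron_lengths) / len(intron_lengths)) if intron_lengths else None,
        median_exons_per_gene=_lower_median([len(g.exons) for g in genes]),
        median_introns_per_gene=_lower_median([len(g.introns) for g in genes]),
    )


def is_complete_cds(seq: str) -> bool:
    """Complete iff length is a codon multiple, starts with ATG, ends with a
    stop codon, and has no in-frame internal stop. Raises on non-ACGTN
    characters."""
    up = seq.upper()
    bad = set(up) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in CDS: {sorted(bad)}")
    if len(up) % 3 != 0 or len(up) < 6:
        return False
    if up[:3] != "ATG" or up[-3:] not in STOP_CODONS:
        return False
    for i in range(3, len(up) - 3, 3):
        if up[i : i + 3] in STOP_CODONS:
            return False
    return True


def filter_complete_cds(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Subset of *records* passing :func:`is_complete_cds`."""
    return [rec for rec in records if is_complete_cds(rec.seq)]


@dataclass(frozen=True)
class IntergenicRecord:
    """Distances from one gene to its neighbors (left/right of the span,
    strand-agnostic)."""

    gene_id: str
    five_prime_bp: int
    three_prime_bp: int
    five_truncated: bool
    three_truncated: bool
    five_overlap: bool
    three_overlap: bool


def intergenic_distances(
    genes: list[GeneModel], scaffold_lengths: dict[str, int]
) -> list[IntergenicRecord]:
    """Per-gene distance to the nearest neighboring gene on each side.

    Sides with no neighbor report the distance to the scaffold end and are
    flagged truncated; overlapping neighbors give distance 0 with an
    overlap flag.
    """
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.interval.scaffold, []).append(g)

    out: list[IntergenicRecord] = []
    for scaffold, group in by_scaffold.items():
        if scaffold not in scaffold_lengths:
            raise ValueError(f"no length known for scaffold {scaffold!r}")
        slen = scaffold_lengths[scaffold]
        group = sorted(group, key=lambda g: (g.interval.start, g.interval.end))
        for i, g in enumerate(group):
            if i > 0:
                prev = group[i - 1]
                left = max(0, g.interval.start - prev.interval.end)
                left_overlap = prev.interval.end > g.interval.start
                left_trunc = False
            else:
                left, left_overlap, left_trunc = g.interval.start, False, True
            if i + 1 < len(group):
                nxt = group[i + 1]
                right = max(0, nxt.interval.start - g.interval.end)
                right_overlap = g.interval.end > nxt.interval.start
                right_trunc = False
            else:
                right, right_overlap, right_trunc = slen - g.interval.end, False, True
            out.append(
                IntergenicRecord(
                    g.gene_id, left, right, left_trunc, right_trunc,
                    left_overlap, right_overlap,
                )
            )
    return out


def table1_report(
    sequences: list[SequenceRecord], genes: list[GeneModel]
) -> dict:
    """Assembly + gene statistics as one flat report dict."""
    asm = assembly_stats(sequences)
    gs = gene_stats(genes, asm.total_length)
    gc_cod, gc_non = partitioned_gc(sequences, genes)
    fmt = lambda v, nd=2: None if v is None else round_half_up(v, nd)
    return {
        "total_scaffold_length_bp": asm.total_length,
        "number_of_scaffolds": asm.n_sequences,
        "n50_scaffold_length_bp": asm.n50,
        "gc_overall_pct": fmt(asm.gc_overall),
        "gc_coding_pct": fmt(gc_cod),
        "gc_noncoding_pct": fmt(gc_non),
        "predicted_genes": gs.n_genes,
        "percent_coding": gs.percent_coding,
        "average_cds_size_nt": fmt(gs.mean_cds_length),
        "gene_density_per_mbp": fmt(gs.gene_density_per_mbp),
        "total_exons": gs.n_exons,
        "total_introns": gs.n_introns,
        "average_exon_length_nt": fmt(gs.mean_exon_length),
        "average_intron_length_nt": fmt(gs.mean_intron_length),
        "median_exons_per_gene": gs.median_exons_per_gene,
        "median_introns_per_gene": gs.median_introns_per_gene,
    }
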