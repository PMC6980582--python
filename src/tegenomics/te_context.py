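"""Detection of TE-surrounded genes and their silencing association.

A gene is TE-surrounded when each flank window (default 1000 bp, truncated
at scaffold edges) intersects at least one repeat longer than the length
cutoff (default strictly > 400 bp). Qualification is by interval
intersection, so a repeat overlapping the gene body counts for any flank
window it reaches; upstream/downstream are taken strand-agnostically as
left/right of the gene span.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import pandas as pd

from .expression import fisher_exact_two_sided, is_expressed, is_silent_zero, STAGES
from .models import GeneModel, RepeatHit
from .reports import pct

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000
DEFAULT_MIN_LEN = 400


class RepeatIndex:
    """Per-scaffold repeat intervals sorted by start, for window queries."""

    def __init__(self, repeats: list[RepeatHit]):
        self._by_scaffold: dict[str, list[RepeatHit]] = {}
        for hit in repeats:
            self._by_scaffold.setdefault(hit.interval.scaffold, []).append(hit)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for name, hits in self._by_scaffold.items():
            hits.sort(key=lambda h: (h.interval.start, h.interval.end))
            self._starts[name] = [h.interval.start for h in hits]
            self._max_len[name] = max(h.length for h in hits)

    def scaffolds(self) -> set[str]:
        return set(self._by_scaffold)

    def overlapping(self, scaffold: str, start: int, end: int) -> list[RepeatHit]:
        """All repeats intersecting the half-open window [start, end)."""
        if end <= start or scaffold not in self._by_scaffold:
            return []
        hits = self._by_scaffold[scaffold]
        starts = self._starts[scaffold]
        # any overlapping hit starts in [start - max_len, end)
        lo = bisect_right(starts, start - self._max_len[scaffold] - 1)
        hi = bisect_right(starts, end - 1)
        return [h for h in hits[lo:hi] if h.interval.end > start and h.interval.start < end]


@dataclass(frozen=True)
class FlankReport:
    gene_id: str
    left_hits: tuple[tuple[RepeatHit, int], ...]
    right_hits: tuple[tuple[RepeatHit, int], ...]
    left_truncated: bool
    right_truncated: bool

    @property
    def is_te_surrounded(self) -> bool:
        return bool(self.left_hits) and bool(self.right_hits)


def flanking_repeats(
    gene: GeneModel,
    index: RepeatIndex,
    window: int = DEFAULT_WINDOW,
    min_len: int = DEFAULT_MIN_LEN,
    scaffold_length: int | None = None,
) -> FlankReport:
    """Qualifying repeats (length strictly > *min_len*) in each flank window.

    The left window is ``[gene.start - window, gene.start)`` and the right
    window ``[gene.end, gene.end + window)``, each clipped to the scaffold
    and flagged truncated when clipping occurred. Distance is the edge-to-
    edge gap to the gene span, 0 for overlap.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    iv = gene.interval
    if iv.scaffold not in index.scaffolds():
        log.warning("gene %s: scaffold %s has no repeats", gene.gene_id, iv.scaffold)

    left_start = max(0, iv.start - window)
    left_trunc = iv.start - window < 0
    left = [
        (h, max(0, iv.start - h.interval.end))
        for h in index.overlapping(iv.scaffold, left_start, iv.start)
        if h.length > min_len
    ]

    right_end = iv.end + window
    right_trunc = False
    if scaffold_length is not None and right_end > scaffold_length:
        right_end = scaffold_length
        right_trunc = True
    right = [
        (h, max(0, h.interval.start - iv.end))
        for h in index.overlapping(iv.scaffold, iv.end, right_end)
        if h.length > min_len
    ]
    return FlankReport(gene.gene_id, tuple(left), tuple(right), left_trunc, right_trunc)


def classify_te_surrounded(
    genes: list[GeneModel],
    repeats: list[RepeatHit],
    window: int = DEFAULT_WINDOW,
    min_len: int = DEFAULT_MIN_LEN,
    scaffold_lengths: dict[str, int] | None = None,
) -> tuple[set[str], list[FlankReport]]:
    """TE-surrounded gene ids (both flanks hit) plus per-gene flank reports."""
    index = RepeatIndex(repeats)
    reports = [
        flanking_repeats(
            g, index, window, min_len,
            (scaffold_lengths or {}).get(g.interval.scaffold),
        )
        for g in genes
    ]
    surrounded = {r.gene_id for r in reports if r.is_te_surrounded}
    return surrounded, reports


@dataclass(frozen=True)
class TeContextResult:
    te_surrounded: frozenset[str]
    n_te_surrounded: int
    n_silent_among: int
    pct_silent_among: float
    n_background: int
    n_silent_background: int
    background_silent_pct: float
    fisher_p: float

    def summary(self) -> dict:
        return {
            "n_te_surrounded": self.n_te_surrounded,
            "n_silent_among": self.n_silent_among,
            "pct_silent_among": self.pct_silent_among,
            "n_background": self.n_background,
            "n_silent_background": self.n_silent_background,
            "background_silent_pct": self.background_silent_pct,
            "fisher_p": self.fisher_p,
        }


def suppression_association(
    te_surrounded: set[str],
    expression: pd.DataFrame,
    threshold: float = 1.0,
    silent_rule: str = "not_expressed",
) -> TeContextResult:
    """Association between TE context and transcriptional silencing.

    *silent_rule* is ``not_expressed`` (no stage strictly above the FPKM
    threshold; the default) or ``zero`` (exactly 0 FPKM at every stage).
    Reports silent counts and one-decimal percentages inside and outside
    the TE-surrounded set, plus a two-sided Fisher exact p-value for the
    2x2 TE-surrounded x silent table.
    """
    if silent_rule not in ("not_expressed", "zero"):
        raise ValueError(f"unknown silent_rule {silent_rule!r}")
    known = set(expression["gene_id"])
    missing = sorted(te_surrounded - known)
    if missing:
        raise ValueError(f"genes missing from expression table: {missing[:10]}")

    def silent(values) -> bool:
        if silent_rule == "zero":
            return is_silent_zero(values)
        return not is_expressed(values, threshold)

    fpkm_cols = list(STAGES)
    in_silent = in_total = out_silent = out_total = 0
    for row in expression.itertuples(index=False):
        s = silent([getattr(row, c) for c in fpkm_cols])
        if row.gene_id in te_surrounded:
            in_total += 1
            in_silent += s
        else:
            out_total += 1
            out_silent += s

    p = fisher_exact_two_sided(
        in_silent, in_total - in_silent, out_silent, out_total - out_silent
    )
    return TeContextResult(
        te_surrounded=frozenset(te_surrounded),
        n_te_surrounded=in_total,
        n_silent_among=in_silent,
        pct_silent_among=pct(in_silent, in_total) if in_total else 0.0,
        n_background=out_total,
        n_silent_background=out_silent,
        background_silent_pct=pct(out_silent, out_total) if out_total else 0.0,
        fisher_p=p,
    )


@dataclass(frozen=True)
class RescueResult:
    n_silent: int
    paralog_rescued: frozenset[str]
    ortholog_conserved: frozenset[str]

    def summary(self) -> dict:
        n = self.n_silent
        return {
            "n_silent": n,
            "n_paralog_rescued": len(self.paralog_rescued),
            "pct_paralog_rescued": pct(len(self.paralog_rescued), n) if n else 0.0,
            "n_ortholog_conserved": len(self.ortholog_conserved),
            "pct_ortholog_conserved": pct(len(self.ortholog_conserved), n) if n else 0.0,
        }


def rescue_evidence(
    silent_te_genes: set[str],
    te_surrounded: set[str],
    paralog_family_of: dict[str, str],
    expression: pd.DataFrame,
    family_genome_span: dict[str, int],
    ortholog_family_of: dict[str, str] | None = None,
    threshold: float = 1.0,
    min_genomes: int = 5,
) -> RescueResult:
    """Rescue evidence that silent TE-surrounded genes are real genes.

    paralog-rescued: the gene shares a paralog family with at least one
    gene that is not TE-surrounded and is expressed (> threshold FPKM in
    some stage). ortholog-conserved: the gene's ortholog family spans at
    least *min_genomes* other genomes. Genes in no family contribute to
    neither count.
    """
    fpkm_cols = list(STAGES)
    expressed_ids = {
        row.gene_id
        for row in expression.itertuples(index=False)
        if is_expressed([getattr(row, c) for c in fpkm_cols], threshold)
    }
    members: dict[str, set[str]] = {}
    for gene, fam in paralog_family_of.items():
        members.setdefault(fam, set()).add(gene)

    ortholog_family_of = ortholog_family_of or paralog_family_of
    rescued, conserved = set(), set()
    for gene in silent_te_genes:
        fam = paralog_family_of.get(gene)
        if fam is not None:
            others = members[fam] - {gene}
            if any(o not in te_surrounded and o in expressed_ids for o in others):
                rescued.add(gene)
        ofam = ortholog_family_of.get(gene)
        if ofam is not None and family_genome_span.get(ofam, 0) >= min_genomes:
            conserved.add(gene)
    return RescueResult(
        n_silent=len(silent_te_genes),
        paralog_rescued=frozenset(rescued),
        ortholog_conserved=frozenset(conserved),
    )
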