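"""Multi-tool evidence integration.

Secretome voting (>= 3 of 4 predictors) with the TM/ER/GPI exclusion
cascade, small-secreted-protein and cysteine-rich classification, CAZyme
agreement voting, three-way gene-support evidence, and Pfam-accession-list
tagging/filtering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .expression import STAGES, is_expressed
from .io_formats import Column, TableSchema
from .models import SchemaError

SECRETION_TOOLS = ("signalp", "wolfpsort", "targetp", "protcomp")
CAZYME_TOOLS = ("dbcan", "blast", "pfam")
CAZYME_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")

_YN = frozenset({"Y", "N"})
_PFAM_RE = re.compile(r"^PF\d{5}$")
_CAZY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)\d+$")

SECRETION_SCHEMA = TableSchema(
    columns=(
        Column("gene_id", "str"),
        Column("signalp", "str", allowed=_YN),
        Column("wolfpsort", "str", allowed=_YN),
        Column("targetp", "str", allowed=_YN),
        Column("protcomp", "str", allowed=_YN),
        Column("tm_helices", "str", required=False, default=""),
        Column("er_motif", "str", allowed=_YN, required=False, default="N"),
        Column("gpi_anchor", "str", allowed=_YN, required=False, default="N"),
        Column("protein_length", "int"),
        Column("cys_count", "int"),
    )
)

CAZYME_SCHEMA = TableSchema(
    columns=(
        Column("gene_id", "str"),
        Column("dbcan", "str", required=False, default=""),
        Column("blast", "str", required=False, default=""),
        Column("pfam", "str", required=False, default=""),
    )
)


def parse_helices(text: str) -> list[tuple[int, int]]:
    """Parse 'start-end;start-end' (1-based aa) helix coordinates."""
    if not text or text == ".":
        return []
    out = []
    for part in text.split(";"):
        start_s, end_s = part.split("-")
        out.append((int(start_s), int(end_s)))
    return out


def secretome_vote(votes: pd.DataFrame, min_votes: int = 3) -> set[str]:
    """Genes called secreted by at least *min_votes* of the four predictors."""
    for tool in SECRETION_TOOLS:
        if tool not in votes.columns:
            raise SchemaError(f"missing verdict column {tool!r}")
    out = set()
    for row in votes.itertuples(index=False):
        n_yes = sum(getattr(row, tool) == "Y" for tool in SECRETION_TOOLS)
        if n_yes >= min_votes:
            out.add(row.gene_id)
    return out


def apply_exclusions(
    preliminary: set[str], votes: pd.DataFrame, n_term_window: int = 70
) -> set[str]:
    """Drop ER-motif, GPI-anchored and transmembrane proteins.

    A single helix starting within *n_term_window* aa of the N-terminus is
    exempt (treated as the signal peptide); any other helix configuration
    excludes the gene. The three exclusions commute.
    """
    info = {row.gene_id: row for row in votes.itertuples(index=False)}
    kept = set()
    for gene in preliminary:
        row = info[gene]
        if row.er_motif == "Y" or row.gpi_anchor == "Y":
            continue
        helices = parse_helices(row.tm_helices)
        if helices and not (len(helices) == 1 and helices[0][0] <= n_term_window):
            continue
        kept.add(gene)
    return kept


def classify_ssp(
    secreted: set[str],
    votes: pd.DataFrame,
    max_len: int = 300,
    cys_frac_min: float = 0.03,
) -> tuple[set[str], set[str]]:
    """(SSP set, cysteine-rich subset).

    SSP: secreted with protein length strictly below *max_len* aa;
    cysteine-rich: SSP with Cys fraction strictly above *cys_frac_min*.
    """
    info = {row.gene_id: row for row in votes.itertuples(index=False)}
    ssp, cys_rich = set(), set()
    for gene in secreted:
        row = info[gene]
        if row.protein_length <= 0:
            raise ValueError(f"gene {gene}: non-positive protein length")
        if row.protein_length < max_len:
            ssp.add(gene)
            if row.cys_count / row.protein_length > cys_frac_min:
                cys_rich.add(gene)
    return ssp, cys_rich


def secretome_pipeline(
    votes: pd.DataFrame,
    min_votes: int = 3,
    n_term_window: int = 70,
    max_len: int = 300,
    cys_frac_min: float = 0.03,
) -> dict:
    """Full cascade: vote, exclude, classify. Returns all intermediate sets."""
    preliminary = secretome_vote(votes, min_votes)
    secreted = apply_exclusions(preliminary, votes, n_term_window)
    ssp, cys_rich = classify_ssp(secreted, votes, max_len, cys_frac_min)
    return {
        "preliminary": preliminary,
        "secreted": secreted,
        "ssp": ssp,
        "cysteine_rich": cys_rich,
    }


def _parse_family_calls(text: str) -> list[str]:
    """Parse a predictor's call cell: ''/'.'/'none' or 'GH5' or 'GH5,CBM1'."""
    if not text or text in (".", "none"):
        return []
    fams = [f.strip() for f in text.split(",") if f.strip()]
    for fam in fams:
        if not _CAZY_RE.match(fam):
            raise ValueError(f"invalid CAZyme family label {fam!r}")
    return fams


def cazyme_vote(cazy: pd.DataFrame, min_agree: int = 2) -> dict[str, set[str]]:
    """Per-gene CAZyme family assignments.

    A family is assigned when at least *min_agree* of the three predictors
    call exactly that family for the gene; a gene may carry several
    families. Genes with no assignment are absent from the result.
    """
    out: dict[str, set[str]] = {}
    for row in cazy.itertuples(index=False):
        tally: dict[str, int] = {}
        for tool in CAZYME_TOOLS:
            for fam in set(_parse_family_calls(getattr(row, tool))):
                tally[fam] = tally.get(fam, 0) + 1
        assigned = {fam for fam, n in tally.items() if n >= min_agree}
        if assigned:
            out[row.gene_id] = assigned
    return out


@dataclass(frozen=True)
class EvidenceFlags:
    gene_id: str
    rnaseq_supported: bool
    domain_supported: bool
    ortholog_supported: bool

    @property
    def supported(self) -> bool:
        return self.rnaseq_supported or self.domain_supported or self.ortholog_supported


def gene_support_evidence(
    expression: pd.DataFrame,
    pfam_domains: dict[str, set[str]],
    ortholog_family_of: dict[str, str],
    family_genome_span: dict[str, int],
    threshold: float = 1.0,
    min_genomes: int = 5,
) -> list[EvidenceFlags]:
    """Three-way support flags for every gene in the expression table.

    rnaseq: > threshold FPKM in some stage; domain: at least one Pfam
    domain; ortholog: family spanning strictly more than *min_genomes*
    genomes.
    """
    fpkm_cols = list(STAGES)
    flags = []
    for row in expression.itertuples(index=False):
        gene = row.gene_id
        fam = ortholog_family_of.get(gene)
        flags.append(
            EvidenceFlags(
                gene_id=gene,
                rnaseq_supported=is_expressed([getattr(row, c) for c in fpkm_cols], threshold),
                domain_supported=bool(pfam_domains.get(gene)),
                ortholog_supported=(
                    fam is not None and family_genome_span.get(fam, 0) > min_genomes
                ),
            )
        )
    return flags


def validate_pfam_accessions(domain_list: set[str]) -> None:
    bad = sorted(d for d in domain_list if not _PFAM_RE.match(d))
    if bad:
        raise ValueError(f"malformed Pfam accessions: {bad[:5]}")


def filter_by_domain_list(
    genes: list[str],
    pfam_domains: dict[str, set[str]],
    domain_list: set[str],
    mode: str = "filter",
) -> tuple[list[str], list[str]] | set[str]:
    """Split *genes* on membership of any domain in *domain_list*.

    mode='filter' returns (kept, removed); mode='tag' returns just the
    matching set. Drives both TE-gene removal and TF tagging.
    """
    validate_pfam_accessions(domain_list)
    matching = {g for g in genes if pfam_domains.get(g, set()) & domain_list}
    if mode == "tag":
        return matching
    if mode == "filter":
        return [g for g in genes if g not in matching], [g for g in genes if g in matching]
    raise ValueError(f"unknown mode {mode!r}")
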