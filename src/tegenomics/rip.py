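"""RIP-style C→T hypermutation statistics over repeat-family alignments.

Each family is a gap-free-or-gapped multiple alignment of repeat copies
against a model sequence (majority consensus by default). Per copy we
count transitions/transversions and bin every C→T event by the dinucleotide
context CpX, where X is the model's next non-gap base; G→A events are the
reverse-strand image and are binned by the complement of the model's
previous non-gap base. A family is called RIP-like when its pooled
transition/transversion ratio strictly exceeds the cutoff (default 2) and
strictly more than the cutoff fraction of copies (default 1/3) show a
dominant context.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

from .models import SequenceRecord

log = logging.getLogger(__name__)

CONTEXTS = ("CpA", "CpC", "CpG", "CpT")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = frozenset("ACGT")

DEFAULT_TITV_MIN = 2.0
DEFAULT_BIAS_MIN = 1.0 / 3.0
DEFAULT_MIN_COPIES = 3


@dataclass
class RepeatFamilyAlignment:
    """Aligned copies of one repeat family plus the model they are scored
    against."""

    family_id: str
    model: str
    copies: list[str]
    copy_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.copy_ids:
            self.copy_ids = [f"{self.family_id}_copy{i}" for i in range(len(self.copies))]
        width = len(self.model)
        for cid, seq in zip(self.copy_ids, self.copies):
            if len(seq) != width:
                raise ValueError(
                    f"family {self.family_id}: copy {cid} length {len(seq)} != model {width}"
                )
        bad = set("".join(self.copies) + self.model) - set("ACGTN-")
        if bad:
            raise ValueError(f"family {self.family_id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class MutationCounts:
    transitions: int
    transversions: int
    c_to_t_by_context: dict[str, int]

    @property
    def total_c_to_t(self) -> int:
        return sum(self.c_to_t_by_context.values())


@dataclass(frozen=True)
class FamilyRipCall:
    family_id: str
    n_copies: int
    transitions: int
    transversions: int
    titv_ratio: float | None  # None = undefined (0/0); inf = n/0 with n>0
    biased_fraction: float
    dominant_context: str | None
    is_rip: bool


def build_consensus(copies: list[str]) -> str:
    """Per-column majority over non-gap characters, ties broken A<C<G<T<N;
    columns whose majority (or entirety) is gaps emit '-'."""
    if len(copies) < 2:
        raise ValueError("consensus needs at least 2 copies")
    width = len(copies[0])
    if any(len(c) != width for c in copies):
        raise ValueError("copies have unequal lengths")
    out = []
    order = {b: i for i, b in enumerate("ACGTN")}
    for col in range(width):
        column = [c[col] for c in copies]
        bases = Counter(ch for ch in column if ch != "-")
        n_gaps = len(column) - sum(bases.values())
        if not bases or n_gaps > sum(bases.values()):
            out.append("-")
            continue
        best = min(bases.items(), key=lambda kv: (-kv[1], order[kv[0]]))
        out.append(best[0])
    return "".join(out)


def _next_base(seq: str, pos: int, step: int) -> str | None:
    """Nearest non-gap character from *pos* in direction *step*, or None."""
    i = pos + step
    while 0 <= i < len(seq):
        if seq[i] != "-":
            return seq[i]
        i += step
    return None


def count_mutations(model: str, copy: str) -> MutationCounts:
    """Substitution counts of *copy* against *model*.

    Only columns where both rows carry an unambiguous base are compared.
    Context lookups use the model's nearest non-gap neighbor; a neighbor
    of N (or none) leaves the event counted as a transition but unbinned.
    """
    if len(model) != len(copy):
        raise ValueError(f"length mismatch: model {len(model)} vs copy {len(copy)}")
    transitions = transversions = 0
    contexts = {c: 0 for c in CONTEXTS}
    for i, (m, c) in enumerate(zip(model, copy)):
        if m not in _BASES or c not in _BASES or m == c:
            continue
        if (m, c) in _TRANSITIONS:
            transitions += 1
            if m == "C" and c == "T":
                nxt = _next_base(model, i, +1)
                if nxt in _BASES:
                    contexts[f"Cp{nxt}"] += 1
            elif m == "G" and c == "A":
                prev = _next_base(model, i, -1)
                if prev in _BASES:
                    contexts[f"Cp{_COMPLEMENT[prev]}"] += 1
        else:
            transversions += 1
    return MutationCounts(transitions, transversions, contexts)


def dominant_context(counts: MutationCounts) -> str | None:
    """The strict-argmax context of one copy, or None when the maximum is 0
    or tied with the runner-up."""
    ranked = sorted(counts.c_to_t_by_context.items(), key=lambda kv: -kv[1])
    if ranked[0][1] == 0:
        return None
    if len(ranked) > 1 and ranked[1][1] == ranked[0][1]:
        return None
    return ranked[0][0]


@dataclass(frozen=True)
class FamilyRipStats:
    family_id: str
    per_copy: tuple[MutationCounts, ...]
    titv_ratio: float | None
    biased_fraction: float
    family_dominant_context: str | None


def family_rip_statistics(
    family: RepeatFamilyAlignment, min_copies: int = DEFAULT_MIN_COPIES
) -> FamilyRipStats | None:
    """Pooled ti/tv ratio and the fraction of copies carrying a dominant
    context; returns None (with a logged reason) below *min_copies*."""
    if len(family.copies) < min_copies:
        log.info(
            "family %s skipped: %d copies < min_copies=%d",
            family.family_id, len(family.copies), min_copies,
        )
        return None
    per_copy = tuple(count_mutations(family.model, c) for c in family.copies)
    ti = sum(c.transitions for c in per_copy)
    tv = sum(c.transversions for c in per_copy)
    if tv > 0:
        titv: float | None = ti / tv
    elif ti > 0:
        titv = math.inf
    else:
        titv = None
    dominants = [d for d in (dominant_context(c) for c in per_copy) if d is not None]
    biased_fraction = len(dominants) / len(per_copy)
    family_dom = Counter(dominants).most_common(1)[0][0] if dominants else None
    return FamilyRipStats(family.family_id, per_copy, titv, biased_fraction, family_dom)


def classify_rip_family(
    stats: FamilyRipStats,
    titv_min: float = DEFAULT_TITV_MIN,
    bias_min: float = DEFAULT_BIAS_MIN,
) -> FamilyRipCall:
    """Apply the strict >titv_min and >bias_min rule; an infinite ti/tv
    passes, an undefined (0/0) one fails."""
    titv = stats.titv_ratio
    titv_ok = titv is not None and titv > titv_min
    is_rip = titv_ok and stats.biased_fraction > bias_min
    return FamilyRipCall(
        family_id=stats.family_id,
        n_copies=len(stats.per_copy),
        transitions=sum(c.transitions for c in stats.per_copy),
        transversions=sum(c.transversions for c in stats.per_copy),
        titv_ratio=titv,
        biased_fraction=stats.biased_fraction,
        dominant_context=stats.family_dominant_context,
        is_rip=is_rip,
    )


def analyze_family(
    family: RepeatFamilyAlignment,
    titv_min: float = DEFAULT_TITV_MIN,
    bias_min: float = DEFAULT_BIAS_MIN,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> FamilyRipCall | None:
    stats = family_rip_statistics(family, min_copies)
    if stats is None:
        return None
    return classify_rip_family(stats, titv_min, bias_min)


def genome_rip_summary(calls: list[FamilyRipCall]) -> dict:
    """Histogram of dominant contexts over RIP-called families."""
    hist: dict[str, int] = {}
    for call in calls:
        if call.is_rip and call.dominant_context is not None:
            hist[call.dominant_context] = hist.get(call.dominant_context, 0) + 1
    modal = max(hist.items(), key=lambda kv: kv[1])[0] if hist else None
    return {
        "n_families": len(calls),
        "n_rip": sum(c.is_rip for c in calls),
        "context_histogram": hist,
        "modal_context": modal,
    }


def family_from_records(
    family_id: str, records: list[SequenceRecord], model_suffix: str = "_model"
) -> RepeatFamilyAlignment:
    """Build an alignment from multi-FASTA records; a first record whose id
    ends with *model_suffix* (or equals 'consensus') supplies the model,
    otherwise a majority consensus is built from all records."""
    if not records:
        raise ValueError(f"family {family_id}: no records")
    first = records[0]
    if first.id.endswith(model_suffix) or first.id == "consensus":
        model, rest = first.seq, records[1:]
    else:
        model, rest = build_consensus([r.seq for r in records]), records
    return RepeatFamilyAlignment(
        family_id=family_id,
        model=model,
        copies=[r.seq for r in rest],
        copy_ids=[r.id for r in rest],
    )
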