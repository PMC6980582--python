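"""Stage-wise expression classification.

Implements the expressed/silent calls (strict ``> 1 FPKM``), pseudocount
log2 fold changes, the seven-way expression-pattern decision (three
single-stage enriched labels, three two-stage co-overexpressed labels, and
not-significant), transition up/down sets, the constitutive top-k set, and
Fisher exact category enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .io_formats import Column, TableSchema
from .models import ConfigError

STAGES = ("hyphae", "primordia", "fruiting_body")

FPKM_SCHEMA = TableSchema(
    columns=(
        Column("gene_id", "str"),
        Column("hyphae", "float"),
        Column("primordia", "float"),
        Column("fruiting_body", "float"),
    )
)

#: The seven pattern labels. H/P/F: enriched in one stage; HP/PF/HF:
#: co-overexpressed in two stages; NS: not significantly different.
PATTERNS = ("H", "P", "F", "HP", "PF", "HF", "NS")


def is_expressed(fpkms, threshold: float = 1.0) -> bool:
    """True iff FPKM strictly exceeds *threshold* in at least one stage."""
    return any(v > threshold for v in fpkms)


def is_silent_zero(fpkms) -> bool:
    """True iff FPKM is exactly zero in every stage."""
    return all(v == 0 for v in fpkms)


def pairwise_logfc(fpkm_a: float, fpkm_b: float, pseudocount: float = 1.0) -> float:
    """log2 fold change of *a* over *b* with a pseudocount in both terms."""
    if pseudocount < 0:
        raise ConfigError(f"pseudocount must be >= 0, got {pseudocount}")
    if pseudocount == 0 and (fpkm_a == 0 or fpkm_b == 0):
        raise ConfigError("pseudocount 0 is undefined for zero FPKM values")
    return math.log2((fpkm_a + pseudocount) / (fpkm_b + pseudocount))


@dataclass(frozen=True)
class PatternCall:
    gene_id: str
    pattern: str
    logfc_hp: float
    logfc_pf: float
    logfc_hf: float


def classify_pattern(
    gene_id: str,
    fpkm_h: float,
    fpkm_p: float,
    fpkm_f: float,
    pseudocount: float = 1.0,
    logfc_threshold: float = 1.0,
) -> PatternCall:
    """Assign exactly one of the seven expression-pattern labels.

    A stage is single-enriched when it exceeds both others with
    logFC > threshold. Two stages are co-overexpressed when each exceeds
    the third with logFC > threshold while their mutual |logFC| is strictly
    below the threshold. Everything else is NS.

    The labels are mutually exclusive by logFC antisymmetry: a pair used
    for a single-enriched call has |logFC| > threshold, which contradicts
    the |logFC| < threshold requirement of any co-call sharing that pair.
    """
    t = logfc_threshold
    l_hp = pairwise_logfc(fpkm_h, fpkm_p, pseudocount)
    l_pf = pairwise_logfc(fpkm_p, fpkm_f, pseudocount)
    l_hf = pairwise_logfc(fpkm_h, fpkm_f, pseudocount)

    if l_hp > t and l_hf > t:
        pattern = "H"
    elif -l_hp > t and l_pf > t:
        pattern = "P"
    elif -l_hf > t and -l_pf > t:
        pattern = "F"
    elif l_hf > t and l_pf > t and abs(l_hp) < t:
        pattern = "HP"
    elif -l_hp > t and -l_hf > t and abs(l_pf) < t:
        pattern = "PF"
    elif l_hp > t and -l_pf > t and abs(l_hf) < t:
        pattern = "HF"
    else:
        pattern = "NS"
    return PatternCall(gene_id, pattern, l_hp, l_pf, l_hf)


def classify_patterns(
    table: pd.DataFrame, pseudocount: float = 1.0, logfc_threshold: float = 1.0
) -> pd.DataFrame:
    """Vectorized :func:`classify_pattern` over an FPKM table."""
    calls = [
        classify_pattern(
            row.gene_id, row.hyphae, row.primordia, row.fruiting_body,
            pseudocount, logfc_threshold,
        )
        for row in table.itertuples(index=False)
    ]
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "pattern": [c.pattern for c in calls],
            "logfc_hp": [c.logfc_hp for c in calls],
            "logfc_pf": [c.logfc_pf for c in calls],
            "logfc_hf": [c.logfc_hf for c in calls],
        }
    )


def transition_de(
    table: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    pseudocount: float = 1.0,
    logfc_threshold: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Up/down regulated gene sets for the a-to-b stage transition.

    up: logFC(b over a) > threshold; down: < -threshold. Disjoint by
    construction.
    """
    for s in (stage_a, stage_b):
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; expected one of {STAGES}")
    up, down = set(), set()
    for row in table.itertuples(index=False):
        lfc = pairwise_logfc(getattr(row, stage_b), getattr(row, stage_a), pseudocount)
        if lfc > logfc_threshold:
            up.add(row.gene_id)
        elif lfc < -logfc_threshold:
            down.add(row.gene_id)
    return up, down


def constitutive_top_k(table: pd.DataFrame, k: int = 1000) -> set[str]:
    """Genes in the per-stage top-k (FPKM descending) of every stage.

    Ties at rank k are broken by ascending gene_id so the set is
    deterministic.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    k = min(k, len(table))
    result: set[str] | None = None
    for stage in STAGES:
        ranked = table.sort_values([stage, "gene_id"], ascending=[False, True])
        top = set(ranked["gene_id"].head(k))
        result = top if result is None else result & top
    return result or set()


# ---------------------------------------------------------------------------
# Fisher exact test by hypergeometric summation
# ---------------------------------------------------------------------------


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Computed by exact hypergeometric summation with the point-probability
    inclusion rule: sum the probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    All comparisons are on exact integer numerators (common denominator
    C(N, a+c)), so no float tie-breaking tolerance is needed.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    observed = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= observed:
            total += w
    return float(Fraction(total, math.comb(n, c1)))


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted q-values, preserving input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvalues[i] * m / rank)
        q[i] = val
        prev = val
    return q


def fisher_enrichment(
    foreground: set[str],
    background: set[str],
    category_map: dict[str, set[str]],
    alpha: float = 0.01,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-category two-sided Fisher enrichment of *foreground* vs *background*.

    *category_map* maps gene_id to a set of category labels; genes absent
    from the map carry no category. Raw p-values are always reported; a BH
    column is added only on request (off by default).
    """
    if not foreground:
        raise ValueError("empty foreground set")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    members: dict[str, set[str]] = {}
    for gene in background:
        for cat in category_map.get(gene, ()):
            members.setdefault(cat, set()).add(gene)

    rows = []
    n_fg, n_bg = len(foreground), len(background)
    for cat in sorted(members):
        in_cat = members[cat]
        a = len(foreground & in_cat)
        b = n_fg - a
        c = len(in_cat) - a
        d = (n_bg - n_fg) - c
        p = fisher_exact_two_sided(a, b, c, d)
        fg_rate = a / n_fg
        bg_rate = len(in_cat) / n_bg
        rows.append(
            {
                "category": cat,
                "n_foreground_in": a,
                "n_foreground_out": b,
                "n_background_in": len(in_cat),
                "direction": "enriched" if fg_rate >= bg_rate else "depleted",
                "p_value": p,
                "significant": p < alpha,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "category", "n_foreground_in", "n_foreground_out",
            "n_background_in", "direction", "p_value", "significant",
        ],
    )
    if bh and len(df):
        df["q_value"] = benjamini_hochberg(df["p_value"].tolist())
    return df


def expression_counts(table: pd.DataFrame, threshold: float = 1.0) -> dict:
    """Expressed / not-expressed / strict-zero counts over an FPKM table."""
    fpkm_cols = list(STAGES)
    expressed = sum(
        is_expressed(row, threshold) for row in table[fpkm_cols].itertuples(index=False)
    )
    zero = sum(is_silent_zero(row) for row in table[fpkm_cols].itertuples(index=False))
    return {
        "n_genes": len(table),
        "n_expressed": expressed,
        "n_not_expressed": len(table) - expressed,
        "n_zero_all_stages": zero,
    }
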