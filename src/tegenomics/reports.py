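"""Ratio reporting helpers and count-based summary reports.

Every percentage printed by the toolkit goes through :func:`pct`, which uses
decimal round-half-up so that reported one-decimal figures are reproducible
regardless of binary float representation.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round *x* to *ndigits* decimals with ties going away from zero."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` at fixed rounding."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# Count-based summary reports. These are the exact code paths the pipeline
# result objects use to print their ratios, exposed so summaries can also be
# rebuilt from externally supplied counts.
# ---------------------------------------------------------------------------


def suppression_summary(n_cohort: int, n_silent: int, ndigits: int = 1) -> dict:
    """Silent fraction of a TE-surrounded cohort."""
    return {
        "n_te_surrounded": n_cohort,
        "n_silent_among": n_silent,
        "pct_silent_among": pct(n_silent, n_cohort, ndigits),
    }


def expression_summary(n_total: int, n_expressed: int, ndigits: int = 1) -> dict:
    """Genome-wide expressed / not-expressed split."""
    return {
        "n_genes": n_total,
        "n_expressed": n_expressed,
        "n_not_expressed": n_total - n_expressed,
        "pct_expressed": pct(n_expressed, n_total, ndigits),
        "pct_not_expressed": pct(n_total - n_expressed, n_total, ndigits),
    }


def rescue_summary(
    n_silent: int, n_paralog_rescued: int, n_ortholog_conserved: int, ndigits: int = 1
) -> dict:
    """Paralog/ortholog rescue evidence over a silent TE-surrounded cohort."""
    return {
        "n_silent": n_silent,
        "n_paralog_rescued": n_paralog_rescued,
        "pct_paralog_rescued": pct(n_paralog_rescued, n_silent, ndigits),
        "n_ortholog_conserved": n_ortholog_conserved,
        "pct_ortholog_conserved": pct(n_ortholog_conserved, n_silent, ndigits),
    }


def repeat_fraction_summary(repeat_bp: float, genome_bp: float, ndigits: int = 1) -> dict:
    return {
        "repeat_bp": repeat_bp,
        "genome_bp": genome_bp,
        "pct_repeat": pct(repeat_bp, genome_bp, ndigits),
    }


def repressed_cds_summary(n_total: int, n_repressed: int, ndigits: int = 1) -> dict:
    """Fraction of repeat-region complete CDSs with zero FPKM at all stages."""
    return {
        "n_complete_cds": n_total,
        "n_repressed": n_repressed,
        "pct_repressed": pct(n_repressed, n_total, ndigits),
    }


def percent_coding_from_counts(
    n_genes: int, mean_cds_nt: float, genome_bp: float, ndigits: int = 2
) -> float:
    """Percent of the assembly that is coding, from gene count and mean CDS size."""
    return pct(n_genes * mean_cds_nt, genome_bp, ndigits)


def ssp_summary(n_ssp: int, n_de: int, n_zero: int, ndigits: int = 1) -> dict:
    """Differential-expression and strict-zero silent fractions of the SSP set."""
    return {
        "n_ssp": n_ssp,
        "n_de": n_de,
        "pct_de": pct(n_de, n_ssp, ndigits),
        "n_zero_fpkm": n_zero,
        "pct_zero_fpkm": pct(n_zero, n_ssp, ndigits),
    }


def tf_pattern_summary(n_de_tf: int, n_pf_pattern: int, ndigits: int = 1) -> dict:
    """Fraction of DE transcription-factor genes co-overexpressed in the two late stages."""
    return {
        "n_de_tf": n_de_tf,
        "n_pf_co_overexpressed": n_pf_pattern,
        "pct_pf_co_overexpressed": pct(n_pf_pattern, n_de_tf, ndigits),
    }


def write_json_report(payload: dict, path: str | Path, config: dict | None = None) -> None:
    """Write a JSON report, embedding the configuration that produced it."""
    doc = dict(payload)
    doc["config"] = config or {}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
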