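import numpy as np
import pandas as pd
import pytest

from tegenomics.models import GeneModel, GenomicInterval, RepeatHit
from tegenomics.te_context import (
    RepeatIndex,
    classify_te_surrounded,
    flanking_repeats,
    rescue_evidence,
    suppression_association,
)


def gene(gid, start, end, scaffold="s"):
    iv = GenomicInterval(scaffold, start, end)
    return GeneModel(gid, iv, exons=[iv], cds=[iv])


def repeat(start, end, scaffold="s", family="fam"):
    return RepeatHit(GenomicInterval(scaffold, start, end), family, "LTR/Gypsy")


def brute_force_surrounded(genes, repeats, window=1000, min_len=400, scaffold_lengths=None):
    """All-pairs interval-intersection oracle for the TE-surrounded rule."""
    out = set()
    for g in genes:
        iv = g.interval
        slen = (scaffold_lengths or {}).get(iv.scaffold)
        left_lo, left_hi = max(0, iv.start - window), iv.start
        right_lo = iv.end
        right_hi = iv.end + window if slen is None else min(iv.end + window, slen)
        left = right = False
        for r in repeats:
            if r.interval.scaffold != iv.scaffold or r.length <= min_len:
                continue
            if r.interval.start < left_hi and r.interval.end > left_lo:
                left = True
            if r.interval.start < right_hi and r.interval.end > right_lo:
                right = True
        if left and right:
            out.add(g.gene_id)
    return out


class TestFlankingRepeats:
    def test_stated_rule_arithmetic(self):
        g = gene("g", 5000, 6000)
        index = RepeatIndex([repeat(3900, 4600), repeat(6200, 6800)])
        report = flanking_repeats(g, index)
        assert [d for _, d in report.left_hits] == [400]
        assert [d for _, d in report.right_hits] == [200]
        assert report.is_te_surrounded

    def test_exact_length_400_rejected(self):
        g = gene("g", 5000, 6000)
        index = RepeatIndex([repeat(4100, 4500), repeat(6200, 6800)])
        report = flanking_repeats(g, index)
        assert report.left_hits == ()

    def test_length_401_accepted(self):
        g = gene("g", 5000, 6000)
        index = RepeatIndex([repeat(4099, 4500)])
        report = flanking_repeats(g, index)
        assert len(report.left_hits) == 1

    def test_overlap_with_gene_start_distance_zero(self):
        g = gene("g", 5000, 6000)
        index = RepeatIndex([repeat(4990, 5500)])
        report = flanking_repeats(g, index)
        assert [d for _, d in report.left_hits] == [0]

    def test_distance_exactly_window_excluded(self):
        # repeat ending at start-window does not intersect the half-open window
        g = gene("g", 5000, 6000)
        index = RepeatIndex([repeat(3400, 4000)])
        assert flanking_repeats(g, index).left_hits == ()

    def test_truncated_flags(self):
        g = gene("g", 500, 900)
        index = RepeatIndex([repeat(0, 450)])
        report = flanking_repeats(g, index, scaffold_length=1200)
        assert report.left_truncated
        assert report.right_truncated
        assert len(report.left_hits) == 1

    def test_missing_scaffold_empty_flanks(self):
        g = gene("g", 5000, 6000, scaffold="other")
        index = RepeatIndex([repeat(4000, 4600)])
        report = flanking_repeats(g, index)
        assert not report.left_hits and not report.right_hits


class TestClassify:
    def test_left_only_excluded(self):
        genes = [gene("g", 5000, 6000)]
        surrounded, _ = classify_te_surrounded(genes, [repeat(4000, 4600)])
        assert surrounded == set()

    def test_window_zero_degenerate(self):
        genes = [gene("g", 5000, 6000)]
        repeats = [repeat(4000, 4600), repeat(6100, 6700)]
        surrounded, _ = classify_te_surrounded(genes, repeats, window=0)
        assert surrounded == set()

    def test_planted_truth_recovery(self, small_bundle):
        b = small_bundle
        lengths = {r.id: len(r) for r in b.genome.sequences}
        surrounded, _ = classify_te_surrounded(
            b.genome.genes, b.genome.repeats, scaffold_lengths=lengths
        )
        assert surrounded == b.truth.te_surrounded_ids

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n_genes = int(rng.integers(1, 20))
            n_repeats = int(rng.integers(0, 60))
            genes = []
            for i in range(n_genes):
                start = int(rng.integers(0, 19_000))
                genes.append(gene(f"g{i}", start, start + int(rng.integers(100, 1000))))
            repeats = []
            for _ in range(n_repeats):
                start = int(rng.integers(0, 19_500))
                repeats.append(repeat(start, start + int(rng.integers(50, 1500))))
            got, _ = classify_te_surrounded(genes, repeats)
            assert got == brute_force_surrounded(genes, repeats)

    def test_monotone_in_window_and_min_len(self):
        rng = np.random.default_rng(7)
        genes = [gene(f"g{i}", int(s), int(s) + 500) for i, s in enumerate(rng.integers(0, 50_000, 20))]
        repeats = [
            repeat(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 50_000, 100), rng.integers(100, 1200, 100))
        ]
        prev = set()
        for window in (200, 500, 1000, 2000):
            cur, _ = classify_te_surrounded(genes, repeats, window=window)
            assert prev <= cur
            prev = cur
        prev = set()
        for min_len in (800, 400, 200, 0):
            cur, _ = classify_te_surrounded(genes, repeats, min_len=min_len)
            assert prev <= cur
            prev = cur


class TestSuppressionAssociation:
    def test_counts_and_percentages(self, fpkm_table):
        result = suppression_association({"g1", "g3"}, fpkm_table)
        # g1 expressed (2.5), g3 not (all exactly 1.0 fails the strict rule)
        assert result.n_te_surrounded == 2
        assert result.n_silent_among == 1
        assert result.pct_silent_among == 50.0

    def test_zero_rule(self, fpkm_table):
        result = suppression_association({"g1", "g3"}, fpkm_table, silent_rule="zero")
        assert result.n_silent_among == 0  # neither is all-zero

    def test_missing_genes_listed(self, fpkm_table):
        with pytest.raises(ValueError, match="g999"):
            suppression_association({"g999"}, fpkm_table)

    def test_fisher_matches_scipy(self):
        from scipy.stats import fisher_exact

        table = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(40)],
                "hyphae": [0.0] * 18 + [5.0] * 22,
                "primordia": [0.0] * 40,
                "fruiting_body": [0.0] * 40,
            }
        )
        te = {f"g{i}" for i in range(20)}  # 18 silent in TE set, 2 outside...
        result = suppression_association(te, table)
        a = result.n_silent_among
        b = result.n_te_surrounded - a
        c = result.n_silent_background
        d = result.n_background - c
        expected = fisher_exact([[a, b], [c, d]]).pvalue
        assert result.fisher_p == pytest.approx(expected, rel=1e-12)

    def test_silent_fraction_within_binomial_ci(self):
        from tests.conftest import small_config
        from tegenomics.simulate import simulate_all

        q = 0.7
        bundle = simulate_all(
            small_config(seed=5, n_genes=300, n_scaffolds=5, scaffold_length=500_000,
                         frac_te_surrounded=0.5, p_silent_given_te=q)
        )
        surrounded = bundle.truth.te_surrounded_ids
        result = suppression_association(surrounded, bundle.expression)
        n = result.n_te_surrounded
        # 99% normal-approx binomial CI around q
        half = 2.576 * (q * (1 - q) / n) ** 0.5
        assert abs(result.n_silent_among / n - q) <= half + 1e-9


class TestRescueEvidence:
    def _expression(self, expressed_ids, all_ids):
        return pd.DataFrame(
            {
                "gene_id": all_ids,
                "hyphae": [5.0 if g in expressed_ids else 0.0 for g in all_ids],
                "primordia": [0.0] * len(all_ids),
                "fruiting_body": [0.0] * len(all_ids),
            }
        )

    def test_planted_recovery(self):
        # s1 rescued by expressed non-TE paralog p1; s2's paralog is TE-surrounded;
        # s3 has no family; s1's family spans 6 genomes, s2's only 3.
        silent = {"s1", "s2", "s3"}
        te = {"s1", "s2", "s3", "p2"}
        families = {"s1": "famA", "p1": "famA", "s2": "famB", "p2": "famB"}
        spans = {"famA": 6, "famB": 3}
        expr = self._expression({"p1", "p2"}, ["s1", "s2", "s3", "p1", "p2"])
        result = rescue_evidence(silent, te, families, expr, spans)
        assert result.paralog_rescued == {"s1"}
        assert result.ortholog_conserved == {"s1"}
        summary = result.summary()
        assert summary["pct_paralog_rescued"] == pytest.approx(33.3)

    def test_min_genomes_at_least_rule(self):
        silent = {"s1"}
        families = {"s1": "famA"}
        expr = self._expression(set(), ["s1"])
        result = rescue_evidence(silent, set(), families, expr, {"famA": 5}, min_genomes=5)
        assert result.ortholog_conserved == {"s1"}
        result = rescue_evidence(silent, set(), families, expr, {"famA": 4}, min_genomes=5)
        assert result.ortholog_conserved == set()

    def test_gene_without_family_contributes_nothing(self):
        expr = self._expression(set(), ["s1"])
        result = rescue_evidence({"s1"}, set(), {}, expr, {})
        assert result.paralog_rescued == set()
        assert result.ortholog_conserved == set()
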