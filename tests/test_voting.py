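import itertools

import numpy as np
import pandas as pd
import pytest

from tegenomics.models import SchemaError
from tegenomics.voting import (
    SECRETION_TOOLS,
    apply_exclusions,
    cazyme_vote,
    classify_ssp,
    filter_by_domain_list,
    gene_support_evidence,
    parse_helices,
    secretome_pipeline,
    secretome_vote,
)


def vote_row(gene_id, yes=4, tm="", er="N", gpi="N", length=200, cys=2):
    row = {"gene_id": gene_id}
    for i, tool in enumerate(SECRETION_TOOLS):
        row[tool] = "Y" if i < yes else "N"
    row.update(tm_helices=tm, er_motif=er, gpi_anchor=gpi, protein_length=length, cys_count=cys)
    return row


def votes_frame(rows):
    return pd.DataFrame(rows)


class TestSecretomeVote:
    def test_three_of_four_included(self):
        votes = votes_frame([vote_row("g1", yes=3)])
        assert secretome_vote(votes) == {"g1"}

    def test_two_of_four_excluded(self):
        votes = votes_frame([vote_row("g1", yes=2)])
        assert secretome_vote(votes) == set()

    def test_missing_verdict_column_raises(self):
        votes = votes_frame([vote_row("g1")]).drop(columns=["targetp"])
        with pytest.raises(SchemaError, match="targetp"):
            secretome_vote(votes)

    def test_min_votes_4_is_intersection(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(100):
            yes = int(rng.integers(0, 5))
            rows.append(vote_row(f"g{i}", yes=yes))
        votes = votes_frame(rows)
        all_four = {
            r["gene_id"]
            for r in rows
            if all(r[tool] == "Y" for tool in SECRETION_TOOLS)
        }
        assert secretome_vote(votes, min_votes=4) == all_four


class TestExclusions:
    def test_single_nterminal_helix_retained(self):
        votes = votes_frame([vote_row("g1", tm="10-30")])
        assert apply_exclusions({"g1"}, votes) == {"g1"}

    def test_single_late_helix_excluded(self):
        votes = votes_frame([vote_row("g1", tm="100-120")])
        assert apply_exclusions({"g1"}, votes) == set()

    def test_multiple_helices_excluded(self):
        votes = votes_frame([vote_row("g1", tm="20-40;200-220")])
        assert apply_exclusions({"g1"}, votes) == set()

    def test_er_and_gpi_excluded(self):
        votes = votes_frame([vote_row("g1", er="Y"), vote_row("g2", gpi="Y")])
        assert apply_exclusions({"g1", "g2"}, votes) == set()

    def test_boundary_70(self):
        votes = votes_frame([vote_row("g1", tm="70-90"), vote_row("g2", tm="71-91")])
        assert apply_exclusions({"g1", "g2"}, votes) == {"g1"}

    def test_exclusions_commute(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(50):
            rows.append(
                vote_row(
                    f"g{i}",
                    tm=["", "10-30", "100-120", "20-40;200-220"][int(rng.integers(0, 4))],
                    er="YN"[int(rng.integers(0, 2))],
                    gpi="YN"[int(rng.integers(0, 2))],
                )
            )
        votes = votes_frame(rows)
        genes = {r["gene_id"] for r in rows}
        # applying the cascade to a pre-filtered subset in any order matches
        full = apply_exclusions(genes, votes)
        er_only = {
            g for g in genes
            if votes.set_index("gene_id").loc[g, "er_motif"] == "N"
        }
        assert apply_exclusions(er_only & genes, votes) == full


class TestSsp:
    def test_length_boundary(self):
        votes = votes_frame([vote_row("g1", length=299), vote_row("g2", length=300)])
        ssp, _ = classify_ssp({"g1", "g2"}, votes)
        assert ssp == {"g1"}

    def test_cysteine_rich(self):
        votes = votes_frame([vote_row("g1", length=100, cys=4), vote_row("g2", length=100, cys=3)])
        ssp, rich = classify_ssp({"g1", "g2"}, votes)
        assert rich == {"g1"}  # 4% > 3%; 3% is not strictly greater

    def test_zero_length_raises(self):
        votes = votes_frame([vote_row("g1", length=0)])
        with pytest.raises(ValueError, match="protein length"):
            classify_ssp({"g1"}, votes)


class TestPipelineProperties:
    def test_planted_truth_recovery(self, small_bundle):
        result = secretome_pipeline(small_bundle.secretion_votes)
        truth = small_bundle.truth
        assert result["secreted"] == truth.secreted_ids
        assert result["ssp"] == truth.ssp_ids
        assert result["cysteine_rich"] == truth.cysteine_rich_ids
        assert result["preliminary"] >= truth.secreted_ids | truth.excluded_ids

    def test_intersection_bounded_by_vote_set(self, small_bundle):
        votes = small_bundle.secretion_votes
        assert len(secretome_vote(votes, min_votes=4)) <= len(secretome_vote(votes, min_votes=3))

    def test_monotonicity_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(1, 10))
            rows = [vote_row(f"g{i}", yes=int(rng.integers(0, 5))) for i in range(n)]
            votes = votes_frame(rows)
            base = secretome_vote(votes)
            # adding a Y vote never removes a gene
            i = int(rng.integers(0, n))
            tool = SECRETION_TOOLS[int(rng.integers(0, 4))]
            boosted = votes.copy()
            boosted.loc[i, tool] = "Y"
            assert base <= secretome_vote(boosted)
            # raising min_votes never grows the set
            assert secretome_vote(votes, min_votes=4) <= base


class TestCazymeVote:
    def _frame(self, dbcan, blast, pfam):
        return pd.DataFrame([{"gene_id": "g1", "dbcan": dbcan, "blast": blast, "pfam": pfam}])

    def test_two_agree(self):
        assert cazyme_vote(self._frame("GH5", "GH5", "")) == {"g1": {"GH5"}}

    def test_disagreement_unassigned(self):
        assert cazyme_vote(self._frame("GH5", "GH7", "")) == {}

    def test_multi_family(self):
        out = cazyme_vote(self._frame("GH5,CBM1", "GH5", "CBM1"))
        assert out == {"g1": {"GH5", "CBM1"}}

    def test_multiset_agreement_oracle(self):
        # independent recount: for every family label, count predictors
        # listing it; assign iff count >= 2
        rng = np.random.default_rng(5)
        vocab = ["GH5", "GH7", "CBM1", "AA9"]
        for _ in range(100):
            calls = [
                ",".join(sorted(set(rng.choice(vocab, size=rng.integers(0, 3), replace=False))))
                for _ in range(3)
            ]
            frame = self._frame(*calls)
            expected = {}
            tally = {}
            for call in calls:
                for fam in filter(None, call.split(",")):
                    tally[fam] = tally.get(fam, 0) + 1
            fams = {f for f, n in tally.items() if n >= 2}
            if fams:
                expected["g1"] = fams
            assert cazyme_vote(frame) == expected

    def test_min_agree_3_strict(self):
        assert cazyme_vote(self._frame("GH5", "GH5", ""), min_agree=3) == {}
        assert cazyme_vote(self._frame("GH5", "GH5", "GH5"), min_agree=3) == {"g1": {"GH5"}}

    def test_invalid_family_label_raises(self):
        with pytest.raises(ValueError, match="invalid CAZyme"):
            cazyme_vote(self._frame("XX9", "", ""))

    def test_planted_recovery(self, small_bundle):
        assignments = cazyme_vote(small_bundle.cazyme_votes)
        expected = {g: set(v) for g, v in small_bundle.truth.cazyme_assignments.items()}
        assert assignments == expected


class TestGeneSupport:
    def _expression(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "hyphae": [0.0, 5.0, 0.0],
                "primordia": [0.0, 0.0, 0.0],
                "fruiting_body": [0.0, 0.0, 0.0],
            }
        )

    def test_ortholog_only_support(self):
        flags = gene_support_evidence(
            self._expression(), {}, {"g1": "famA"}, {"famA": 6}
        )
        by_id = {f.gene_id: f for f in flags}
        assert by_id["g1"].supported and by_id["g1"].ortholog_supported
        assert not by_id["g1"].rnaseq_supported

    def test_five_genomes_boundary_strict(self):
        flags = gene_support_evidence(
            self._expression(), {}, {"g1": "famA"}, {"famA": 5}
        )
        assert not {f.gene_id: f for f in flags}["g1"].ortholog_supported

    def test_no_memberships_unsupported(self):
        flags = gene_support_evidence(self._expression(), {}, {}, {})
        assert not {f.gene_id: f for f in flags}["g3"].supported

    def test_supported_is_or(self):
        flags = gene_support_evidence(
            self._expression(), {"g3": {"PF00001"}}, {}, {}
        )
        by_id = {f.gene_id: f for f in flags}
        assert by_id["g2"].rnaseq_supported and by_id["g2"].supported
        assert by_id["g3"].domain_supported and by_id["g3"].supported


class TestDomainList:
    def test_te_gene_removed(self):
        kept, removed = filter_by_domain_list(
            ["g1", "g2"], {"g1": {"PF07727"}}, {"PF03732", "PF07727"}
        )
        assert removed == ["g1"] and kept == ["g2"]

    def test_empty_list_removes_nothing(self):
        kept, removed = filter_by_domain_list(["g1"], {"g1": {"PF07727"}}, set())
        assert kept == ["g1"] and removed == []

    def test_malformed_accession_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            filter_by_domain_list(["g1"], {}, {"PF123"})

    def test_tf_tagging_recovery(self):
        tf_list = {"PF01388", "PF04082", "PF11951"}
        domains = {
            "tf1": {"PF01388"},
            "tf2": {"PF04082", "PF00001"},
            "other": {"PF00002"},
        }
        tagged = filter_by_domain_list(
            list(domains), domains, tf_list, mode="tag"
        )
        assert tagged == {"tf1", "tf2"}

    def test_helix_parsing(self):
        assert parse_helices("10-30;200-220") == [(10, 30), (200, 220)]
        assert parse_helices("") == []
        assert parse_helices(".") == []
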