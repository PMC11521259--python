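"""Transcript prioritisation, consequence resolution, MAF filtering,
mask construction and protein-domain restriction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rareburden import annotation_masks as am
from rareburden.annotation_masks import DomainSpan, TranscriptConsequence
from rareburden.variant_io import MISSING, CohortGenotypes, VariantRecord


def tc(transcript="ENST1", biotype="protein_coding", mane=False, canonical=False,
       terms=("missense_variant",), cadd=30.0, loftee="NA", pp=50, vid="9:1:A:G"):
    return TranscriptConsequence(
        variant_id=vid, gene_symbol="NR5A1", transcript_id=transcript,
        biotype=biotype, is_mane=mane, is_canonical=canonical,
        consequence_terms=tuple(terms), cadd_phred=cadd, loftee=loftee,
        protein_position=pp,
    )


class TestSelectTranscript:
    def test_mane_coding_beats_canonical_noncoding(self):
        rows = [
            tc(transcript="ENST_NC", biotype="retained_intron", canonical=True),
            tc(transcript="ENST_MANE", mane=True),
        ]
        assert am.select_transcript(rows).transcript_id == "ENST_MANE"

    def test_single_candidate(self):
        row = tc(canonical=True)
        assert am.select_transcript([row]) is row

    def test_lexicographic_tie_break(self):
        rows = [tc(transcript="ENST2"), tc(transcript="ENST10")]
        assert am.select_transcript(rows).transcript_id == "ENST10"

    def test_canonical_breaks_ties_below_mane(self):
        rows = [tc(transcript="ENSTB", canonical=True), tc(transcript="ENSTA")]
        assert am.select_transcript(rows).transcript_id == "ENSTB"

    @given(perm=st.permutations(range(4)))
    @settings(deadline=None)
    def test_order_independent(self, perm):
        rows = [
            tc(transcript="ENSTA"),
            tc(transcript="ENSTB", canonical=True),
            tc(transcript="ENSTC", mane=True),
            tc(transcript="ENSTD", biotype="nonsense_mediated_decay"),
        ]
        shuffled = [rows[i] for i in perm]
        assert am.select_transcript(shuffled).transcript_id == "ENSTC"


class TestSeverity:
    def test_missense_outranks_splice_region(self):
        assert am.most_severe_term(["missense_variant", "splice_region_variant"]) == "missense_variant"

    def test_single_term(self):
        assert am.most_severe_term(["stop_gained"]) == "stop_gained"

    def test_missense_outranks_synonymous(self):
        assert am.most_severe_term(["synonymous_variant", "missense_variant"]) == "missense_variant"

    def test_unknown_term_named_in_error(self):
        with pytest.raises(ValueError, match="not_a_term"):
            am.most_severe_term(["not_a_term"])

    @pytest.mark.parametrize(
        "term,expected",
        [
            ("stop_gained", True),
            ("frameshift_variant", True),
            ("splice_acceptor_variant", True),
            ("splice_donor_variant", True),
            ("missense_variant", False),
            ("stop_lost", False),
        ],
    )
    def test_ptv_consolidation(self, term, expected):
        assert am.is_ptv(term) is expected


def small_cohort(dosages: dict[str, list[int]], n_samples: int) -> CohortGenotypes:
    variants, rows = [], []
    for i, (vid, d) in enumerate(dosages.items()):
        chrom, pos, ref, alt = vid.split(":")
        variants.append(VariantRecord(chrom, int(pos), ref, alt))
        row = np.zeros(n_samples, dtype=np.int32)
        row[: len(d)] = d
        rows.append(row)
    dosage = np.stack(rows) if rows else np.zeros((0, n_samples), dtype=np.int32)
    full = np.full_like(dosage, 30)
    return CohortGenotypes(
        variants, [f"S{i}" for i in range(n_samples)], dosage, full, full,
        np.maximum(full - 15 * (dosage == 1) - 30 * (dosage == 2), 0),
        15 * (dosage == 1) + 30 * (dosage == 2),
    )


class TestComputeMaf:
    def test_one_het_in_thousand(self):
        cohort = small_cohort({"9:1:A:G": [1]}, 1000)
        assert am.compute_maf(cohort, "9:1:A:G") == pytest.approx(5e-4)

    def test_monomorphic(self):
        cohort = small_cohort({"9:1:A:G": [0]}, 10)
        assert am.compute_maf(cohort, "9:1:A:G") == 0.0

    def test_folding_to_minor_allele(self):
        cohort = small_cohort({"9:1:A:G": [2] * 9 + [1]}, 10)
        # alt frequency 19/20 folds to 1/20
        assert am.compute_maf(cohort, "9:1:A:G") == pytest.approx(0.05)

    def test_all_missing_is_an_error(self):
        cohort = small_cohort({"9:1:A:G": [0] * 10}, 10)
        cohort.dosage[0, :] = MISSING
        with pytest.raises(ValueError, match="missing"):
            am.compute_maf(cohort, "9:1:A:G")


class TestBuildMask:
    def annotations(self):
        return am.resolve_annotations(
            [
                tc(vid="9:1:A:G", terms=("missense_variant",), cadd=25.0, pp=30),
                tc(vid="9:2:A:G", terms=("missense_variant",), cadd=24.9, pp=40),
                tc(vid="9:3:A:G", terms=("stop_gained",), cadd=40.0, loftee="HC", pp=50),
                tc(vid="9:4:A:G", terms=("stop_gained",), cadd=40.0, loftee="LC", pp=60),
                tc(vid="9:5:A:G", terms=("synonymous_variant",), cadd=2.0, pp=70),
            ]
        )

    def cohort(self):
        return small_cohort(
            {f"9:{i}:A:G": [1] for i in range(1, 6)}, 2000
        )  # MAF 2.5e-4 each

    def test_cadd_threshold_inclusive(self):
        mask = am.build_mask(self.annotations(), self.cohort(), "missense_cadd25")
        assert mask.variant_ids == {"9:1:A:G"}

    def test_low_confidence_ptv_excluded(self):
        mask = am.build_mask(self.annotations(), self.cohort(), "hc_ptv")
        assert mask.variant_ids == {"9:3:A:G"}

    def test_damaging_is_union(self):
        anns, cohort = self.annotations(), self.cohort()
        dam = am.build_mask(anns, cohort, "damaging")
        ptv = am.build_mask(anns, cohort, "hc_ptv")
        mis = am.build_mask(anns, cohort, "missense_cadd25")
        assert dam.variant_ids == ptv.variant_ids | mis.variant_ids

    def test_common_variant_excluded_by_maf(self):
        cohort = small_cohort({f"9:{i}:A:G": [1] * 30 for i in range(1, 6)}, 10000)
        # 30 hets / 10000 samples: MAF 1.5e-3 >= 0.1%
        mask = am.build_mask(self.annotations(), cohort, "missense_cadd25")
        assert mask.variant_ids == frozenset()

    def test_lowering_maf_threshold_never_grows_mask(self):
        anns = self.annotations()
        cohort = small_cohort({f"9:{i}:A:G": [1] for i in range(1, 6)}, 2000)
        prev = None
        for thr in (0.5, 1e-3, 2.6e-4, 1e-5):
            mask = am.build_mask(anns, cohort, "damaging", maf_threshold=thr)
            if prev is not None:
                assert mask.variant_ids <= prev
            prev = mask.variant_ids

    def test_unknown_mask_name(self):
        with pytest.raises(ValueError, match="unknown mask"):
            am.build_mask(self.annotations(), self.cohort(), "everything")


class TestDomainRestriction:
    domains = [DomainSpan("NR5A1", "DBD", 10, 85), DomainSpan("NR5A1", "LBD", 225, 460)]

    def build(self, pps):
        anns = am.resolve_annotations(
            [tc(vid=f"9:{i}:A:G", pp=pp) for i, pp in enumerate(pps, start=1)]
        )
        cohort = small_cohort({f"9:{i}:A:G": [1] for i in range(1, len(pps) + 1)}, 2000)
        mask = am.build_mask(anns, cohort, "missense_cadd25")
        return anns, mask

    def test_interval_membership(self):
        anns, mask = self.build([30, 150, 250])
        dbd = am.restrict_to_domains(mask, anns, self.domains, ["DBD"])
        assert dbd.variant_ids == {"9:1:A:G"}
        assert dbd.domain_scope == ("DBD",)

    def test_end_residue_inclusive(self):
        anns, mask = self.build([85, 86])
        dbd = am.restrict_to_domains(mask, anns, self.domains, ["DBD"])
        assert dbd.variant_ids == {"9:1:A:G"}

    def test_hinge_dropped_and_scopes_partition(self):
        anns, mask = self.build([30, 150, 250, 400])
        dbd = am.restrict_to_domains(mask, anns, self.domains, ["DBD"])
        lbd = am.restrict_to_domains(mask, anns, self.domains, ["LBD"])
        both = am.restrict_to_domains(mask, anns, self.domains, ["DBD", "LBD"])
        assert "9:2:A:G" not in both.variant_ids  # hinge variant
        assert dbd.variant_ids | lbd.variant_ids == both.variant_ids
        assert dbd.variant_ids <= mask.variant_ids and both.variant_ids <= mask.variant_ids

    def test_no_protein_position_dropped(self):
        anns = am.resolve_annotations([tc(vid="9:1:A:G", pp=None)])
        cohort = small_cohort({"9:1:A:G": [1]}, 2000)
        mask = am.build_mask(anns, cohort, "missense_cadd25")
        out = am.restrict_to_domains(mask, anns, self.domains, ["DBD", "LBD"])
        assert out.variant_ids == frozenset()

    def test_unknown_domain_is_an_error(self):
        anns, mask = self.build([30])
        with pytest.raises(ValueError, match="hinge"):
            am.restrict_to_domains(mask, anns, self.domains, ["hinge"])


class TestTables:
    def test_annotation_table_round_trip(self, tmp_path, tiny_toy):
        path = tmp_path / "ann.tsv"
        am.write_annotation_table(tiny_toy.annotations, path)
        assert am.read_annotation_table(path) == tiny_toy.annotations

    def test_protein_position_ranges_use_start(self):
        assert am._parse_protein_position("123-125") == 123
        assert am._parse_protein_position("123") == 123
        assert am._parse_protein_position("") is None

    def test_overlapping_domains_rejected(self, tmp_path):
        path = tmp_path / "dom.tsv"
        path.write_text("gene\tdomain\tstart\tend\nG\tA\t1\t50\nG\tB\t40\t90\n")
        with pytest.raises(ValueError, match="overlap"):
            am.read_domain_table(path)
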