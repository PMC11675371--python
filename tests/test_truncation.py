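"""Truncation marking, the last-exon NMD rule, and haploinsufficiency calls."""

import pytest

from senscan._errors import ConsequenceError, RangeError
from senscan.examples import truncation_fixture
from senscan.io import VariantTable
from senscan.truncation import (
    TRUNCATING,
    HaploThresholds,
    classify_truncation,
    haploinsufficiency_report,
    mark_truncation_site,
)
from senscan.variant_model import SourceLabel, dedupe_variants, parse_hgvs_p


class TestMarkSite:
    def test_nonsense_position_maps_to_first_codon_nucleotide(self, toy_transcript):
        v = parse_hgvs_p("p.L25*")
        assert mark_truncation_site(v, toy_transcript) == 73  # 3·24 + 1

    def test_explicit_hint_passes_through(self, toy_transcript):
        v = parse_hgvs_p("p.T271fs")
        assert mark_truncation_site(v, toy_transcript, cds_hint=812) == 812

    def test_missense_rejected(self, toy_transcript):
        with pytest.raises(ConsequenceError):
            mark_truncation_site(parse_hgvs_p("p.R451C"), toy_transcript)

    def test_site_beyond_cds_rejected(self, toy_transcript):
        v = parse_hgvs_p("p.L400*")  # codon start 1198 > CDS length 1002
        with pytest.raises(RangeError):
            mark_truncation_site(v, toy_transcript)


class TestNmdRule:
    def test_stop_in_middle_exon_predicts_nmd(self, toy_transcript):
        call = classify_truncation(parse_hgvs_p("p.K150*"), toy_transcript)
        assert call.exon_index == 2 and call.predicted_nmd

    def test_stop_in_last_exon_escapes_nmd(self, toy_transcript):
        call = classify_truncation(parse_hgvs_p("p.K300*"), toy_transcript)
        assert call.exon_index == 3 and not call.predicted_nmd

    def test_first_nucleotide_of_last_exon_belongs_to_last_exon(self, toy_transcript):
        # exon 3 starts at CDS nt 601 = codon 201
        call = classify_truncation(parse_hgvs_p("p.K201*"), toy_transcript)
        assert call.cds_position == 601
        assert call.exon_index == 3 and not call.predicted_nmd

    def test_exhaustive_over_all_codons(self, toy_transcript):
        """predicted_nmd is true exactly for codons starting before exon 3
        (CDS nt 601), checked for every residue of the toy protein."""
        for pos in range(1, toy_transcript.protein_length + 1):
            call = classify_truncation(parse_hgvs_p(f"p.K{pos}*"), toy_transcript)
            expected = 3 * (pos - 1) + 1 < 601
            assert call.predicted_nmd == expected, f"codon {pos}"

    def test_single_exon_transcript_never_predicts_nmd(self):
        from senscan.synthetic import generate_transcript

        t = generate_transcript(1, [300])
        for pos in (1, 50, 99):
            assert not classify_truncation(parse_hgvs_p(f"p.K{pos}*"), t).predicted_nmd


class TestHaploinsufficiencyReport:
    @pytest.mark.parametrize(
        "gene, expected_call",
        [
            ("NLGN1", "tolerant"),
            ("NLGN2", "tolerant"),
            ("NLGN3", "tolerant"),
            ("NLGN4X", "intolerant"),
        ],
    )
    def test_nlgn_fixture_calls(self, gene, expected_call):
        clinical, population, transcript = truncation_fixture(gene)
        report = haploinsufficiency_report(clinical, population, transcript)
        assert report.tolerance_call == expected_call
        assert report.rationale

    def test_nlgn3_rationale_notes_female_carrier_bias(self):
        clinical, population, transcript = truncation_fixture("NLGN3")
        report = haploinsufficiency_report(clinical, population, transcript)
        assert "female" in report.rationale
        assert "hemizygous males" in report.rationale
        assert report.population.n_female == 18 and report.population.n_male == 2

    def test_autosomal_fixture_counts_match_published_tallies(self):
        clinical, population, transcript = truncation_fixture("NLGN1")
        report = haploinsufficiency_report(clinical, population, transcript)
        assert report.population.total == 53
        assert report.population.before_last_exon == 53
        assert report.clinical.total == 3

    def test_subcounts_sum_to_totals(self):
        for gene in ("NLGN1", "NLGN2", "NLGN3", "NLGN4X"):
            _, population, transcript = truncation_fixture(gene)
            report = haploinsufficiency_report(
                VariantTable([], SourceLabel.CLINICAL), population, transcript
            )
            c = report.population
            assert c.before_last_exon + c.last_exon == c.total

    def test_empty_tables_indeterminate(self, toy_transcript):
        report = haploinsufficiency_report(
            VariantTable([], SourceLabel.CLINICAL),
            VariantTable([], SourceLabel.POPULATION),
            toy_transcript,
        )
        assert report.tolerance_call == "indeterminate"

    def test_counts_invariant_under_input_permutation(self):
        clinical, population, transcript = truncation_fixture("NLGN3")
        shuffled = VariantTable(list(reversed(population.records)), SourceLabel.POPULATION)
        a = haploinsufficiency_report(clinical, population, transcript)
        b = haploinsufficiency_report(clinical, shuffled, transcript)
        assert a.to_dict() == b.to_dict()

    def test_counts_match_brute_force_recount(self):
        """Report tallies equal a direct recount of the deduplicated
        truncating list partitioned by last-exon status."""
        clinical, population, transcript = truncation_fixture("NLGN3")
        report = haploinsufficiency_report(clinical, population, transcript)
        truncating = [v for v in dedupe_variants(population.records) if v.consequence in TRUNCATING]
        before = sum(
            1 for v in truncating if classify_truncation(v, transcript).predicted_nmd
        )
        assert report.population.total == len(truncating)
        assert report.population.before_last_exon == before
        assert report.population.last_exon == len(truncating) - before

    def test_thresholds_are_configurable(self):
        clinical, population, transcript = truncation_fixture("NLGN1")
        strict = HaploThresholds(t_pop=100)
        report = haploinsufficiency_report(clinical, population, transcript, strict)
        assert report.tolerance_call != "tolerant"
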