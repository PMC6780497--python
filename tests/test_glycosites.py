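"""Sequon validation in protein context and protein-centric site inference."""

import re

import pytest

from nglyco.glycosites import (
    call_glycosites,
    count_unique,
    find_deamidated_asn,
    is_valid_sequon,
    locate_peptide,
)
from nglyco.io_formats import ProteinRecord

from conftest import make_peptide_record


def proteome(*pairs):
    return {acc: ProteinRecord(acc, "", seq) for acc, seq in pairs}


class TestFindDeamidatedAsn:
    def test_single_site(self):
        rec = make_peptide_record("LKNGSR", "deamidation_N(3)")
        assert find_deamidated_asn(rec) == [3]

    def test_q_deamidation_ignored(self):
        rec = make_peptide_record("LQNGSR", "deamidation_Q(2)")
        assert find_deamidated_asn(rec) == []

    def test_two_sites_ascending(self):
        rec = make_peptide_record("NGSANGSR", "deamidation_N(5);deamidation_N(1)")
        assert find_deamidated_asn(rec) == [1, 5]


class TestLocatePeptide:
    @pytest.mark.parametrize(
        "peptide,protein,expected",
        [
            ("NGS", "MKNGSL", [3]),
            ("AA", "AAA", [1, 2]),  # overlapping occurrences allowed
            ("W", "MKNGSL", []),
        ],
    )
    def test_examples(self, peptide, protein, expected):
        assert locate_peptide(peptide, protein) == expected


class TestIsValidSequon:
    @pytest.mark.parametrize(
        "sequence,pos,ok,sequon",
        [
            ("MKNGSL", 3, True, "NGS"),
            ("MKNPSL", 3, False, "NPS"),  # X may be anything but proline
            ("MKNGAL", 3, False, "NGA"),
            ("MKNGS", 3, True, "NGS"),
            ("MKNG", 3, False, "NG"),  # no +2 residue
            ("MKAGSL", 3, False, "AGS"),  # not an N
        ],
    )
    def test_examples(self, sequence, pos, ok, sequon):
        assert is_valid_sequon(sequence, pos) == (ok, sequon)

    def test_out_of_range_position(self):
        with pytest.raises(ValueError, match="outside protein"):
            is_valid_sequon("MKNGSL", 7)


class TestCallGlycosites:
    def test_internal_site_mapped_to_protein_coordinates(self):
        records = [make_peptide_record("LKNGSR", "deamidation_N(3)")]
        gps, sites, log = call_glycosites(records, proteome(("P1", "AALKNGSRTT")))
        assert len(gps) == 1
        (site,) = gps[0].glyco_sites
        assert (site.protein_accession, site.protein_position, site.sequon) == ("P1", 5, "NGS")
        assert len(log) == 0

    def test_peptide_terminal_asn_validated_in_protein_context(self):
        # the S/T completing the sequon lies in the next tryptic peptide
        records = [make_peptide_record("AAGN", "deamidation_N(4)")]
        gps, sites, _ = call_glycosites(records, proteome(("P1", "KAAGNFSDE")))
        assert len(gps) == 1
        (site,) = gps[0].glyco_sites
        assert (site.protein_position, site.sequon) == (5, "NFS")
        # independent whole-protein regex scan agrees
        scan = {m.start() + 1 for m in re.finditer(r"(?=N[^P][ST])", "KAAGNFSDE")}
        assert site.protein_position in scan

    def test_artifact_deamidation_discarded_and_logged(self):
        records = [make_peptide_record("LKNAAR", "deamidation_N(3)")]
        gps, sites, log = call_glycosites(records, proteome(("P1", "AALKNAARTT")))
        assert gps == [] and sites == []
        assert set(log["reason"]) == {"deamidation_outside_sequon", "discarded_no_valid_sequon"}

    def test_mixed_valid_and_artifact_site(self):
        # one N in a sequon, one outside: peptide kept, artifact logged
        records = [make_peptide_record("NGSANAAR", "deamidation_N(1);deamidation_N(5)")]
        gps, sites, log = call_glycosites(records, proteome(("P1", "KNGSANAAR")))
        assert len(gps) == 1
        assert [s.protein_position for s in gps[0].glyco_sites] == [2]
        assert (log["reason"] == "deamidation_outside_sequon").sum() == 1

    def test_unknown_accession_logged_peptide_still_mapped(self):
        records = [make_peptide_record("LKNGSR", "deamidation_N(3)", accessions=("GHOST", "P1"))]
        gps, _, log = call_glycosites(records, proteome(("P1", "AALKNGSRTT")))
        assert len(gps) == 1
        assert "accession_not_in_fasta" in set(log["reason"])

    def test_peptide_not_found_dropped(self):
        records = [make_peptide_record("WWWNGSWW", "deamidation_N(4)")]
        gps, _, log = call_glycosites(records, proteome(("P1", "AALKNGSRTT")))
        assert gps == []
        assert "peptide_not_found_in_claimed_proteins" in set(log["reason"])

    def test_shared_peptide_emits_sites_for_all_accessions(self):
        records = [
            make_peptide_record("LKNGSR", "deamidation_N(3)", accessions=("P1", "P2"))
        ]
        gps, sites, _ = call_glycosites(
            records, proteome(("P1", "AALKNGSRTT"), ("P2", "LKNGSRCCCC"))
        )
        assert len(gps) == 1
        assert {(s.protein_accession, s.protein_position) for s in gps[0].glyco_sites} == {
            ("P1", 5),
            ("P2", 3),
        }

    def test_repeated_occurrence_flagged_ambiguous(self):
        records = [make_peptide_record("ANGSR", "deamidation_N(2)")]
        gps, sites, _ = call_glycosites(records, proteome(("P1", "ANGSRANGSR")))
        assert gps[0].ambiguous
        assert [s.protein_position for s in gps[0].glyco_sites] == [2, 7]

    def test_site_records_deduplicated_across_peptides(self):
        records = [
            make_peptide_record("LKNGSR", "deamidation_N(3)", replicate="R1"),
            make_peptide_record("ALKNGSR", "deamidation_N(4)", replicate="R1"),
        ]
        gps, sites, _ = call_glycosites(records, proteome(("P1", "AALKNGSRTT")))
        assert len(sites) == 1
        assert sites[0].supporting_peptides == {"LKNGSR", "ALKNGSR"}


class TestCountUnique:
    def test_replicates_count_once(self):
        records = [
            make_peptide_record("LKNGSR", "deamidation_N(3)", replicate=r) for r in "1234"
        ]
        gps, _, _ = call_glycosites(records, proteome(("P1", "AALKNGSRTT")))
        assert count_unique(gps) == (1, 1)

    def test_shared_peptide_counts_both_proteins(self):
        records = [make_peptide_record("LKNGSR", "deamidation_N(3)", accessions=("P1", "P2"))]
        gps, _, _ = call_glycosites(
            records, proteome(("P1", "AALKNGSRTT"), ("P2", "LKNGSRCCCC"))
        )
        assert count_unique(gps) == (1, 2)

    def test_empty_input(self):
        assert count_unique([]) == (0, 0)

    def test_order_invariance(self, small_study):
        from nglyco.io_formats import index_proteome, read_fasta, read_psm_table
        from nglyco.psm_filtering import aggregate_psms, compute_q_values, filter_fdr

        _, paths, _ = small_study
        prot = index_proteome(read_fasta(paths["fasta"]))
        peptides = aggregate_psms(filter_fdr(compute_q_values(read_psm_table(paths["glyco_psms"]))))
        fwd, _, _ = call_glycosites(peptides, prot)
        rev, _, _ = call_glycosites(peptides[::-1], prot)
        assert count_unique(fwd) == count_unique(rev)
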