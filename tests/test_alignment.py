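"""Alignment I/O, haplotype collapsing, coding QC and site statistics."""

import pytest
from hypothesis import given, settings, strategies as st

from barcodedelim.alignment import (
    check_coding,
    collapse_haplotypes,
    read_alignment,
    site_statistics,
    write_fasta,
)
from barcodedelim.errors import (
    AlignmentError,
    ConfigurationError,
    IdentifierError,
    InputError,
)
from conftest import make_alignment


class TestReadAlignment:
    def test_parses_equal_length_records(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\nACGT\n>b\nacgtacgt\n>c\nNNNN-CGT\n")
        a = read_alignment(p)
        assert a.n_samples == 3 and a.length == 8
        assert a.sequence("b") == "ACGTACGT"  # case-normalised

    def test_unequal_lengths_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGTACGTAC\n>b\nACGTACGTA\n")
        with pytest.raises(AlignmentError):
            read_alignment(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n>a\nACGT\n>b\nACGA\n")
        with pytest.raises(IdentifierError):
            read_alignment(p)

    def test_empty_and_single_record_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(InputError):
            read_alignment(p)
        p.write_text(">a\nACGT\n")
        with pytest.raises(InputError):
            read_alignment(p)

    def test_fasta_round_trip(self, tmp_path):
        a = make_alignment([("s1", "ACGTN-GT"), ("s2", "ACCTNNGT")])
        write_fasta(a, tmp_path / "out.fasta")
        b = read_alignment(tmp_path / "out.fasta")
        assert tuple(b.records()) == tuple(a.records())


class TestCheckCoding:
    def test_clean_coding_sequence(self):
        a = make_alignment([("s1", "ATGGCT"), ("s2", "ATGGCA")])
        rep = check_coding(a, frame=1, code="vertebrate_mito")
        assert rep.all_clean

    def test_aga_is_internal_stop_in_vertebrate_mito(self):
        # AGA codes for arginine in the standard code but is a stop in the
        # vertebrate mitochondrial code
        a = make_alignment([("s1", "ATGAGAGCT"), ("s2", "ATGCGAGCT")])
        rep = check_coding(a, frame=1, code="vertebrate_mito")
        assert rep.samples[0].internal_stop_codons == (2,)
        assert rep.samples[1].internal_stop_codons == ()
        std = check_coding(a, frame=1, code="standard")
        assert std.all_clean

    def test_gap_flag(self):
        a = make_alignment([("s1", "ATG-CT"), ("s2", "ATGGCT")])
        rep = check_coding(a)
        assert rep.samples[0].has_gaps and not rep.samples[0].coding_clean
        assert rep.samples[1].coding_clean

    def test_terminal_stop_not_internal(self):
        a = make_alignment([("s1", "ATGGCTTAA"), ("s2", "ATGGCTTAC")])
        rep = check_coding(a)
        assert rep.samples[0].internal_stop_codons == ()

    def test_unknown_code_and_frame_rejected(self):
        a = make_alignment([("s1", "ATGGCT"), ("s2", "ATGGCA")])
        with pytest.raises(ConfigurationError):
            check_coding(a, code="klingon")
        with pytest.raises(ConfigurationError):
            check_coding(a, frame=4)


class TestCollapseHaplotypes:
    def test_first_occurrence_is_representative(self):
        a = make_alignment([("s1", "ACGT"), ("s2", "ACGT"), ("s3", "ACGA")])
        red, hmap = collapse_haplotypes(a)
        assert red.ids == ("s1", "s3")
        assert hmap.representative_of == {"s1": "s1", "s2": "s1", "s3": "s3"}
        assert hmap.haplotype_count == 2

    def test_all_distinct_is_identity(self):
        a = make_alignment([("s1", "ACGT"), ("s2", "ACGA")])
        red, hmap = collapse_haplotypes(a)
        assert red.ids == a.ids
        assert all(hmap.representative_of[s] == s for s in a.ids)

    def test_n_containing_near_duplicates_do_not_collapse(self):
        a = make_alignment([("s1", "ACGT"), ("s2", "ACGN")])
        red, _ = collapse_haplotypes(a)
        assert red.n_samples == 2

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=2, max_size=12
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_size_bounded(self, seqs):
        a = make_alignment([(f"s{i}", s) for i, s in enumerate(seqs)])
        red, hmap = collapse_haplotypes(a)
        assert red.n_samples <= a.n_samples
        assert (red.n_samples == a.n_samples) == (len(set(seqs)) == len(seqs))
        red2, hmap2 = collapse_haplotypes(red)
        assert red2.ids == red.ids
        assert all(hmap2.representative_of[s] == s for s in red.ids)


class TestSiteStatistics:
    def test_by_definition_counts(self):
        # columns: (A,A,A,A) conserved; (A,A,G,G) PI; (A,A,A,T) singleton
        a = make_alignment([("s1", "AAA"), ("s2", "AAA"), ("s3", "AGA"), ("s4", "AGT")])
        s = site_statistics(a)
        assert (s.n_conserved, s.n_variable) == (1, 2)
        assert (s.n_parsimony_informative, s.n_singleton) == (1, 1)

    def test_single_column_conserved(self):
        a = make_alignment([("s1", "A"), ("s2", "A")])
        s = site_statistics(a)
        assert s.n_conserved == 1 and s.n_variable == 0

    def test_outgroup_excluded_by_default(self):
        a = make_alignment(
            [("s1", "AA"), ("s2", "AA"), ("out", "GG")], outgroup=("out",)
        )
        assert site_statistics(a).n_variable == 0
        assert site_statistics(a, exclude_outgroup=False).n_variable == 2

    def test_gap_columns_dropped_under_complete_deletion(self):
        a = make_alignment([("s1", "A-G"), ("s2", "AAG"), ("s3", "ATG")])
        s = site_statistics(a)
        assert s.n_sites_considered == 2
        s2 = site_statistics(a, complete_deletion=False)
        assert s2.n_sites_considered == 3

    def test_all_samples_excluded_is_error(self):
        a = make_alignment([("s1", "AA"), ("s2", "AA")], outgroup=("s1", "s2"))
        with pytest.raises(InputError):
            site_statistics(a)

    @given(
        st.lists(
            st.text(alphabet="ACGTN-", min_size=8, max_size=8), min_size=3, max_size=10
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_count_identities_hold(self, seqs):
        a = make_alignment([(f"s{i}", s) for i, s in enumerate(seqs)])
        s = site_statistics(a)
        assert s.n_conserved + s.n_variable == s.n_sites_considered
        assert s.n_parsimony_informative + s.n_singleton == s.n_variable

    def test_column_census_against_brute_force(self):
        # independent per-column tally for the (A,A,G,G)-style PI definition
        seqs = ["ACGGT", "ACGAT", "AGGAC", "AGTAC"]
        a = make_alignment([(f"s{i}", s) for i, s in enumerate(seqs)])
        s = site_statistics(a)
        pi = 0
        for col in zip(*seqs):
            counts = {c: col.count(c) for c in set(col)}
            if len(counts) >= 2 and sum(1 for v in counts.values() if v >= 2) >= 2:
                pi += 1
        assert s.n_parsimony_informative == pi
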