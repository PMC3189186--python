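import warnings

import pytest
from Bio import AlignIO
from hypothesis import given
from hypothesis import strategies as st

from pishift.seqio import (
    Alignment,
    ProteinRecord,
    PTMAnnotation,
    apply_signal_cleavage,
    extract_alignable_region,
    read_alignment,
    read_cleavage_table,
    read_fasta,
    read_ptm_table,
    read_selection_table,
    write_fasta,
)

SEQ_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"


class TestReadFasta:
    def test_two_entries(self, write_fasta_file):
        path = write_fasta_file([("fam1|human|P1", "MKTAG"), ("fam1|mouse|P2", "MKTAA")])
        records = read_fasta(path)
        assert len(records) == 2
        assert records[0].sequence == "MKTAG"
        assert records[0].family == "fam1"
        assert records[0].species == "human"
        assert records[0].id == "P1"
        assert records[1].sequence == "MKTAA"

    def test_lowercase_normalized(self, write_fasta_file):
        path = write_fasta_file([("f|s|low", "mktag")])
        assert read_fasta(path)[0].sequence == "MKTAG"

    def test_digit_rejected_naming_record(self, write_fasta_file):
        path = write_fasta_file([("f|s|bad1", "M1K")])
        with pytest.raises(ValueError, match="bad1"):
            read_fasta(path)

    def test_validation_matches_alphabet_scan(self, write_fasta_file):
        # oracle: a sequence is valid iff every letter is in the 21-letter set
        for seq in ("MKX", "MKB", "MJ", "ACDEFGHIKLMNPQRSTVWYX"):
            path = write_fasta_file([("f|s|r", seq)], name=f"{seq}.fasta")
            valid = set(seq) <= set(SEQ_ALPHABET)
            if valid:
                assert read_fasta(path)[0].sequence == seq
            else:
                with pytest.raises(ValueError):
                    read_fasta(path)

    def test_empty_file_errors(self, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(empty)

    def test_stop_symbol_stripped_with_warning(self, write_fasta_file):
        path = write_fasta_file([("f|s|stop", "MKT*")])
        with pytest.warns(UserWarning, match="stop symbol"):
            records = read_fasta(path)
        assert records[0].sequence == "MKT"

    def test_headers_without_delimiter_keep_full_id(self, write_fasta_file):
        path = write_fasta_file([("plainheader", "MKT")])
        rec = read_fasta(path)[0]
        assert rec.id == "plainheader"
        assert rec.species == ""
        assert rec.family == ""

    def test_custom_delimiter(self, write_fasta_file):
        path = write_fasta_file([("fam;sp;id1", "MKT")])
        rec = read_fasta(path, delimiter=";")[0]
        assert (rec.family, rec.species, rec.id) == ("fam", "sp", "id1")

    @given(
        st.lists(
            st.text(alphabet=SEQ_ALPHABET, min_size=1, max_size=40),
            min_size=1,
            max_size=5,
        )
    )
    def test_roundtrip_identity(self, sequences):
        # property: read_fasta(write_fasta(records)) == records
        import tempfile, os

        records = [
            ProteinRecord(id=f"r{i}", species=f"sp{i}", family="fam", sequence=seq)
            for i, seq in enumerate(sequences)
        ]
        fd, path = tempfile.mkstemp(suffix=".fasta")
        os.close(fd)
        try:
            write_fasta(records, path)
            back = read_fasta(path)
        finally:
            os.unlink(path)
        assert [(r.id, r.species, r.family, r.sequence) for r in back] == [
            (r.id, r.species, r.family, r.sequence) for r in records
        ]


class TestSignalCleavage:
    def test_prefix_removed(self):
        rec = ProteinRecord(id="r", species="s", family="f", sequence="MKWVTAG")
        assert apply_signal_cleavage(rec, 3).sequence == "VTAG"

    def test_zero_is_identity(self):
        rec = ProteinRecord(id="r", species="s", family="f", sequence="MKWVTAG")
        assert apply_signal_cleavage(rec, 0) is rec

    def test_ptm_positions_shifted(self):
        # oracle: residue at old position 5 of "MKWVTAG" is 'T'; after
        # removing 3 residues it sits at position 2 of "VTAG"
        rec = ProteinRecord(
            id="r", species="s", family="f", sequence="MKWVTAG",
            ptms=[PTMAnnotation(position=5, kind="phospho")],
        )
        mature = apply_signal_cleavage(rec, 3)
        assert mature.ptms[0].position == 2
        assert mature.sequence[mature.ptms[0].position - 1] == rec.sequence[5 - 1]

    def test_ptm_in_prefix_dropped_with_warning(self):
        rec = ProteinRecord(
            id="r", species="s", family="f", sequence="MKWVTAG",
            ptms=[PTMAnnotation(position=2, kind="glyco"), PTMAnnotation(position=6, kind="phospho")],
        )
        with pytest.warns(UserWarning, match="dropped 1 PTM"):
            mature = apply_signal_cleavage(rec, 3)
        assert [p.position for p in mature.ptms] == [3]

    def test_cleaving_whole_sequence_errors(self):
        rec = ProteinRecord(id="r", species="s", family="f", sequence="MKW")
        with pytest.raises(ValueError):
            apply_signal_cleavage(rec, 3)
        with pytest.raises(ValueError):
            apply_signal_cleavage(rec, 7)


class TestReadAlignment:
    def test_three_equal_rows(self, write_fasta_file):
        path = write_fasta_file(
            [("f|human|h", "AC-DE"), ("f|mouse|m", "ACKDE"), ("f|cow|c", "AC--E")],
            name="aln.fasta",
        )
        aln = read_alignment(path, "fasta")
        assert aln.species == ["human", "mouse", "cow"]
        assert aln.length == 5

    def test_ragged_rows_error_reports_lengths(self, write_fasta_file):
        path = write_fasta_file([("a", "ACDEFGHIKL"), ("b", "ACDEFGHIK")], name="ragged.fasta")
        with pytest.raises(ValueError, match="10"):
            read_alignment(path, "fasta")

    def test_clustal_equals_fasta(self, write_fasta_file, tmp_path):
        # oracle: round-trip the same alignment through both readers
        path = write_fasta_file(
            [("human", "AC-DE"), ("mouse", "ACKDE")], name="aln.fasta"
        )
        clustal_path = tmp_path / "aln.aln"
        AlignIO.convert(path, "fasta", clustal_path, "clustal")
        assert read_alignment(path, "fasta").rows == read_alignment(clustal_path, "clustal").rows

    def test_ungap_recovers_sequence(self, write_fasta_file):
        path = write_fasta_file([("f|sp|x", "A-C-D")], name="gapped.fasta")
        assert read_alignment(path).ungapped("sp") == "ACD"

    def test_unknown_format(self, write_fasta_file):
        path = write_fasta_file([("x", "AC")], name="x.fasta")
        with pytest.raises(ValueError, match="format"):
            read_alignment(path, "phylip")


class TestExtractAlignableRegion:
    def test_no_exclusive_gaps(self):
        aln = Alignment(rows={"A": "AC-DE", "B": "AC-DE"})
        assert extract_alignable_region(aln, "A", "B") == "ACDE"

    def test_column_scan_oracle(self):
        aln = Alignment(rows={"ref": "ACKDE", "other": "AC--E"})
        # oracle: column-by-column scan
        expected = "".join(
            r for r, o in zip("ACKDE", "AC--E") if r != "-" and o != "-"
        )
        assert expected == "ACE"
        assert extract_alignable_region(aln, "ref", "other") == expected

    def test_self_extraction_is_ungapped_row(self):
        aln = Alignment(rows={"A": "A--CD-E", "B": "GGGGGGG"})
        assert extract_alignable_region(aln, "A", "A") == aln.ungapped("A")

    def test_length_bounded_by_min_ungapped(self):
        aln = Alignment(rows={"A": "AC-DEF--", "B": "-CKD--GG"})
        region = extract_alignable_region(aln, "A", "B")
        assert len(region) <= min(len(aln.ungapped("A")), len(aln.ungapped("B")))

    def test_missing_species_errors(self):
        aln = Alignment(rows={"A": "AC"})
        with pytest.raises(KeyError, match="B"):
            extract_alignable_region(aln, "A", "B")


class TestSelectionTable:
    def _write(self, tmp_path, text, name="slr.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_well_formed(self, tmp_path):
        path = self._write(tmp_path, "site\tomega\tpvalue\n2\t1.5\t0.01\n1\t0.2\t0.9\n3\t3.0\t0.001\n")
        records = read_selection_table(path)
        assert [r.site for r in records] == [1, 2, 3]
        assert records[1].omega == 1.5

    def test_duplicate_site_errors(self, tmp_path):
        path = self._write(tmp_path, "site\tomega\tpvalue\n7\t1.0\t0.5\n7\t2.0\t0.1\n")
        with pytest.raises(ValueError, match="duplicate site 7"):
            read_selection_table(path)

    def test_missing_column_named(self, tmp_path):
        path = self._write(tmp_path, "site\tomega\n1\t1.0\n")
        with pytest.raises(ValueError, match="pvalue"):
            read_selection_table(path)

    def test_pvalue_out_of_range(self, tmp_path):
        path = self._write(tmp_path, "site\tomega\tpvalue\n1\t1.0\t1.2\n")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            read_selection_table(path)

    def test_negative_omega(self, tmp_path):
        path = self._write(tmp_path, "site\tomega\tpvalue\n1\t-0.5\t0.2\n")
        with pytest.raises(ValueError, match="omega"):
            read_selection_table(path)

    def test_extra_columns_tolerated(self, tmp_path):
        path = self._write(tmp_path, "site\tomega\tpvalue\tnote\textra\n1\t1.0\t0.5\thello\tzz\n")
        records = read_selection_table(path)
        assert records[0].note == "hello"


class TestSideTables:
    def test_cleavage_table(self, tmp_path):
        path = tmp_path / "cleave.tsv"
        path.write_text("id\tcleavage_pos\nP1\t21\nP2\t0\n")
        assert read_cleavage_table(path) == {"P1": 21, "P2": 0}

    def test_cleavage_table_missing_column(self, tmp_path):
        path = tmp_path / "cleave.tsv"
        path.write_text("id\tpos\nP1\t21\n")
        with pytest.raises(ValueError, match="cleavage_pos"):
            read_cleavage_table(path)

    def test_ptm_table_grouped(self, tmp_path):
        path = tmp_path / "ptm.tsv"
        path.write_text(
            "id\tposition\tkind\tevidence\nP1\t10\tphospho\texperimental\n"
            "P1\t20\tglyco\tpotential\nP2\t5\tphospho\tby_similarity\n"
        )
        table = read_ptm_table(path)
        assert len(table["P1"]) == 2
        assert table["P2"][0].evidence == "by_similarity"

    def test_ptm_vocabulary_enforced(self):
        with pytest.raises(ValueError):
            PTMAnnotation(position=1, kind="methyl")
        with pytest.raises(ValueError):
            PTMAnnotation(position=1, kind="phospho", evidence="guessed")
        with pytest.raises(ValueError):
            PTMAnnotation(position=0, kind="phospho")

    def test_record_rejects_ptm_beyond_end(self):
        with pytest.raises(ValueError, match="beyond"):
            ProteinRecord(
                id="r", species="s", family="f", sequence="MK",
                ptms=[PTMAnnotation(position=3, kind="phospho")],
            )
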