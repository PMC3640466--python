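"""Gapped sequences, gap-list mapping, alignments and sequence file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molkit import (
    AlignmentHandle, SequenceError, create_sequence, create_view,
    read_alignment, read_sequences, rule_based_process, write_alignment,
    write_sequences,
)
from molkit import fixtures as fx


def random_gapped(rng, max_len=40):
    n = int(rng.integers(1, max_len))
    return "".join(rng.choice(list("ACDEFGH-"), size=n))


class TestCreateSequence:
    def test_gap_list_by_inspection(self):
        assert create_sequence("s", "AB--C").gap_list == [(2, 2)]

    def test_alternating_gaps(self):
        assert create_sequence("s", "-A-A-").gap_list == \
            [(0, 1), (2, 1), (4, 1)]

    def test_illegal_character(self):
        with pytest.raises(SequenceError, match="illegal character"):
            create_sequence("s", "AB?C")

    def test_dot_normalised_and_uppercased(self):
        s = create_sequence("s", "a.c")
        assert s.string == "A-C"

    def test_gap_list_reconstructs_string(self, rng):
        for _ in range(200):
            s = create_sequence("s", random_gapped(rng))
            rebuilt = list("X" * len(s))
            for start, length in s.gap_list:
                for k in range(start, start + length):
                    rebuilt[k] = "-"
            assert [c == "-" for c in rebuilt] == \
                [c == "-" for c in s.string]


class TestMapping:
    def test_example_two_gaps_before(self):
        s = create_sequence("s", "AB--C")
        assert s.pos_to_residue_index(4) == 2
        assert s.pos_to_residue_index(2) is None

    def test_ungapped_is_identity_plus_offset(self):
        s = create_sequence("s", "ACDEF", offset=10)
        for pos in range(5):
            assert s.pos_to_residue_index(pos) == pos + 10

    def test_inverse_example(self):
        s = create_sequence("s", "AB--C")
        assert s.residue_index_to_pos(2) == 4

    def test_index_below_offset_rejected(self):
        s = create_sequence("s", "ABC", offset=5)
        with pytest.raises(IndexError):
            s.residue_index_to_pos(4)

    def test_pos_out_of_range(self):
        with pytest.raises(IndexError):
            create_sequence("s", "ABC").pos_to_residue_index(3)

    def test_matches_naive_scan_on_random_strings(self, rng):
        for _ in range(300):
            string = random_gapped(rng)
            s = create_sequence("s", string)
            for pos in range(len(string)):
                naive = (None if string[pos] == "-"
                         else pos - string[:pos].count("-"))
                assert s.pos_to_residue_index(pos) == naive

    def test_round_trip_bijection(self, rng):
        for _ in range(200):
            s = create_sequence("s", random_gapped(rng))
            for pos in range(len(s)):
                idx = s.pos_to_residue_index(pos)
                if idx is not None:
                    assert s.residue_index_to_pos(idx) == pos

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACDEFGH-", min_size=1, max_size=60))
    def test_mapping_bijection_property(self, string):
        seq = create_sequence("s", string)
        seen = set()
        for pos in range(len(string)):
            idx = seq.pos_to_residue_index(pos)
            if string[pos] == "-":
                assert idx is None
            else:
                assert idx not in seen
                seen.add(idx)
                assert seq.residue_index_to_pos(idx) == pos
        assert len(seen) == seq.non_gap_count

    def test_inspected_entries_bounded_by_gap_count(self, rng):
        # the efficiency contract: queries walk the gap list, not the string
        for _ in range(100):
            s = create_sequence("s", random_gapped(rng, max_len=120))
            n_gap_runs = len(s.gap_list)
            for pos in range(len(s)):
                s.map_stats.reset()
                s.pos_to_residue_index(pos)
                assert s.map_stats.entries_inspected <= n_gap_runs


class TestAttach:
    def make_attached(self, n=3, string=None):
        ent = fx.make_polyala_helix(n)
        rule_based_process(ent)
        view = create_view(ent, ent.atoms)
        s = create_sequence("s", string or "A" * n)
        s.attach_view(view)
        return s, view

    def test_attach_and_resolve(self):
        s, view = self.make_attached(3)
        res = s.residue_at_pos(1)
        assert res.number == 2

    def test_code_mismatch_reports_position(self):
        ent = fx.make_polyala_helix(3)
        rule_based_process(ent)
        view = create_view(ent, ent.atoms)
        s = create_sequence("s", "AVA")
        with pytest.raises(SequenceError, match="position 1"):
            s.attach_view(view)

    def test_count_mismatch(self):
        ent = fx.make_polyala_helix(3)
        view = create_view(ent, ent.atoms)
        s = create_sequence("s", "AAAA")
        with pytest.raises(SequenceError, match="3 residues"):
            s.attach_view(view)

    def test_gapped_attachment_maps_through_gaps(self):
        s, _ = self.make_attached(3, "A-AA")
        assert s.residue_at_pos(1) is None
        assert s.residue_at_pos(2).number == 2

    def test_x_matches_anything(self):
        s, _ = self.make_attached(3, "AXA")
        assert s.attached_view is not None


class TestAlignmentEditing:
    def make_aln(self):
        return AlignmentHandle([create_sequence("a", "ACDE"),
                                create_sequence("b", "AC-E")])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(SequenceError, match="length"):
            AlignmentHandle([create_sequence("a", "ACD"),
                             create_sequence("b", "AC")])

    def test_insert_gap_column_at_start(self):
        aln = self.make_aln()
        aln.insert_gap_column(0)
        assert aln[0].string == "-ACDE"
        assert aln[1].string == "-AC-E"

    def test_insert_then_remove_is_identity(self):
        aln = self.make_aln()
        aln.insert_gap_column(2)
        aln.remove_column(2)
        assert aln[0].string == "ACDE"
        assert aln[1].string == "AC-E"

    def test_remove_nongap_column_refused_unless_forced(self):
        aln = self.make_aln()
        with pytest.raises(SequenceError, match="force"):
            aln.remove_column(0)
        aln.remove_column(0, force=True)
        assert aln[0].string == "CDE"

    def test_column_access(self):
        assert self.make_aln().column(2) == ["D", "-"]

    def test_gap_lists_consistent_after_random_edits(self, rng):
        aln = AlignmentHandle([create_sequence("a", "ACDEFGHIKL"),
                               create_sequence("b", "ACDE-GHIKL"),
                               create_sequence("c", "A-DEFGHIK-")])
        for _ in range(50):
            pos = int(rng.integers(0, aln.length + 1))
            if rng.random() < 0.5 or aln.length < 2:
                aln.insert_gap_column(pos)
            else:
                aln.remove_column(int(rng.integers(0, aln.length)), force=True)
            for s in aln:
                assert s.gap_list == [
                    g for g in _runs(s.string)], s.string
        assert len({len(s.string) for s in aln}) == 1


def _runs(string):
    out, start = [], None
    for i, c in enumerate(string):
        if c == "-" and start is None:
            start = i
        elif c != "-" and start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(string) - start))
    return out


class TestFileIO:
    def test_fasta_read(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">s1\nACDEF\n>s2\nACD-F\n")
        seqs = read_sequences(p)
        assert len(seqs) == 2
        assert seqs[0].string == "ACDEF"
        assert seqs[1].string == "ACD-F"

    def test_fasta_round_trip(self, tmp_path):
        seqs = [create_sequence("a", "ACDEFGHIKLMNPQRSTVWY"),
                create_sequence("b", "ACD---HIKLMNPQRSTVWY")]
        p = tmp_path / "rt.fasta"
        write_sequences(seqs, p)
        back = read_sequences(p)
        assert [(s.name, s.string) for s in back] == \
            [(s.name, s.string) for s in seqs]

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">s\nAC\n>s\nAD\n")
        with pytest.raises(SequenceError, match="duplicate"):
            read_sequences(p)

    def test_clustal_blocks_concatenated(self, tmp_path):
        block1_a, block2_a = "A" * 60, "C" * 60
        block1_b, block2_b = "G" * 60, "T" * 60
        p = tmp_path / "two.aln"
        p.write_text(
            "CLUSTAL W (1.83) multiple sequence alignment\n\n"
            f"sq1             {block1_a}\nsq2             {block1_b}\n\n"
            f"sq1             {block2_a}\nsq2             {block2_b}\n")
        aln = read_alignment(p, "clustal")
        assert aln.length == 120
        # cross-format oracle: same alignment rendered as FASTA
        f = tmp_path / "same.fasta"
        f.write_text(f">sq1\n{block1_a}{block2_a}\n>sq2\n{block1_b}{block2_b}\n")
        ref = read_alignment(f, "fasta")
        assert [s.string for s in aln] == [s.string for s in ref]

    def test_ragged_clustal_rejected(self, tmp_path):
        p = tmp_path / "ragged.aln"
        p.write_text("CLUSTAL W\n\nsq1  ACDEF\nsq2  ACD\n")
        with pytest.raises(SequenceError):
            read_alignment(p, "clustal")

    def test_pir_round_trip_preserves_type(self, tmp_path):
        s = create_sequence("query", "ACDEF")
        s.pir_type = "F1"
        s.description = "test fragment"
        p = tmp_path / "one.pir"
        write_sequences([s], p, fmt="pir")
        back = read_sequences(p, fmt="pir")
        assert back[0].name == "query"
        assert back[0].string == "ACDEF"
        assert back[0].pir_type == "F1"
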