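"""Derived proteins, variable-position tables, repeats and motifs."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastidcompat import fixtures
from plastidcompat.io_formats import AnnotatedGenome, Feature
from plastidcompat.protein_analysis import (
    DerivedProtein,
    ProteinAlignment,
    align_proteins,
    column_to_residue,
    deletion_sizes,
    derive_protein,
    exclusive_differences,
    find_tandem_repeats,
    n_replaced_residues,
    parse_change,
    poly_run,
    read_variable_table,
    scan_zinc_finger,
    span_contains,
    ungap,
    variable_position_table,
    write_variable_table,
)

PEPT = st.text(alphabet="ABCD", min_size=0, max_size=30)


def _cds_genome(cds, gid="acc"):
    flank = "ACGTAC" * 5
    feat = Feature("locus", "CDS", len(flank), len(flank) + len(cds), "+")
    return AnnotatedGenome(id=gid, seq=flank + cds + flank, circular=False,
                           features=[feat])


class TestDeriveProtein:
    def test_minimal_cds(self):
        assert derive_protein(_cds_genome("ATGTAA"), "locus").seq == "M"

    def test_alternative_start_gives_579_residue_product(self):
        g = fixtures.accd_gene_genome(start_disrupted=True)
        p = derive_protein(g, "accD")
        assert len(p.seq) == 579
        assert p.start_mode == "alternative_downstream"
        full = derive_protein(fixtures.accd_gene_genome(), "accD")
        assert len(full.seq) == 590 and full.start_mode == "annotated"
        assert full.seq[11:] == p.seq  # shorter product = same frame

    def test_stop_disruption_reads_through(self):
        # annotated CDS ends without a stop; next in-frame stop is downstream
        flank = "ACGTAC" * 5
        cds = "ATGAAACTTCAA"  # M K L Q, no stop
        seq = flank + cds + "GTTTAA" + flank
        g = AnnotatedGenome(id="a", seq=seq, circular=False, features=[
            Feature("locus", "CDS", len(flank), len(flank) + len(cds), "+")])
        p = derive_protein(g, "locus")
        assert p.seq == "MKLQV"
        assert p.readthrough

    def test_no_alternative_start_errors(self):
        g = _cds_genome("CTT" * 70 + "TAA")
        with pytest.raises(ValueError, match="no alternative"):
            derive_protein(g, "locus")

    def test_missing_stop_before_sequence_end_errors(self):
        flank = "ACGTAC" * 5
        cds = "ATGAAACTT"
        seq = flank + cds + "GTTGTTG"  # no in-frame stop downstream
        g = AnnotatedGenome(id="a", seq=seq, circular=False, features=[
            Feature("locus", "CDS", len(flank), len(flank) + len(cds), "+")])
        with pytest.raises(ValueError, match="stop"):
            derive_protein(g, "locus")

    def test_stop_symbol_banned_in_container(self):
        with pytest.raises(ValueError):
            DerivedProtein("a", "l", "MK*L")


def _prot(acc, seq):
    return DerivedProtein(acc, "locus", seq)


class TestAlignProteins:
    def test_identical_sequences_have_no_variable_columns(self):
        aln = align_proteins([_prot("a", "MKLVST"), _prot("b", "MKLVST")])
        table = variable_position_table(aln, "a")
        assert table.rows == []

    def test_single_replacement_gives_one_column(self):
        aln = align_proteins([_prot("a", "MKLVSTWYHH"),
                              _prot("b", "MKLVATWYHH")])
        table = variable_position_table(aln, "a")
        assert len(table.rows) == 1
        row = table.rows[0]
        assert (row.kind, row.change, row.start) == ("replacement", "S>A", 5)

    def test_contiguous_deletion_gives_one_gap_block(self):
        base = "MKLVSTWYHHQRAGFPDE"
        aln = align_proteins([_prot("a", base),
                              _prot("b", base[:6] + base[12:])])
        table = variable_position_table(aln, "a")
        assert len(table.rows) == 1
        row = table.rows[0]
        assert row.kind == "deletion" and row.n_residues == 6

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_proteins([_prot("a", "MKL"), _prot("b", "")])

    def test_mixed_loci_rejected(self):
        with pytest.raises(ValueError, match="loci"):
            align_proteins([_prot("a", "MKL"),
                            DerivedProtein("b", "other", "MKL")])


class TestVariablePositionTables:
    def test_accd_table_reproduces_shipped_rows(self, accd_table):
        shipped = fixtures.load_table1()
        got = [(r.positions, r.change, tuple(accd_table.occurrence_sorted(
            r.occurrence))) for r in accd_table.rows]
        want = [(r.positions, r.change, tuple(shipped.occurrence_sorted(
            r.occurrence))) for r in shipped.rows]
        assert got == want

    def test_accd_alignment_statistics(self, accd_table):
        assert accd_table.alignment_length == 610
        assert accd_table.n_variable_positions == 19
        assert accd_table.n_indel_columns == 80

    def test_bccp3_table_reproduces_shipped_rows(self, bccp3_table):
        shipped = fixtures.load_table2()
        got = [(r.positions, r.change) for r in bccp3_table.rows]
        want = [(r.positions, r.change) for r in shipped.rows]
        assert got == want
        assert bccp3_table.n_variable_positions == 9
        assert bccp3_table.n_indel_columns == 0

    def test_single_sequence_alignment_gives_empty_table(self):
        aln = ProteinAlignment("locus", ["a"], ["MKLV"])
        assert variable_position_table(aln, "a").rows == []

    def test_tsv_roundtrip(self, accd_table, tmp_path):
        path = tmp_path / "table.tsv"
        write_variable_table(accd_table, path,
                             exclusive_target=set(fixtures.INCOMPATIBLE))
        again = read_variable_table(path, "accD", fixtures.REFERENCE,
                                    610, fixtures.ACCESSIONS)
        assert [(r.positions, r.change) for r in again.rows] == [
            (r.positions, r.change) for r in accd_table.rows]

    def test_parse_change_forms(self):
        assert parse_change("SD>IH") == ("replacement", "SD", "IH")
        assert parse_change("del 31 AA") == ("deletion", "", "")
        assert parse_change("ins Q") == ("insertion", "", "Q")
        assert parse_change("absence of MIN (3 AA)") == ("absence", "MIN", "")
        with pytest.raises(ValueError):
            parse_change("gibberish")


class TestExclusiveDifferences:
    def test_accd_exclusive_set(self, accd_table):
        excl = exclusive_differences(accd_table, fixtures.INCOMPATIBLE,
                                     fixtures.COMPATIBLE)
        assert n_replaced_residues(excl) == 7
        assert deletion_sizes(excl) == [8, 1, 3]

    def test_bccp3_exclusive_set_in_biotinyl_domain(self, bccp3_table):
        excl = exclusive_differences(bccp3_table, fixtures.INCOMPATIBLE,
                                     fixtures.COMPATIBLE)
        assert [r.start for r in excl.rows] == [211, 252, 254, 279]
        lo, hi = fixtures.BIOTINYL_DOMAIN
        assert all(lo <= r.start <= r.end <= hi for r in excl.rows)

    def test_target_and_complement_are_disjoint(self, accd_table):
        a = exclusive_differences(accd_table, fixtures.INCOMPATIBLE,
                                  fixtures.COMPATIBLE)
        b = exclusive_differences(accd_table, fixtures.COMPATIBLE,
                                  fixtures.INCOMPATIBLE)
        keys = lambda t: {(r.start, r.end, r.change) for r in t.rows}
        assert keys(a) & keys(b) == set()

    def test_overlapping_sets_rejected(self, accd_table):
        with pytest.raises(ValueError, match="overlap"):
            exclusive_differences(accd_table, {"L100"}, {"L100", "721"})

    def test_empty_table_gives_empty_subtable(self):
        from plastidcompat.protein_analysis import VariablePositionTable
        t = VariablePositionTable("l", "r", 100, ["r", "a", "b"], [])
        assert exclusive_differences(t, {"a"}, {"b"}).rows == []


def _repeat_oracle(seq, lo, hi):
    """Independent triple enumeration: every maximal (start, unit, copies)."""
    found = set()
    for k in range(lo, hi + 1):
        for i in range(len(seq) - 2 * k + 1):
            unit = seq[i:i + k]
            if i >= k and seq[i - k:i] == unit:
                continue
            copies = 1
            while seq[i + copies * k: i + copies * k + k] == unit:
                copies += 1
            if copies >= 2:
                found.add((i, k, copies))
    return found


class TestRepeatsAndMotifs:
    def test_isdtnd_duplication_found(self, accd_alignment):
        seq = ungap(accd_alignment.row("VIR320"))
        hits = [r for r in find_tandem_repeats(seq, (6, 6))
                if r.unit == "ISDTND"]
        assert any(r.copies == 2 for r in hits)
        assert fixtures.isdtnd_copies(accd_alignment, "VIR320") == 2
        assert fixtures.isdtnd_copies(accd_alignment, "721") == 1

    def test_repeat_free_string_gives_nothing(self):
        assert find_tandem_repeats("ABCDEFGHIJKLMNOPQRSTUVWXYZABCD"[:30],
                                   (2, 10)) == []

    @settings(derandomize=True, max_examples=120)
    @given(seq=PEPT)
    def test_matches_exhaustive_oracle(self, seq):
        if len(seq) < 2:
            return
        hi = max(1, len(seq) // 2)
        got = {(r.start, r.unit_length, r.copies)
               for r in find_tandem_repeats(seq, (1, hi))}
        assert got == _repeat_oracle(seq, 1, hi)

    def test_poly_e_lengths_across_accessions(self, accd_alignment):
        lengths = {acc: poly_run(ungap(accd_alignment.row(acc)), "E").length
                   for acc in accd_alignment.ids}
        assert lengths == {"WL1238": 3, "JI1794": 3, "721": 6,
                           "L100": 4, "VIR320": 3}

    def test_poly_run_absent_residue(self):
        assert poly_run("MKLV", "E") == (0, 0, 0)

    @settings(derandomize=True, max_examples=80)
    @given(seq=PEPT, residue=st.sampled_from("ABCD"))
    def test_poly_run_matches_regex_oracle(self, seq, residue):
        runs = [(m.start(), m.end()) for m in re.finditer(f"{residue}+", seq)]
        best = max(runs, key=lambda t: t[1] - t[0], default=(0, 0))
        got = poly_run(seq, residue)
        assert got.length == best[1] - best[0]
        if got.length:
            assert (got.start, got.end) == best

    def test_zinc_finger_single_constructed_motif(self):
        seq = "C" + "AA" + "C" + "A" * 15 + "C" + "AA" + "C"
        assert scan_zinc_finger(seq) == [(0, 24)]
        assert scan_zinc_finger("MKLVST" * 5) == []

    def test_zinc_finger_contains_the_240_column(self, accd_alignment):
        row = accd_alignment.row("WL1238")
        spans = scan_zinc_finger(ungap(row))
        assert len(spans) == 1
        res = column_to_residue(row, 240)
        assert span_contains(spans[0], res - 1)
        assert not span_contains(spans[0], column_to_residue(row, 559) - 1)
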