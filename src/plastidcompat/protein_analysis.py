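"""Derived-protein construction and protein-alignment difference tables.

This module reproduces the protein-level workflow used to compare allelic
variants of a plastid or nuclear locus across accessions:

* translate each allele into its *derived protein*, handling two biological
  complications seen at hypervariable plastid loci: a disrupted annotated
  start codon (translation restarts at the first in-frame ATG downstream)
  and a disrupted stop codon (translation reads through to the next
  in-frame stop);
* align the derived proteins and tabulate every variable position against a
  chosen reference accession, merging adjacent columns that change in the
  same accessions into multi-residue rows — the familiar
  "positions / amino-acid change / occurrence" table layout;
* filter that table for *exclusive* differences: rows carried by exactly a
  target set of accessions and nobody else (the determinant-candidate
  filter);
* annotate tandem peptide repeats, homopolymer runs (e.g. poly-E
  stretches), and the CX2CX15CX2C zinc-finger motif.

All table coordinates are 1-based alignment columns, matching how such
tables are printed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import AnnotatedGenome, revcomp
from .variant_screen import PLASTID_TABLE, STOP_CODONS

START_SCAN_CODONS = 60  # how far downstream to look for an alternative ATG


@dataclass(frozen=True)
class DerivedProtein:
    """The polypeptide derived from one allele of a CDS locus."""

    accession: str
    locus: str
    seq: str
    start_mode: str = "annotated"  # or "alternative_downstream"
    readthrough: bool = False

    def __post_init__(self):
        if "*" in self.seq:
            raise ValueError("derived protein contains a stop symbol")


def derive_protein(genome: AnnotatedGenome, locus: str) -> DerivedProtein:
    """Translate the annotated CDS ``locus`` under the plastid genetic code.

    If the annotated start codon is not ATG, the first in-frame ATG within
    ``START_SCAN_CODONS`` codons is used instead (``alternative_downstream``);
    if no stop codon terminates the annotated frame, translation extends
    into downstream genomic sequence to the next in-frame stop
    (``readthrough=True``).
    """
    feat = genome.feature_by_locus(locus)
    if feat.kind != "CDS":
        raise ValueError(f"{locus!r} is not an annotated CDS")
    if feat.strand == "+":
        nt = genome.seq[feat.start:]
        limit = feat.end - feat.start
    else:
        nt = revcomp(genome.seq[: feat.end])
        limit = feat.end - feat.start

    start_mode = "annotated"
    offset = 0
    if nt[0:3] != "ATG":
        for codon_i in range(1, START_SCAN_CODONS + 1):
            if nt[3 * codon_i: 3 * codon_i + 3] == "ATG":
                offset = 3 * codon_i
                start_mode = "alternative_downstream"
                break
        else:
            raise ValueError(
                f"{locus!r} in {genome.id!r}: annotated start codon disrupted and "
                f"no alternative in-frame ATG within {START_SCAN_CODONS} codons"
            )

    aa: list[str] = []
    readthrough = False
    i = offset
    while True:
        codon = nt[i: i + 3]
        if len(codon) < 3:
            raise ValueError(
                f"{locus!r} in {genome.id!r}: no in-frame stop codon before "
                f"sequence end"
            )
        if codon in STOP_CODONS:
            break
        if i + 3 > limit:
            readthrough = True
        aa.append(PLASTID_TABLE.forward_table.get(codon, "X"))
        i += 3
    return DerivedProtein(genome.id, locus, "".join(aa), start_mode, readthrough)


# ---------------------------------------------------------------------------
# alignment


@dataclass
class ProteinAlignment:
    """A gapped multiple alignment: one equal-length row per accession."""

    locus: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, accession: str) -> str:
        return self.rows[self.ids.index(accession)]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def align_proteins(proteins: Sequence[DerivedProtein]) -> ProteinAlignment:
    """Multiple alignment of derived proteins of one locus.

    Deterministic center-star scheme: every sequence is globally aligned
    (Needleman-Wunsch, BLOSUM62, affine gaps) to the first sequence, and the
    pairwise alignments are merged on the center's coordinates, allotting
    each center position the longest insertion observed.  Input order is the
    tie-break, so a fixed accession order gives a fixed alignment.
    """
    if len(proteins) < 2:
        raise ValueError("alignment needs at least two sequences")
    loci = {p.locus for p in proteins}
    if len(loci) > 1:
        raise ValueError(f"cannot align different loci: {sorted(loci)}")
    for p in proteins:
        if not p.seq:
            raise ValueError(f"empty sequence for accession {p.accession!r}")

    center = proteins[0].seq
    aligner = _make_aligner()
    pairs = []
    for p in proteins[1:]:
        aln = aligner.align(center, p.seq)[0]
        pairs.append((str(aln[0]), str(aln[1])))

    # insertion length relative to center before each center position
    # (index 0..len(center); len(center) = insertions after the last residue)
    ins = [0] * (len(center) + 1)
    per_seq: list[tuple[list[str], list[str]]] = []  # (inserts, aligned residues)
    for crow, qrow in pairs:
        inserts = [""] * (len(center) + 1)
        aligned = [""] * len(center)
        cpos = 0
        for c, q in zip(crow, qrow):
            if c == "-":
                inserts[cpos] += q
            else:
                aligned[cpos] = q
                cpos += 1
        per_seq.append((inserts, aligned))
        for i, s in enumerate(inserts):
            ins[i] = max(ins[i], len(s))

    def build_row(inserts, aligned):
        out = []
        for i in range(len(center)):
            out.append(inserts[i].ljust(ins[i], "-"))
            out.append(aligned[i])
        out.append(inserts[len(center)].ljust(ins[len(center)], "-"))
        return "".join(out)

    rows = [build_row([""] * (len(center) + 1), list(center))]
    for inserts, aligned in per_seq:
        rows.append(build_row(inserts, aligned))
    return ProteinAlignment(proteins[0].locus, [p.accession for p in proteins], rows)


# ---------------------------------------------------------------------------
# variable-position tables


@dataclass(frozen=True)
class VariableRow:
    """One row of a variable-position table.

    ``start``/``end`` are 1-based inclusive alignment columns; ``kind`` is
    replacement / deletion / insertion / absence (N-terminal deletion) /
    addition (C-terminal extension); ``occurrence`` is the set of accessions
    carrying the change.
    """

    start: int
    end: int
    kind: str
    ref_residues: str  # residues of the reference over the span ("" for ins)
    alt_residues: str  # residues carried by the occurrence set ("" for del)
    occurrence: frozenset[str]

    @property
    def positions(self) -> str:
        return str(self.start) if self.start == self.end else f"{self.start}-{self.end}"

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1

    @property
    def change(self) -> str:
        k = self.n_residues
        if self.kind == "replacement":
            return f"{self.ref_residues}>{self.alt_residues}"
        if self.kind == "absence":
            return f"absence of {self.ref_residues} ({k} AA)"
        if self.kind == "addition":
            return f"addition of {self.alt_residues} ({k} AA)"
        if self.kind == "deletion":
            if k == 1:
                return f"del {self.ref_residues}"
            if k <= 10:
                return f"del {self.ref_residues} ({k} AA)"
            return f"del {k} AA"
        if self.kind == "insertion":
            if k == 1:
                return f"ins {self.alt_residues}"
            if k <= 10:
                return f"ins {self.alt_residues} ({k} AA)"
            return f"ins {k} AA"
        raise ValueError(self.kind)


@dataclass
class VariablePositionTable:
    locus: str
    reference: str
    alignment_length: int
    accession_order: list[str]
    rows: list[VariableRow]

    def __post_init__(self):
        for r in self.rows:
            if not (1 <= r.start <= r.end <= self.alignment_length):
                raise ValueError(
                    f"row {r.positions} outside alignment of length "
                    f"{self.alignment_length}"
                )

    @property
    def n_variable_positions(self) -> int:
        """Distinct alignment columns carrying at least one replacement."""
        cols: set[int] = set()
        for r in self.rows:
            if r.kind == "replacement":
                cols.update(range(r.start, r.end + 1))
        return len(cols)

    @property
    def n_indel_columns(self) -> int:
        """Distinct alignment columns covered by indel-type rows."""
        cols: set[int] = set()
        for r in self.rows:
            if r.kind != "replacement":
                cols.update(range(r.start, r.end + 1))
        return len(cols)

    def occurrence_sorted(self, occ: frozenset[str]) -> list[str]:
        return [a for a in self.accession_order if a in occ]


def variable_position_table(
    alignment: ProteinAlignment, reference: str
) -> VariablePositionTable:
    """Tabulate all differences in the alignment against ``reference``.

    Column-wise events (replacement to a given residue, deletion,
    insertion of a given residue) are grouped by the set of accessions
    carrying them, and maximal runs of adjacent columns with identical
    occurrence sets merge into one row (e.g. a two-residue replacement
    "SD>IH", or an 8-residue deletion).  Within a reference gap block,
    differing inserted residues split into separate rows, so two accessions
    inserting different residues at the same column yield two rows.
    """
    if reference not in alignment.ids:
        raise ValueError(f"reference {reference!r} not in alignment")
    ref_row = alignment.row(reference)
    others = [a for a in alignment.ids if a != reference]
    n = alignment.length

    # per-column atomic events: (kind, ref_char, alt_char) -> accession set
    events: list[dict[tuple[str, str, str], set[str]]] = []
    for c in range(n):
        col_events: dict[tuple[str, str, str], set[str]] = {}
        r = ref_row[c]
        for acc in others:
            a = alignment.row(acc)[c]
            if a == r:
                continue
            if r != "-" and a != "-":
                key = ("replacement", r, a)
            elif a == "-":
                key = ("deletion", r, "")
            else:
                key = ("insertion", "", a)
            col_events.setdefault(key, set()).add(acc)
        events.append(col_events)

    rows: list[VariableRow] = []
    open_runs: dict[tuple[str, frozenset], list] = {}
    for c in range(n):
        col = {
            (kind, frozenset(accs)): (rchar, achar)
            for (kind, rchar, achar), accs in events[c].items()
        }
        # close runs not continued in this column
        for key in list(open_runs):
            if key not in col:
                rows.append(_close_run(open_runs.pop(key), n))
        for (kind, occ), (rchar, achar) in col.items():
            key = (kind, occ)
            if key in open_runs:
                run = open_runs[key]
                run[2] = c
                run[3] += rchar
                run[4] += achar
            else:
                open_runs[key] = [kind, c, c, rchar, achar, occ]
    for run in open_runs.values():
        rows.append(_close_run(run, n))

    rows.sort(key=lambda r: (r.start, r.end, r.change))
    return VariablePositionTable(
        locus=alignment.locus,
        reference=reference,
        alignment_length=n,
        accession_order=list(alignment.ids),
        rows=rows,
    )


def _close_run(run: list, aln_len: int) -> VariableRow:
    kind, start, end, rres, ares, occ = run
    if kind == "deletion" and start == 0:
        kind = "absence"
    if kind == "insertion" and end == aln_len - 1:
        kind = "addition"
    return VariableRow(start + 1, end + 1, kind, rres, ares, occ)


def exclusive_differences(
    table: VariablePositionTable,
    target: Iterable[str],
    others: Iterable[str],
) -> VariablePositionTable:
    """Rows whose occurrence set is exactly the target accession set.

    ``others`` names the remaining accessions; it must be disjoint from
    ``target`` and is used only for validation — exclusivity means the row
    occurs in every target accession and in no other accession at all.
    """
    target = set(target)
    others = set(others)
    if not target or not others:
        raise ValueError("target and others must both be nonempty")
    if target & others:
        raise ValueError(f"target and others overlap: {sorted(target & others)}")
    rows = [r for r in table.rows if set(r.occurrence) == target]
    return VariablePositionTable(
        table.locus, table.reference, table.alignment_length,
        table.accession_order, rows,
    )


def n_replaced_residues(table: VariablePositionTable) -> int:
    """Residues replaced, counting each residue of a multi-residue row."""
    return sum(r.n_residues for r in table.rows if r.kind == "replacement")


def deletion_sizes(table: VariablePositionTable) -> list[int]:
    return [r.n_residues for r in table.rows if r.kind in ("deletion", "absence")]


# ---------------------------------------------------------------------------
# reconstruction from a reference profile + table rows (the fixture path)


def reconstruct_alignment(
    locus: str,
    reference: str,
    reference_row: str,
    accessions: Sequence[str],
    rows: Iterable[VariableRow],
) -> ProteinAlignment:
    """Rebuild the full multiple alignment from the reference's (gapped)
    alignment row plus a variable-position table.

    Inverse of :func:`variable_position_table`: applying the reconstruction
    and re-tabulating reproduces the table row-for-row.
    """
    others = [a for a in accessions if a != reference]
    mats = {acc: list(reference_row) for acc in others}
    for row in rows:
        span = range(row.start - 1, row.end)
        for acc in row.occurrence:
            if acc == reference:
                continue
            m = mats[acc]
            if row.kind in ("deletion", "absence"):
                for c in span:
                    m[c] = "-"
            elif row.kind == "replacement":
                for i, c in enumerate(span):
                    m[c] = row.alt_residues[i]
            else:  # insertion / addition
                for i, c in enumerate(span):
                    m[c] = row.alt_residues[i] if row.alt_residues else "X"
    return ProteinAlignment(locus, [reference, *others],
                            [reference_row, *("".join(mats[a]) for a in others)])


def ungap(row: str) -> str:
    return row.replace("-", "")


# ---------------------------------------------------------------------------
# variable-table TSV interchange

_CHANGE_RE = re.compile(
    r"^(?:(?P<ref>[A-Z]+)>(?P<alt>[A-Z]+)"
    r"|(?P<kind>del|ins|absence of|addition of)\s*(?P<res>[A-Z]*)"
    r"(?:\s*\((?P<k>\d+) AA\))?(?:\s*AA)?)$"
)


def parse_change(change: str) -> tuple[str, str, str]:
    """Parse a change descriptor into (kind, ref_residues, alt_residues).

    Accepts the printed forms: "D>H", "SD>IH", "del E", "del ISDTND (6 AA)",
    "del 31 AA", "ins Q", "absence of ... (11 AA)", "addition of ... (8 AA)".
    """
    text = change.strip()
    m = re.match(r"^(del|ins)\s+(\d+)\s+AA$", text)
    if m:  # residues not listed for long indels
        return ("deletion" if m.group(1) == "del" else "insertion", "", "")
    m = _CHANGE_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse change descriptor {change!r}")
    if m.group("ref"):
        return ("replacement", m.group("ref"), m.group("alt"))
    kind = {"del": "deletion", "ins": "insertion",
            "absence of": "absence", "addition of": "addition"}[m.group("kind")]
    res = m.group("res") or ""
    if kind in ("deletion", "absence"):
        return (kind, res, "")
    return (kind, "", res)


def parse_positions(positions: str) -> tuple[int, int]:
    text = positions.strip().replace("–", "-")
    if "-" in text:
        a, b = text.split("-")
        return int(a), int(b)
    return int(text), int(text)


def read_variable_table(
    path,
    locus: str,
    reference: str,
    alignment_length: int,
    accession_order: Sequence[str],
) -> VariablePositionTable:
    """Read a variable-position TSV (columns: positions, change, accessions,
    exclusive); alignment metadata is supplied by the caller."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    rows = []
    for _, r in df.iterrows():
        start, end = parse_positions(r["positions"])
        kind, ref_res, alt_res = parse_change(r["change"])
        occ = frozenset(x.strip() for x in r["accessions"].split(","))
        rows.append(VariableRow(start, end, kind, ref_res, alt_res, occ))
    return VariablePositionTable(locus, reference, alignment_length,
                                 list(accession_order), rows)


def write_variable_table(
    table: VariablePositionTable, path, exclusive_target=None
) -> None:
    import pandas as pd

    target = set(exclusive_target) if exclusive_target else None
    recs = []
    for r in table.rows:
        recs.append({
            "positions": r.positions,
            "change": r.change,
            "accessions": ",".join(table.occurrence_sorted(r.occurrence)),
            "exclusive": int(target is not None and set(r.occurrence) == target),
        })
    pd.DataFrame(recs, columns=["positions", "change", "accessions", "exclusive"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# repeats and motifs


@dataclass(frozen=True)
class RepeatAnnotation:
    """A maximal tandem array: ``copies`` adjacent copies of ``unit``
    starting at 0-based position ``start``."""

    unit: str
    unit_length: int
    copies: int
    start: int
    kind: str  # tandem_repeat | homopolymer_run

    @property
    def end(self) -> int:
        return self.start + self.unit_length * self.copies

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def find_tandem_repeats(
    seq: str, unit_len_range: tuple[int, int] | None = None
) -> list[RepeatAnnotation]:
    """All maximal tandem arrays (copies >= 2) with unit length in range.

    An array (start, unit_len, copies) is maximal when the copy count is
    the largest possible at that start and the array cannot be extended by
    a full unit to the left.  Overlapping arrays of different unit lengths
    are all reported.
    """
    n = len(seq)
    if unit_len_range is None:
        unit_len_range = (1, max(1, n // 2))
    lo, hi = unit_len_range
    if lo < 1 or hi > n // 2:
        raise ValueError(f"unit length range ({lo}, {hi}) outside [1, {n // 2}]")
    out = []
    for k in range(lo, hi + 1):
        for i in range(0, n - 2 * k + 1):
            unit = seq[i: i + k]
            if i >= k and seq[i - k: i] == unit:
                continue  # extendable to the left: not a maximal start
            copies = 1
            while seq[i + copies * k: i + (copies + 1) * k] == unit:
                copies += 1
            if copies >= 2:
                out.append(RepeatAnnotation(
                    unit=unit, unit_length=k, copies=copies, start=i,
                    kind="homopolymer_run" if k == 1 else "tandem_repeat",
                ))
    out.sort(key=lambda r: (r.start, r.unit_length))
    return out


class PolyRun(NamedTuple):
    length: int
    start: int
    end: int  # half-open; (0, 0) when the residue does not occur


def poly_run(seq: str, residue: str) -> PolyRun:
    """Longest run of ``residue`` in ``seq`` (leftmost on ties)."""
    if len(residue) != 1:
        raise ValueError("residue must be a single amino-acid letter")
    best = PolyRun(0, 0, 0)
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == residue:
            j = i
            while j < n and seq[j] == residue:
                j += 1
            if j - i > best.length:
                best = PolyRun(j - i, i, j)
            i = j
        else:
            i += 1
    return best


ZINC_FINGER = re.compile(r"(?=(C.{2}C.{15}C.{2}C))")
ZINC_FINGER_LEN = 24


def scan_zinc_finger(seq: str) -> list[tuple[int, int]]:
    """All spans matching the CX2CX15CX2C motif (fixed spacing, overlaps
    allowed); 0-based half-open spans."""
    return [(m.start(), m.start() + ZINC_FINGER_LEN)
            for m in ZINC_FINGER.finditer(seq)]


def span_contains(span: tuple[int, int], pos: int) -> bool:
    """Is a 0-based position inside a half-open span?"""
    return span[0] <= pos < span[1]


def column_to_residue(row: str, col: int) -> int:
    """Map a 1-based alignment column to the 1-based residue index in the
    ungapped sequence of ``row``; errors if the column is a gap."""
    if not 1 <= col <= len(row):
        raise ValueError(f"column {col} outside alignment of length {len(row)}")
    if row[col - 1] == "-":
        raise ValueError(f"column {col} is a gap in this sequence")
    return col - row[:col].count("-")
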