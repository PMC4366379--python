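"""Reference fixtures for the five-accession pea study design.

The study compares one cultivated tester line (WL1238, the reference) with
four wild accessions: JI1794 and 721 (cytoplasm compatible with the
tester's nucleus) and VIR320 and L100 (cytoplasm incompatible).  The
variable-position tables for the plastid accD product and the nuclear
Bccp3 (BCCP) product are shipped as TSV assets; the full protein
alignments are reconstructed from those tables on top of *synthetic*
reference profiles.

The reference profiles are synthetic stand-ins: the published alignment
figures are not machine-readable, so the WL1238 accD (590 aa over a
610-column alignment) and Bccp3 (290 aa) sequences are generated here to
satisfy every tabulated constraint — the residues named in the change
rows, the tandemly duplicated ISDTND hexapeptide at alignment columns
124-135 plus its extra copy at 151-156, the poly-E stretch whose length
differs among accessions (3 in WL1238/JI1794/VIR320, 4 in L100, 6 in 721),
a CX2CX15CX2C zinc-finger motif containing column 240, and a methionine at
residue 12 so that loss of the annotated start yields a 579-residue
alternative-start product.  Filler positions use a deterministic
pseudo-random choice from an alphabet excluding E, C and the ISDTND
letters, so none of the motif-bearing features can arise by accident.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .compatibility_model import CrossOutcome, DeterminantGenotype
from .io_formats import AnnotatedGenome, Feature
from .linkage import RILTable
from .protein_analysis import (
    ProteinAlignment,
    VariablePositionTable,
    read_variable_table,
    reconstruct_alignment,
    ungap,
)

#: Fixed accession order (reference first); also the alignment input order.
ACCESSIONS = ("WL1238", "JI1794", "721", "L100", "VIR320")
REFERENCE = "WL1238"
INCOMPATIBLE = ("VIR320", "L100")
COMPATIBLE = ("721", "JI1794")

ACCD_ALIGNMENT_LENGTH = 610
BCCP3_ALIGNMENT_LENGTH = 290
#: alignment columns of the tandemly duplicated ISDTND hexapeptide
ISDTND_REGION = (124, 135)
#: Bccp3 alignment columns of the biotinyl (biotin-attachment) domain
BIOTINYL_DOMAIN = (196, 290)

_FILLER_ALPHABET = "GALVFWPHKRQYM"  # no E, C, I, S, D, T, N


def _fill(row: dict[int, str], length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(_FILLER_ALPHABET), size=length)
    return "".join(row.get(c, letters[c - 1]) for c in range(1, length + 1))


def accd_reference_row() -> str:
    """WL1238 accD row of the 610-column alignment (synthetic; 590 aa ungapped).

    Gap columns 141-143, 175-180, 399-401 and 603-610 hold the insertions /
    C-terminal addition seen only in other accessions.
    """
    row: dict[int, str] = {}

    def seg(start: int, residues: str):
        for i, aa in enumerate(residues):
            row[start + i] = aa

    for lo, hi in [(141, 143), (175, 180), (399, 401), (603, 610)]:
        for c in range(lo, hi + 1):
            row[c] = "-"
    seg(1, "MINEDPSSLTD")         # residues absent from the wild alleles
    seg(12, "M")                  # the alternative start (579-aa product)
    seg(46, "DKI")
    seg(109, "R")
    seg(112, "I")
    seg(116, "R")
    seg(124, "ISDTNDISDTND")      # tandem duplication, columns 124-135
    seg(136, "DTN")
    seg(151, "ISDTND")            # near-identical extra copy, all accessions
    seg(196, "TNIKDICE")
    seg(210, "P")
    seg(214, "E")
    seg(224, "SD")
    seg(228, "C")                 # zinc finger CX2CX15CX2C: 228/231/247/250
    seg(231, "C")
    seg(240, "E")                 # the E>R change sits inside the motif
    seg(247, "C")
    seg(249, "Q")
    seg(250, "C")
    seg(340, "EEE")
    seg(345, "Q")
    seg(375, "HP")
    seg(379, "E")
    seg(383, "N")
    seg(384, "Q")
    seg(402, "EEE")               # poly-E stretch next to the 399-401 gap
    seg(407, "Q")
    seg(559, "E")
    return _fill(row, ACCD_ALIGNMENT_LENGTH, seed=11)


def bccp3_reference_row() -> str:
    """WL1238 Bccp3 row (synthetic; 290 aa, no gaps in the alignment)."""
    row: dict[int, str] = {}
    for col, aa in [(1, "M"), (70, "T"), (130, "M"), (135, "S"), (159, "M"),
                    (179, "A"), (211, "M"), (252, "H"), (254, "V"), (279, "M")]:
        row[col] = aa
    return _fill(row, BCCP3_ALIGNMENT_LENGTH, seed=13)


def _data_path(name: str):
    return resources.files("plastidcompat") / "data" / name


def load_table1() -> VariablePositionTable:
    """The shipped accD variable-position table (29 rows)."""
    with resources.as_file(_data_path("table1_accd.tsv")) as p:
        return read_variable_table(p, "accD", REFERENCE,
                                   ACCD_ALIGNMENT_LENGTH, ACCESSIONS)


def load_table2() -> VariablePositionTable:
    """The shipped Bccp3 variable-position table (10 rows, 9 positions)."""
    with resources.as_file(_data_path("table2_bccp3.tsv")) as p:
        return read_variable_table(p, "Bccp3", REFERENCE,
                                   BCCP3_ALIGNMENT_LENGTH, ACCESSIONS)


def accd_alignment() -> ProteinAlignment:
    """Five-accession accD protein alignment reconstructed from the table."""
    return reconstruct_alignment("accD", REFERENCE, accd_reference_row(),
                                 ACCESSIONS, load_table1().rows)


def bccp3_alignment() -> ProteinAlignment:
    return reconstruct_alignment("Bccp3", REFERENCE, bccp3_reference_row(),
                                 ACCESSIONS, load_table2().rows)


def isdtnd_copies(alignment: ProteinAlignment, accession: str,
                  region: tuple[int, int] = ISDTND_REGION) -> int:
    """Tandem copies of the ISDTND hexapeptide within an alignment region."""
    lo, hi = region
    segment = ungap(alignment.row(accession)[lo - 1: hi])
    return segment.count("ISDTND")


# ---------------------------------------------------------------------------
# nucleotide-level accD fixture (for derived-protein construction)

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def back_translate(protein: str) -> str:
    """Deterministic one-codon-per-residue reverse translation."""
    return "".join(_CODON[aa] for aa in protein)


def accd_gene_genome(start_disrupted: bool = False,
                     accession: str = REFERENCE) -> AnnotatedGenome:
    """A minimal genome carrying the accD CDS (590 codons + stop).

    With ``start_disrupted`` the first 11 codons are replaced by codons
    without an ATG, so the annotated start codon is lost and translation
    must restart at the in-frame ATG of residue 12, yielding the
    579-residue alternative-start product.
    """
    protein = ungap(accd_reference_row())
    cds = back_translate(protein) + "TAA"
    if start_disrupted:
        # 11 junk codons (no ATG, no stop) in place of codons 1-11
        cds = "CTT" * 11 + cds[33:]
    flank = "ACGTAC" * 20
    seq = flank + cds + flank
    feat = Feature("accD", "CDS", len(flank), len(flank) + len(cds), "+")
    return AnnotatedGenome(id=accession, seq=seq, circular=False, features=[feat])


# ---------------------------------------------------------------------------
# genome-size fixture (gap-length accounting)

VIR320_EFFECTIVE_LENGTH = 121_824  # resolved 121,529 bp + gaps of 258 + 37 bp


def gap_length_fixture(seed: int = 0) -> tuple[AnnotatedGenome, AnnotatedGenome]:
    """(query, reference) pair for the gap-aware length convention.

    The reference is a gap-free 122,180 bp sequence; the query genome has
    121,529 bp of resolved sequence plus two assembly gaps whose reference
    regions are 258 and 37 bp, so its effective length is 121,824 bp.
    """
    rng = np.random.default_rng(seed)
    ref_seq = "".join(rng.choice(list("ACGT"), size=122_180))
    a, b, d = 30_000, 70_000, 100_000  # gap 1, gap 2, plain deletion
    g1, g2 = 120, 80  # arbitrary N-run lengths of the two gaps
    # remove 258+37 bp at the gaps and 356 bp elsewhere: 122,180-651=121,529
    qseq = (ref_seq[:a] + "N" * g1 + ref_seq[a + 258: b] + "N" * g2
            + ref_seq[b + 37: d] + ref_seq[d + 356:])
    gap1 = (a, a + g1)
    gap2 = (a + g1 + (b - a - 258), a + g1 + (b - a - 258) + g2)
    query = AnnotatedGenome(id="VIR320", seq=qseq, gaps=[gap1, gap2])
    reference = AnnotatedGenome(id="WL1238", seq=ref_seq)
    return query, reference


# ---------------------------------------------------------------------------
# RIL mapping fixture (88 F6 lines, three LGIII loci + Scs1 assignment)

RIL_LOCI = ("PhlC", "Bccp3", "AJ832139")


def paper_ril_table() -> tuple[RILTable, pd.Series]:
    """The 88-line mapping population as described for the Bccp3 placement.

    Five lines are crossovers between PhlC and AJ832139; in three of them
    Bccp3 follows PhlC, in two it follows AJ832139.  The remaining 83 lines
    are non-recombinant.  The Scs1 phenotype-assigned genotype coincides
    with Bccp3 in every line.  Returns (table, scs1_assignments).
    """
    rows = []
    crossovers = [("A", "A", "B"), ("B", "B", "A"), ("A", "A", "B"),  # with PhlC
                  ("A", "B", "B"), ("B", "A", "A")]                    # with AJ
    for g in crossovers:
        rows.append(g)
    for i in range(83):
        allele = "A" if i % 2 == 0 else "B"
        rows.append((allele, allele, allele))
    lines = [f"RIL{i + 1:03d}" for i in range(88)]
    df = pd.DataFrame(rows, index=lines, columns=list(RIL_LOCI))
    scs1 = df["Bccp3"].copy()
    scs1.name = "Scs1"
    return RILTable(df), scs1


# ---------------------------------------------------------------------------
# determinant panel and observed crosses

def paper_determinant_panel() -> list[DeterminantGenotype]:
    """Determinant states of the five accessions under the rule model.

    cyt_secondary of VIR320 and L100 is masked by their primary determinant
    and is not identifiable from crosses; it is set here from the protein
    feature (ISDTND duplication present in VIR320, absent in L100).
    """
    return [
        DeterminantGenotype("WL1238", False, True, False, True),
        DeterminantGenotype("JI1794", False, True, False, True),
        DeterminantGenotype("721", False, False, False, False),
        DeterminantGenotype("L100", True, False, True, False),
        DeterminantGenotype("VIR320", True, True, True, True),
    ]


def paper_example_crosses(include_selfs: bool = False) -> list[CrossOutcome]:
    """The unambiguous example crosses (cytoplasm donor written first)."""
    listed = [
        ("VIR320", "L100", "compatible"),
        ("L100", "VIR320", "compatible"),
        ("VIR320", "WL1238", "incompatible"),
        ("VIR320", "JI1794", "incompatible"),
        ("VIR320", "721", "incompatible"),
        ("L100", "WL1238", "incompatible"),
        ("L100", "721", "incompatible"),
        ("WL1238", "VIR320", "compatible"),
        ("JI1794", "VIR320", "compatible"),
        ("WL1238", "JI1794", "compatible"),
        ("JI1794", "WL1238", "compatible"),
        ("WL1238", "721", "incompatible"),
        ("WL1238", "L100", "incompatible"),
        ("721", "WL1238", "partial"),
        ("721", "L100", "compatible"),
    ]
    out = [CrossOutcome(*t) for t in listed]
    if include_selfs:
        out += [CrossOutcome(a, a, "compatible") for a in ACCESSIONS]
    return out


# ---------------------------------------------------------------------------
# syntenic gene-interval table (synthetic emulation)

MEDICAGO_INTERVAL = (22_386_715, 23_539_540)
BCCP3_GENE_ID = "11410363"


def medicago_interval_table() -> pd.DataFrame:
    """Synthetic stand-in for the annotated Medicago truncatula chromosome 3
    interval between the phospholipase C and NSP2 anchor genes.

    166 genes, 70 of them "hypothetical protein"; the real anchor GeneIDs
    (11411269, 11406790), the BCCP gene (11410363), the chloroplast lumen
    common family protein (11418002) and holocarboxylase synthetase hcs2
    (11411288, ~535 kb from the BCCP gene) are included by identifier; all
    other records are synthetic filler.
    """
    lo, hi = MEDICAGO_INTERVAL
    n = 166
    gene_len = 2000
    starts = np.linspace(lo, hi - gene_len, n).astype(int)
    special = {
        0: ("11411269", "Phosphoinositide phospholipase C"),
        40: ("11418002", "Chloroplast lumen common family protein"),
        80: (BCCP3_GENE_ID,
             "Biotin carboxyl carrier protein of acetyl-CoA carboxylase"),
        157: ("11411288", "Holocarboxylase synthetase hcs2"),
        n - 1: ("11406790", "Nodulation-signaling pathway 2 protein"),
    }
    filler_desc = [
        "Serine/threonine protein kinase",
        "Pentatricopeptide repeat-containing protein",
        "ABC transporter family protein",
        "F-box family protein",
        "Cytochrome P450 family protein",
        "Leucine-rich repeat receptor-like kinase",
        "MYB transcription factor",
        "Ubiquitin-conjugating enzyme",
    ]
    rows = []
    n_hyp = 0
    fill_i = 0
    for i in range(n):
        if i in special:
            gid, desc = special[i]
        elif n_hyp < 70 and i % 2 == 1:
            gid, desc = f"9{i:07d}", "hypothetical protein"
            n_hyp += 1
        else:
            gid = f"9{i:07d}"
            desc = filler_desc[fill_i % len(filler_desc)]
            fill_i += 1
        rows.append({"gene_id": gid, "description": desc, "chrom": "NC_016409",
                     "start": int(starts[i]), "end": int(starts[i]) + gene_len})
    df = pd.DataFrame(rows, columns=["gene_id", "description", "chrom",
                                     "start", "end"])
    assert (df["description"] == "hypothetical protein").sum() == 70
    return df
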