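"""Genome containers and on-disk formats.

A plastome is represented as an :class:`AnnotatedGenome`: one circular DNA
sequence over ``{A, C, G, T, N}`` plus typed features (CDS, intron,
intergenic spacer) and assembly-gap spans.  Circular molecules are stored
linearized at the reference origin; all internal coordinates are 0-based
half-open, while every on-disk table and report uses 1-based inclusive
coordinates.

Also houses two small sequence utilities that belong with the raw-genome
layer: the gap-aware effective genome length (assembly gaps counted at the
length of the corresponding region of a gap-free reference, the convention
used for partially gapped plastome assemblies) and in-silico CAPS
(cleaved amplified polymorphic sequence) prediction for degenerate
restriction sites such as Fsp4HI ``GCNGC``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("CDS", "intron", "intergenic_spacer")

#: IUPAC nucleotide ambiguity codes -> concrete base sets.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeFormatError(ValueError):
    """Raised for malformed genome files or inconsistent annotations."""


@dataclass(frozen=True)
class Feature:
    """An annotated region of the plastome.

    ``kind`` determines downstream handling: variants in a CDS get a coding
    effect classification, variants in introns and intergenic spacers are
    noncoding by definition.
    """

    locus: str
    kind: str  # CDS | intron | intergenic_spacer
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"
    phase: int = 0

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise GenomeFormatError(
                f"feature {self.locus!r}: unsupported kind {self.kind!r}"
            )
        if self.strand not in "+-":
            raise GenomeFormatError(f"feature {self.locus!r}: bad strand")
        if self.end <= self.start:
            raise GenomeFormatError(f"feature {self.locus!r}: empty span")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class AnnotatedGenome:
    """A (linearized) circular plastome with features and assembly gaps.

    gaps are ``(start, end)`` half-open spans that must contain only ``N``.
    """

    id: str
    seq: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.seq)
        for f in self.features:
            if f.start < 0 or f.end > n:
                raise GenomeFormatError(
                    f"feature {f.locus!r} [{f.start}, {f.end}) outside sequence "
                    f"of length {n} in genome {self.id!r}"
                )
        for s, e in self.gaps:
            if s < 0 or e > n or e <= s:
                raise GenomeFormatError(f"gap [{s}, {e}) outside sequence bounds")
            if set(self.seq[s:e]) != {"N"}:
                raise GenomeFormatError(f"gap [{s}, {e}) contains non-N characters")

    def __len__(self) -> int:
        return len(self.seq)

    def feature_by_locus(self, locus: str) -> Feature:
        for f in self.features:
            if f.locus == locus:
                return f
        raise KeyError(f"no feature with locus {locus!r} in genome {self.id!r}")

    def feature_at(self, pos: int) -> Feature | None:
        """Feature containing position ``pos`` (CDS preferred on overlap)."""
        hits = [f for f in self.features if f.contains(pos)]
        if not hits:
            return None
        hits.sort(key=lambda f: (FEATURE_KINDS.index(f.kind), f.start))
        return hits[0]


# ---------------------------------------------------------------------------
# readers / writers


def read_genome(
    fasta_path: str | Path,
    features_path: str | Path | None = None,
    gaps_path: str | Path | None = None,
    circular: bool = True,
) -> AnnotatedGenome:
    """Read a genome from single-record FASTA + (restricted) GFF3 + gap TSV.

    The GFF3 dialect is restricted to the three feature types CDS / intron /
    intergenic_spacer with a ``locus=NAME`` attribute; coordinates are
    converted from GFF 1-based inclusive to internal 0-based half-open.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise GenomeFormatError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    features = list(_read_gff3(features_path, len(seq))) if features_path else []
    gaps = _read_gaps(gaps_path) if gaps_path else []
    return AnnotatedGenome(id=rec.id, seq=seq, circular=circular,
                           features=features, gaps=gaps)


def _read_gff3(path: str | Path, seqlen: int) -> Iterable[Feature]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"{path}: expected 9 GFF3 columns: {line!r}")
            _, _, ftype, start, end, _, strand, phase, attrs = cols
            m = re.search(r"locus=([^;]+)", attrs)
            locus = m.group(1) if m else ftype
            feat = Feature(
                locus=locus,
                kind=ftype,
                start=int(start) - 1,
                end=int(end),
                strand=strand if strand in "+-" else "+",
                phase=int(phase) if phase.isdigit() else 0,
            )
            if feat.end > seqlen:
                raise GenomeFormatError(
                    f"{path}: feature {locus!r} ends at {feat.end} beyond "
                    f"sequence length {seqlen}"
                )
            yield feat


def _read_gaps(path: str | Path) -> list[tuple[int, int]]:
    gaps = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("start"):
                continue
            s, e = line.split("\t")[:2]
            gaps.append((int(s) - 1, int(e)))  # 1-based inclusive -> half-open
    return gaps


def write_genome(
    genome: AnnotatedGenome,
    fasta_path: str | Path,
    features_path: str | Path | None = None,
    gaps_path: str | Path | None = None,
) -> None:
    """Write FASTA / GFF3 / gap TSV; round-trips bit-exactly with read_genome."""
    rec = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    if features_path is not None:
        with open(features_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in genome.features:
                fh.write(
                    "\t".join(
                        [genome.id, "plastidcompat", f.kind, str(f.start + 1),
                         str(f.end), ".", f.strand, str(f.phase),
                         f"locus={f.locus}"]
                    )
                    + "\n"
                )
    if gaps_path is not None:
        with open(gaps_path, "w") as fh:
            fh.write("start\tend\n")
            for s, e in genome.gaps:
                fh.write(f"{s + 1}\t{e}\n")


# ---------------------------------------------------------------------------
# gap-aware genome length


def effective_length(
    genome: AnnotatedGenome,
    reference: AnnotatedGenome,
    anchor: int = 30,
) -> int:
    """Genome length with each assembly gap counted at its reference length.

    Each gap span is anchored to the reference by exact-matching the
    ``anchor`` bp immediately flanking the gap; the gap's assumed length is
    then the distance between the anchors in the reference.  With no gaps
    this is simply ``len(genome)``.
    """
    if not genome.gaps:
        return len(genome)
    total = len(genome)
    for s, e in genome.gaps:
        left = genome.seq[max(0, s - anchor): s]
        right = genome.seq[e: e + anchor]
        if len(left) < anchor or len(right) < anchor:
            raise GenomeFormatError(
                f"gap [{s + 1}, {e}] too close to sequence end to anchor"
            )
        li = _unique_find(reference.seq, left, genome, (s, e))
        ri = _unique_find(reference.seq, right, genome, (s, e))
        ref_region = ri - (li + anchor)
        if ref_region < 0:
            raise GenomeFormatError(
                f"gap [{s + 1}, {e}] anchors map out of order on reference"
            )
        total += ref_region - (e - s)
    return total


def _unique_find(haystack: str, needle: str, genome, gap) -> int:
    first = haystack.find(needle)
    if first == -1:
        raise GenomeFormatError(
            f"gap [{gap[0] + 1}, {gap[1]}] of {genome.id!r}: flanking anchor "
            f"not found in reference"
        )
    if haystack.find(needle, first + 1) != -1:
        raise GenomeFormatError(
            f"gap [{gap[0] + 1}, {gap[1]}] of {genome.id!r}: flanking anchor "
            f"is not unique in reference"
        )
    return first


# ---------------------------------------------------------------------------
# in-silico CAPS


@dataclass(frozen=True)
class CapsResult:
    polymorphic: bool
    sites_a: tuple[int, ...]  # match start positions, plus-strand coords
    sites_b: tuple[int, ...]
    fragments_a: tuple[int, ...]
    fragments_b: tuple[int, ...]


def iupac_find(seq: str, pattern: str) -> list[int]:
    """Start positions of all (possibly overlapping) IUPAC-pattern matches
    on either strand, reported in plus-strand coordinates."""
    try:
        fwd = "".join(f"[{IUPAC[c]}]" for c in pattern.upper())
        rev = "".join(f"[{IUPAC[c]}]" for c in revcomp(pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc}") from exc
    seq = seq.upper()
    hits = {m.start() for m in re.finditer(f"(?=({fwd}))", seq)}
    hits |= {m.start() for m in re.finditer(f"(?=({rev}))", seq)}
    return sorted(hits)


def caps_predict(
    allele_a: str,
    allele_b: str,
    site: str,
    cut_offset: int | None = None,
) -> CapsResult:
    """Predict whether a restriction site is polymorphic between two alleles.

    Matching is case-insensitive, both strands, overlapping matches allowed.
    Fragment lengths are computed by cutting ``cut_offset`` bases into each
    match (defaults to the middle of the recognition sequence) and always
    sum to the amplicon length.
    """
    if not allele_a or not allele_b:
        raise ValueError("caps_predict: empty allele sequence")
    if not site:
        raise ValueError("caps_predict: empty recognition pattern")
    if cut_offset is None:
        cut_offset = len(site) // 2
    sites_a = tuple(iupac_find(allele_a, site))
    sites_b = tuple(iupac_find(allele_b, site))
    return CapsResult(
        polymorphic=sites_a != sites_b,
        sites_a=sites_a,
        sites_b=sites_b,
        fragments_a=_fragments(len(allele_a), sites_a, cut_offset),
        fragments_b=_fragments(len(allele_b), sites_b, cut_offset),
    )


def _fragments(length: int, sites: Sequence[int], cut_offset: int) -> tuple[int, ...]:
    cuts = sorted({s + cut_offset for s in sites if 0 < s + cut_offset < length})
    bounds = [0, *cuts, length]
    return tuple(b - a for a, b in zip(bounds, bounds[1:]))
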