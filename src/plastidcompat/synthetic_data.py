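"""Seeded generators for every input the pipeline consumes.

Each generator plants known ground truth and returns it next to the
generated artifact, so every analysis stage can be tested end-to-end
without any external download:

* :func:`gen_genome_panel` builds a reference plastome-like genome with
  CDS / intron / intergenic-spacer annotation and a panel of accession
  genomes carrying planted variants whose type, region, coding effect and
  presence pattern are chosen up front;
* :func:`gen_ril_population` draws selfed-RIL genotype tables at chosen
  per-meiosis recombination fractions (observable recombinant fraction
  R = 2r/(1+2r));
* :func:`gen_cross_panel` closes a determinant-genotype panel under the
  compatibility rules into a full directed cross-outcome table.

A single integer seed makes every output byte-identical between runs;
generators derive independent substreams from it deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compatibility_model import (
    CrossOutcome,
    DeterminantGenotype,
    forward_panel,
)
from .io_formats import AnnotatedGenome, Feature
from .linkage import RILTable
from .variant_screen import PresenceMatrix, Variant

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class PlantSpec:
    """One variant to plant: where, what, and in whom.

    ``pattern`` selects carrier accessions: the string "incompatible"
    (present in every incompatible-cytoplasm accession, absent elsewhere),
    "all" (every non-reference accession), or an explicit tuple of
    accession names.
    """

    locus: str  # feature to hit (CDS locus or noncoding feature name)
    effect: str  # synonymous | nonsynonymous | inframe_indel | frameshift
    #              | start_loss | stop_loss_extension | noncoding
    vtype: str = "substitution"
    length: int = 1  # indel length in bp (ignored for substitutions)
    pattern: str | tuple[str, ...] = "incompatible"


@dataclass
class GenomePanelConfig:
    """Study-design description for a synthetic plastome panel.

    Defaults mirror a small five-accession comparison: one reference,
    two compatible and two incompatible cytoplasms.
    """

    accessions: dict[str, str] = field(default_factory=lambda: {
        "JI1794": "compatible_cytoplasm",
        "721": "compatible_cytoplasm",
        "L100": "incompatible_cytoplasm",
        "VIR320": "incompatible_cytoplasm",
    })
    reference: str = "WL1238"
    #: (locus, n_codons) for CDS loci, laid out with spacers and introns
    cds_loci: tuple[tuple[str, int], ...] = (
        ("accD", 240), ("rpoB", 200), ("ycf1", 200), ("ycf2", 200),
        ("psbA", 120), ("rbcL", 120), ("matK", 120), ("psaA", 120),
        ("clpP", 120),
    )
    intron_after: tuple[str, ...] = ("rpoB", "ycf1", "matK", "clpP")
    spacer_length: int = 900
    intron_length: int = 500
    planted: tuple[PlantSpec, ...] = ()
    min_spacing: int = 30  # bp between planted variants in one feature


def default_screen_config() -> GenomePanelConfig:
    """The screening study design: planted variants follow the funnel
    composition of the five-accession comparison (37 pattern variants: 15
    noncoding in 14 regions, 5 synonymous in 3 loci, 14 non-synonymous
    substitutions and 3 indels at 4 candidate loci, accD carrying 8 + 3),
    plus decoy variants that do not match the phenotype pattern."""
    planted = []
    # 15 noncoding variants over 14 distinct noncoding regions
    noncoding_regions = [
        "igs_accD", "igs_rpoB", "igs_ycf1", "igs_ycf2", "igs_psbA",
        "igs_rbcL", "igs_matK", "igs_psaA", "igs_clpP", "igs_end",
        "intron_rpoB", "intron_ycf1", "intron_matK", "intron_clpP",
    ]
    for region in noncoding_regions:
        planted.append(PlantSpec(region, "noncoding"))
    planted.append(PlantSpec("igs_accD", "noncoding"))  # 2nd variant, same region
    # 5 synonymous substitutions in 3 further coding loci
    for locus in ("psbA", "psbA", "rbcL", "rbcL", "matK"):
        planted.append(PlantSpec(locus, "synonymous"))
    # the four candidate loci: accD 8 nonsyn + 3 indels, rpoB 1, ycf1 3, ycf2 2
    for _ in range(8):
        planted.append(PlantSpec("accD", "nonsynonymous"))
    planted.append(PlantSpec("accD", "start_loss", vtype="deletion", length=21))
    planted.append(PlantSpec("accD", "inframe_indel", vtype="insertion", length=18))
    planted.append(PlantSpec("accD", "inframe_indel", vtype="deletion", length=6))
    planted.append(PlantSpec("rpoB", "nonsynonymous"))
    for _ in range(3):
        planted.append(PlantSpec("ycf1", "nonsynonymous"))
    for _ in range(2):
        planted.append(PlantSpec("ycf2", "nonsynonymous"))
    # decoys: shared by all wild accessions, or private to single accessions
    for locus in ("psaA", "psaA", "igs_psaA"):
        planted.append(PlantSpec(locus, "nonsynonymous" if locus == "psaA"
                                 else "noncoding", pattern="all"))
    planted.append(PlantSpec("igs_rbcL", "noncoding", pattern=("JI1794",)))
    planted.append(PlantSpec("clpP", "nonsynonymous", pattern=("VIR320",)))
    planted.append(PlantSpec("igs_matK", "noncoding", pattern=("721", "JI1794")))
    return GenomePanelConfig(planted=tuple(planted))


@dataclass
class GenomePanel:
    reference: AnnotatedGenome
    queries: dict[str, AnnotatedGenome]
    truth: PresenceMatrix  # planted variants with effects and presence


def gen_genome_panel(config: GenomePanelConfig, seed: int = 0) -> GenomePanel:
    """Generate (reference, accession genomes, truth variant matrix).

    Variants are planted in non-overlapping, well-separated positions with
    local context adjusted so that left-normalized calling recovers exactly
    the planted records.  Same seed and config give byte-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    seq, features = _build_reference_layout(config, rng)
    planted = _plant_variants(config, seq, features, rng)

    ref_genome = AnnotatedGenome(id=config.reference, seq="".join(seq),
                                 features=features)
    accessions = list(config.accessions)
    present = np.zeros((len(planted), len(accessions)), dtype=bool)
    for i, (variant, carriers) in enumerate(planted):
        for acc in carriers:
            present[i, accessions.index(acc)] = True

    queries = {}
    for j, acc in enumerate(accessions):
        mine = [v for i, (v, _) in enumerate(planted) if present[i, j]]
        # features are reference-frame; query genomes carry none of their own
        queries[acc] = AnnotatedGenome(
            id=acc, seq=_apply_variants(ref_genome.seq, mine), features=[]
        )
    phenotype = dict(config.accessions)
    phenotype[config.reference] = "reference"
    truth = PresenceMatrix([v for v, _ in planted], accessions, present, phenotype)
    return GenomePanel(ref_genome, queries, truth)


def _build_reference_layout(config, rng):
    """Sequence + features: spacer, CDS, [intron], spacer, CDS, ..."""
    seq: list[str] = []
    features: list[Feature] = []

    def add_noncoding(name, kind, length):
        start = len(seq)
        seq.extend(rng.choice(list("ACGT"), size=length))
        features.append(Feature(name, kind, start, start + length, "+"))

    for locus, n_codons in config.cds_loci:
        add_noncoding(f"igs_{locus}", "intergenic_spacer", config.spacer_length)
        start = len(seq)
        body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
        seq.extend("ATG" + "".join(body) + "TAA")
        features.append(Feature(locus, "CDS", start, len(seq), "+"))
        if locus in config.intron_after:
            add_noncoding(f"intron_{locus}", "intron", config.intron_length)
    add_noncoding("igs_end", "intergenic_spacer", config.spacer_length)
    return seq, features


def _carriers(pattern, config) -> tuple[str, ...]:
    if pattern == "incompatible":
        return tuple(a for a, p in config.accessions.items()
                     if p == "incompatible_cytoplasm")
    if pattern == "all":
        return tuple(config.accessions)
    return tuple(pattern)


def _plant_variants(config, seq, features, rng):
    """Choose positions and alleles; may edit the reference in place to
    guarantee the requested coding effect and stable left-normalization."""
    featmap = {f.locus: f for f in features}
    used: list[tuple[int, int]] = []  # claimed reference spans

    def claim(start, end):
        pad = config.min_spacing
        for s, e in used:
            if start - pad < e and end + pad > s:
                return False
        used.append((start, end))
        return True

    def pick_codon(feat, margin=2):
        # a random internal codon start, avoiding start/stop codons
        for _ in range(200):
            k = int(rng.integers(margin, (len(feat) // 3) - margin))
            pos = feat.start + 3 * k
            if claim(pos, pos + 3):
                return pos
        raise ValueError(f"no room to plant in {feat.locus!r}")

    planted: list[tuple[Variant, tuple[str, ...]]] = []
    # fixed-position variants (start/stop disruptions) claim their spans
    # first, then indels, then free-position substitutions
    _prio = {"start_loss": 0, "stop_loss_extension": 0,
             "inframe_indel": 1, "frameshift": 1}
    ordered = sorted(config.planted,
                     key=lambda s: _prio.get(s.effect, 2))
    for spec in ordered:
        feat = featmap.get(spec.locus)
        if feat is None:
            raise ValueError(f"unknown planting locus {spec.locus!r}")
        carriers = _carriers(spec.pattern, config)
        region = feat.kind
        if spec.effect == "noncoding":
            for _ in range(200):
                pos = int(rng.integers(feat.start + 5, feat.end - 5))
                if claim(pos, pos + 1):
                    break
            else:
                raise ValueError(f"no room in {spec.locus!r}")
            ref = str(seq[pos])
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
            v = Variant(pos, pos + 1, "substitution", ref, alt,
                        spec.locus, region, "noncoding")
        elif spec.effect == "synonymous":
            pos = pick_codon(feat)
            seq[pos:pos + 3] = "GCT"  # Ala
            v = Variant(pos + 2, pos + 3, "substitution", "T", "C",
                        spec.locus, region, "synonymous")  # GCT->GCC
        elif spec.effect == "nonsynonymous":
            pos = pick_codon(feat)
            seq[pos:pos + 3] = "GCT"  # Ala -> Thr
            v = Variant(pos, pos + 1, "substitution", "G", "A",
                        spec.locus, region, "nonsynonymous")
        elif spec.effect == "start_loss":
            if not claim(feat.start - spec.length + 12, feat.start + 12):
                raise ValueError(f"start of {spec.locus!r} already claimed")
            if spec.vtype == "deletion":
                # remove upstream spacer bases plus the start codon region
                s = feat.start - (spec.length - 12)
                e = feat.start + 12
                _guard_deletion(seq, s, e)
                v = Variant(s, e, "deletion", "".join(seq[s:e]), "",
                            spec.locus, "CDS", "start_loss")
            else:
                seq[feat.start + 2] = "G"
                v = Variant(feat.start + 2, feat.start + 3, "substitution",
                            "G", "A", spec.locus, "CDS", "start_loss")
        elif spec.effect == "stop_loss_extension":
            stop = feat.end - 3
            if not claim(stop, feat.end):
                raise ValueError(f"stop of {spec.locus!r} already claimed")
            # TAA -> CAA; provide an in-frame downstream stop in the spacer
            ext = feat.end + 12
            claim(ext, ext + 3)
            seq[ext:ext + 3] = "TAA"
            v = Variant(stop, stop + 1, "substitution", "T", "C",
                        spec.locus, "CDS", "stop_loss_extension")
        elif spec.effect in ("inframe_indel", "frameshift"):
            L = spec.length
            if spec.effect == "inframe_indel" and L % 3 != 0:
                raise ValueError("inframe indel length must be a multiple of 3")
            if spec.effect == "frameshift" and L % 3 == 0:
                raise ValueError("frameshift indel length must not be 3k")
            pos = pick_codon(feat, margin=4)
            if spec.vtype == "insertion":
                alt = _insertion_allele(L, seq, pos, rng)
                v = Variant(pos, pos, "insertion", "", alt,
                            spec.locus, region, spec.effect)
            else:
                _guard_deletion(seq, pos, pos + L)
                v = Variant(pos, pos + L, "deletion", "".join(seq[pos:pos + L]),
                            "", spec.locus, region, spec.effect)
        else:
            raise ValueError(f"unsupported effect {spec.effect!r}")
        planted.append((v, carriers))

    planted.sort(key=lambda t: (t[0].ref_start, t[0].ref_end))
    for (a, _), (b, _) in zip(planted, planted[1:]):
        if b.ref_start < a.ref_end:
            raise ValueError(
                f"planted variants overlap at {a.ref_start}-{a.ref_end}"
            )
    return planted


def _guard_deletion(seq, s, e):
    """Prevent leftward normalization drift of a planted deletion."""
    if s > 0 and seq[s - 1] == seq[e - 1]:
        seq[s - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[s - 1]]


def _insertion_allele(length, seq, pos, rng):
    alt = "".join(rng.choice(list("ACGT"), size=length))
    if pos > 0 and alt[-1] == seq[pos - 1]:  # keep left-normalization stable
        alt = alt[:-1] + {"A": "C", "C": "A", "G": "T", "T": "G"}[alt[-1]]
    if alt[0] == seq[pos]:  # and avoid right-shift ambiguity
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[alt[0]] + alt[1:]
    return alt


def _apply_variants(ref_seq: str, variants: list[Variant]) -> str:
    out = ref_seq
    for v in sorted(variants, key=lambda v: v.ref_start, reverse=True):
        out = out[: v.ref_start] + v.alt_allele + out[v.ref_end:]
    return out


# ---------------------------------------------------------------------------
# RIL populations


@dataclass
class RILConfig:
    loci: tuple[str, ...] = ("PhlC", "Bccp3", "AJ832139")
    r: tuple[float, ...] = (0.02, 0.02)  # per-meiosis, one per interval
    n_lines: int = 88

    def __post_init__(self):
        if len(self.r) != len(self.loci) - 1:
            raise ValueError("need one r per adjacent locus interval")
        for r in self.r:
            if not 0 <= r < 0.5:
                raise ValueError(f"per-meiosis r {r} outside [0, 0.5)")


def gen_ril_population(config: RILConfig, seed: int = 0
                       ) -> tuple[RILTable, tuple[float, ...]]:
    """Draw a selfed-RIL genotype table.

    Per line, the first locus is A or B with probability 1/2; each
    following interval flips the genotype with the RIL-observable
    recombinant fraction R = 2r/(1+2r).  Returns (table, truth r values).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    R = [2 * r / (1 + 2 * r) for r in config.r]
    first = rng.random(config.n_lines) < 0.5
    flips = [rng.random(config.n_lines) < Ri for Ri in R]
    rows = []
    for i in range(config.n_lines):
        g = first[i]
        line = [g]
        for flip in flips:
            g = g ^ flip[i]
            line.append(g)
        rows.append(["B" if x else "A" for x in line])
    lines = [f"SIM{i + 1:05d}" for i in range(config.n_lines)]
    df = pd.DataFrame(rows, index=lines, columns=list(config.loci))
    return RILTable(df), tuple(config.r)


# ---------------------------------------------------------------------------
# cross panels


def random_determinant_panel(n: int, seed: int = 0,
                             names: list[str] | None = None
                             ) -> list[DeterminantGenotype]:
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    if names is None:
        names = [f"ACC{i + 1}" for i in range(n)]
    flags = rng.integers(0, 2, size=(n, 4)).astype(bool)
    return [DeterminantGenotype(names[i], *map(bool, flags[i])) for i in range(n)]


def gen_cross_panel(genotypes: list[DeterminantGenotype]
                    ) -> tuple[list[CrossOutcome], list[DeterminantGenotype]]:
    """Deterministic closure of the compatibility rules over a panel:
    the full directed cross table plus the truth genotypes."""
    return forward_panel(genotypes), list(genotypes)
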