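"""Pairwise plastome comparison and the phenotype-pattern candidate funnel.

The screen works the way a desk analysis of assembled plastomes does: each
query genome is globally aligned to the reference (the cultivated tester
line), every difference is recorded as a left-normalized :class:`Variant`,
each variant is assigned to its annotated region and, for CDS variants,
given a coding-effect label under the bacterial/plastid genetic code
(translation table 11).  Variants from several accessions are then combined
into a presence/absence matrix and filtered for the candidate pattern:
present in every accession with an incompatible cytoplasm and absent from
every accession with a compatible one.  Surviving coding, non-synonymous
variants are grouped per locus into a ranked candidate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import FEATURE_KINDS, AnnotatedGenome, Feature, revcomp

PLASTID_TABLE = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = set(PLASTID_TABLE.stop_codons)

EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "inframe_indel",
    "frameshift",
    "start_loss",
    "stop_loss_extension",
    "noncoding",
)

PHENOTYPES = ("incompatible_cytoplasm", "compatible_cytoplasm", "reference")


def translate_cds(nt: str) -> str:
    """Translate a nucleotide string codon-by-codon under table 11,
    stopping at (and excluding) the first stop codon."""
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i:i + 3]
        if codon in STOP_CODONS:
            break
        aa.append(PLASTID_TABLE.forward_table.get(codon, "X"))
    return "".join(aa)


@dataclass
class Variant:
    """One difference between a query genome and the reference.

    ``ref_start``/``ref_end`` are 0-based half-open on the reference
    (``ref_start == ref_end`` for insertions).  ``alt_allele`` is empty for
    deletions, ``ref_allele`` empty for insertions.
    """

    ref_start: int
    ref_end: int
    vtype: str  # substitution | insertion | deletion | inversion
    ref_allele: str
    alt_allele: str
    locus: str = ""
    region: str = ""  # CDS | intron | intergenic_spacer
    effect: str = ""

    def __post_init__(self):
        if self.vtype == "substitution" and (
            len(self.ref_allele) != len(self.alt_allele) or not self.ref_allele
        ):
            raise ValueError("substitution requires equal-length non-empty alleles")

    @property
    def key(self) -> tuple:
        return (self.ref_start, self.ref_end, self.vtype,
                self.ref_allele, self.alt_allele)

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


class NotColinearError(ValueError):
    """Raised when two genomes are too diverged for colinear comparison."""


# ---------------------------------------------------------------------------
# calling


def align_and_call(
    reference: AnnotatedGenome,
    query: AnnotatedGenome,
    annotate: bool = True,
    detect_inversions: bool = True,
    min_identity: float = 0.5,
) -> list[Variant]:
    """Call variants of ``query`` against ``reference`` by global alignment.

    Returns left-normalized variants sorted by reference position; runs of
    adjacent mismatching columns are merged into one (possibly
    multi-nucleotide) substitution record, so several substituted bases in
    one codon make a single record.
    """
    if reference.seq == query.seq:
        return []
    res = edlib.align(query.seq, reference.seq, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query.seq, reference.seq)
    qrow, trow = nice["query_aligned"], nice["target_aligned"]
    ncols = len(trow)
    matches = sum(q == t for q, t in zip(qrow, trow))
    if matches / ncols < min_identity:
        raise NotColinearError(
            f"genomes {reference.id!r} and {query.id!r} are not colinear "
            f"(identity {matches / ncols:.2f})"
        )
    variants = _events_from_rows(trow, qrow)
    variants.sort(key=lambda v: (v.ref_start, v.ref_end))
    variants = _coalesce_clusters(variants, reference.seq)
    variants = [_left_normalize(v, reference.seq) for v in variants]
    variants.sort(key=lambda v: (v.ref_start, v.ref_end))
    if detect_inversions:
        variants = _flag_inversions(variants, reference.seq)
    if annotate:
        variants = [annotate_variant(v, reference) for v in variants]
    return variants


def _events_from_rows(trow: str, qrow: str) -> list[Variant]:
    variants: list[Variant] = []
    rpos = 0  # reference coordinate of current column
    i = 0
    n = len(trow)
    while i < n:
        t, q = trow[i], qrow[i]
        if t == q:
            rpos += 1
            i += 1
        elif t != "-" and q != "-":  # mismatch run -> substitution
            j = i
            start = rpos
            while j < n and trow[j] != "-" and qrow[j] != "-" and trow[j] != qrow[j]:
                rpos += 1
                j += 1
            variants.append(Variant(start, rpos, "substitution",
                                    trow[i:j], qrow[i:j]))
            i = j
        elif q == "-":  # gap in query -> deletion
            j = i
            start = rpos
            while j < n and qrow[j] == "-":
                rpos += 1
                j += 1
            variants.append(Variant(start, rpos, "deletion", trow[i:j], ""))
            i = j
        else:  # gap in reference -> insertion
            j = i
            while j < n and trow[j] == "-":
                j += 1
            variants.append(Variant(rpos, rpos, "insertion", "", qrow[i:j]))
            i = j
    return variants


def _coalesce_clusters(variants: list[Variant], ref: str,
                       max_gap: int = 10) -> list[Variant]:
    """Re-normalize clusters of nearby events that include an indel.

    Optimal global alignment can represent one long indel as several
    nearby pieces (alternative equal-cost paths through repetitive
    context).  Events separated by at most ``max_gap`` matching bases are
    merged into one reference-vs-alternate block, common prefix and suffix
    are trimmed off, and the block is re-emitted as a single substitution,
    insertion or deletion (or a substitution plus an indel for genuinely
    mixed blocks).  Clusters consisting solely of substitutions are left
    untouched: adjacent same-type events separated by matching bases are
    distinct records.
    """
    out: list[Variant] = []
    i = 0
    while i < len(variants):
        j = i
        while (j + 1 < len(variants)
               and variants[j + 1].ref_start - variants[j].ref_end <= max_gap):
            j += 1
        cluster = variants[i: j + 1]
        if len(cluster) == 1 or not any(
            v.vtype in ("insertion", "deletion") for v in cluster
        ):
            out.extend(cluster)
        else:
            out.extend(_merge_cluster(cluster, ref))
        i = j + 1
    return out


def _merge_cluster(cluster: list[Variant], ref: str) -> list[Variant]:
    s, e = cluster[0].ref_start, cluster[-1].ref_end
    alt_parts = []
    pos = s
    for v in cluster:
        alt_parts.append(ref[pos: v.ref_start])
        alt_parts.append(v.alt_allele)
        pos = v.ref_end
    alt_parts.append(ref[pos: e])
    alt = "".join(alt_parts)
    refseg = ref[s:e]
    # trim common prefix then common suffix
    p = 0
    while p < min(len(refseg), len(alt)) and refseg[p] == alt[p]:
        p += 1
    q = 0
    while (q < min(len(refseg), len(alt)) - p
           and refseg[len(refseg) - 1 - q] == alt[len(alt) - 1 - q]):
        q += 1
    refseg = refseg[p: len(refseg) - q]
    alt = alt[p: len(alt) - q]
    s += p
    e -= q
    if not refseg and not alt:
        return []
    if len(refseg) == len(alt):
        return [Variant(s, e, "substitution", refseg, alt)]
    if not refseg:
        return [Variant(s, s, "insertion", "", alt)]
    if not alt:
        return [Variant(s, e, "deletion", refseg, "")]
    # mixed block: substitution over the shared length + an indel remainder
    k = min(len(refseg), len(alt))
    sub = Variant(s, s + k, "substitution", refseg[:k], alt[:k])
    if len(alt) > k:
        return [sub, Variant(s + k, s + k, "insertion", "", alt[k:])]
    return [sub, Variant(s + k, e, "deletion", refseg[k:], "")]


def _left_normalize(v: Variant, ref: str) -> Variant:
    """Shift indels leftward through repeat/homopolymer context."""
    if v.vtype == "deletion":
        s, e = v.ref_start, v.ref_end
        while s > 0 and ref[s - 1] == ref[e - 1]:
            s -= 1
            e -= 1
        if s != v.ref_start:
            return replace(v, ref_start=s, ref_end=e, ref_allele=ref[s:e])
    elif v.vtype == "insertion":
        p, alt = v.ref_start, v.alt_allele
        while p > 0 and ref[p - 1] == alt[-1]:
            alt = ref[p - 1] + alt[:-1]
            p -= 1
        if p != v.ref_start:
            return replace(v, ref_start=p, ref_end=p, alt_allele=alt)
    return v


def _flag_inversions(variants: list[Variant], ref: str,
                     min_len: int = 30, max_gap: int = 10,
                     min_density: float = 0.4,
                     min_rc_identity: float = 0.8) -> list[Variant]:
    """Flag inverted segments as single descriptive records.

    An inverted segment shows up in a colinear alignment as a dense cluster
    of mismatches (every base has ~1/4 chance of matching by accident).
    Clusters of events separated by at most ``max_gap`` matching bases that
    span >= ``min_len`` bp with mismatch density >= ``min_density`` are
    tested: if the query segment is (approximately) the reverse complement
    of the reference segment, the whole cluster is replaced by one
    ``inversion`` record.  No effect classification is attempted for
    inversions.
    """
    out: list[Variant] = []
    i = 0
    while i < len(variants):
        j = i
        while (j + 1 < len(variants)
               and variants[j + 1].ref_start - variants[j].ref_end <= max_gap):
            j += 1
        cluster = variants[i: j + 1]
        merged = _try_inversion(cluster, ref, min_len, min_density,
                                min_rc_identity)
        if merged is not None:
            out.append(merged)
        else:
            out.extend(cluster)
        i = j + 1
    return out


def _try_inversion(cluster, ref, min_len, min_density, min_rc_identity):
    s, e = cluster[0].ref_start, cluster[-1].ref_end
    if e - s < min_len:
        return None
    changed = sum(max(len(v.ref_allele), len(v.alt_allele)) for v in cluster)
    if changed / (e - s) < min_density:
        return None
    alt_parts = []
    pos = s
    for v in cluster:
        alt_parts.append(ref[pos: v.ref_start])
        alt_parts.append(v.alt_allele)
        pos = v.ref_end
    alt_parts.append(ref[pos: e])
    alt = "".join(alt_parts)
    refseg = ref[s:e]
    if len(alt) == len(refseg) and _identity(revcomp(refseg), alt) >= min_rc_identity:
        return Variant(s, e, "inversion", refseg, alt)
    return None


def _identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# annotation / effect classification


def annotate_variant(variant: Variant, genome: AnnotatedGenome) -> Variant:
    """Assign locus/region from the reference annotation and classify the
    coding effect for CDS variants."""
    pos = variant.ref_start
    span_end = max(variant.ref_end, pos + 1)
    overlapping = [f for f in genome.features
                   if f.start < span_end and f.end > pos]
    # a variant touching a CDS (e.g. a deletion spanning a UTR/start-codon
    # boundary) is assigned to the CDS
    overlapping.sort(key=lambda f: (FEATURE_KINDS.index(f.kind), f.start))
    feat = overlapping[0] if overlapping else None
    if feat is None and variant.vtype == "insertion" and pos > 0:
        feat = genome.feature_at(pos - 1)
    if feat is None:
        v = replace(variant, locus=f"unannotated_{pos + 1}",
                    region="intergenic_spacer", effect="noncoding")
        return v
    v = replace(variant, locus=feat.locus, region=feat.kind)
    if variant.vtype == "inversion":
        return v
    return replace(v, effect=classify_effect(v, genome))


def classify_effect(variant: Variant, genome: AnnotatedGenome) -> str:
    """Coding-effect label for an annotated variant.

    A variant is synonymous iff every affected codon translates identically;
    indels are in-frame iff the length change is a multiple of 3.
    Disruption of the annotated start codon dominates (start_loss), then
    disruption of the stop codon (stop_loss_extension).
    """
    if variant.region != "CDS":
        return "noncoding"
    feat = genome.feature_by_locus(variant.locus)
    if feat.kind != "CDS":
        return "noncoding"
    if feat.strand not in "+-":
        raise ValueError(f"CDS {feat.locus!r} without annotated strand")

    if feat.strand == "+":
        start_span = (feat.start, feat.start + 3)
        stop_span = (feat.end - 3, feat.end)
    else:
        start_span = (feat.end - 3, feat.end)
        stop_span = (feat.start, feat.start + 3)
    vs, ve = variant.ref_start, variant.ref_end
    if variant.vtype == "insertion":
        ve = vs + 1  # an insertion sits between vs-1 and vs

    def overlaps(span):
        return vs < span[1] and ve > span[0]

    if overlaps(start_span) and _disrupts_codon(variant, genome, feat, start_span,
                                                expect={"ATG"}):
        return "start_loss"
    if overlaps(stop_span) and _disrupts_codon(variant, genome, feat, stop_span,
                                               expect=STOP_CODONS):
        return "stop_loss_extension"
    if variant.vtype in ("insertion", "deletion"):
        return "inframe_indel" if variant.length_change % 3 == 0 else "frameshift"
    # substitution: translate affected codons before and after
    ref_cds = _extract_cds(genome.seq, feat)
    alt_seq = (genome.seq[: variant.ref_start] + variant.alt_allele
               + genome.seq[variant.ref_end:])
    alt_cds = _extract_cds(alt_seq, feat)
    return ("synonymous" if translate_cds(ref_cds) == translate_cds(alt_cds)
            else "nonsynonymous")


def _extract_cds(seq: str, feat: Feature) -> str:
    sub = seq[feat.start: feat.end]
    return revcomp(sub) if feat.strand == "-" else sub


def _disrupts_codon(variant, genome, feat, span, expect) -> bool:
    """True if applying the variant changes the codon at ``span`` so it is
    no longer in ``expect`` (strand-aware).  Any indel overlapping the codon
    counts as disruptive."""
    if variant.vtype in ("insertion", "deletion"):
        return True
    s, e = span
    codon = list(genome.seq[s:e])
    for i, p in enumerate(range(s, e)):
        if variant.ref_start <= p < variant.ref_end:
            codon[i] = variant.alt_allele[p - variant.ref_start]
    codon = "".join(codon)
    if feat.strand == "-":
        codon = revcomp(codon)
    return codon not in expect


# ---------------------------------------------------------------------------
# presence matrix and funnel


@dataclass
class PresenceMatrix:
    """Variants x accessions boolean matrix with per-accession phenotypes.

    The reference accession is all-absent by construction: differences are
    called against it.
    """

    variants: list[Variant]
    accessions: list[str]
    present: np.ndarray  # bool, shape (n_variants, n_accessions)
    phenotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.variants), len(self.accessions)):
            raise ValueError("presence matrix shape mismatch")
        for acc, ph in self.phenotype.items():
            if ph not in PHENOTYPES:
                raise ValueError(f"unknown phenotype label {ph!r} for {acc!r}")

    @classmethod
    def from_calls(
        cls,
        calls: dict[str, list[Variant]],
        phenotype: dict[str, str],
    ) -> "PresenceMatrix":
        """Combine per-accession call lists; variants are identified by
        (span, type, alleles)."""
        accessions = list(calls)
        keyed: dict[tuple, Variant] = {}
        for acc in accessions:
            for v in calls[acc]:
                keyed.setdefault(v.key, v)
        variants = sorted(keyed.values(), key=lambda v: v.key)
        index = {v.key: i for i, v in enumerate(variants)}
        present = np.zeros((len(variants), len(accessions)), dtype=bool)
        for j, acc in enumerate(accessions):
            for v in calls[acc]:
                present[index[v.key], j] = True
        return cls(variants, accessions, present, dict(phenotype))


def pattern_filter(matrix: PresenceMatrix) -> list[Variant]:
    """Variants present in ALL incompatible-cytoplasm accessions and absent
    from ALL compatible-cytoplasm accessions (order preserved)."""
    inc = [i for i, a in enumerate(matrix.accessions)
           if matrix.phenotype.get(a) == "incompatible_cytoplasm"]
    com = [i for i, a in enumerate(matrix.accessions)
           if matrix.phenotype.get(a) == "compatible_cytoplasm"]
    if not inc or not com:
        raise ValueError(
            "pattern_filter needs at least one incompatible_cytoplasm and one "
            "compatible_cytoplasm accession"
        )
    keep = matrix.present[:, inc].all(axis=1) & ~matrix.present[:, com].any(axis=1)
    return [v for v, k in zip(matrix.variants, keep) if k]


def funnel_counts(filtered: list[Variant]) -> dict[str, int]:
    """Partition a filtered variant list into the screening funnel bins.

    Every variant lands in exactly one bin, so the bins sum to the input
    size (conservation of the funnel).
    """
    noncoding = [v for v in filtered if v.effect == "noncoding"]
    coding = [v for v in filtered if v.effect != "noncoding"]
    synonymous = [v for v in coding if v.effect == "synonymous"]
    indels = [v for v in coding if v.vtype in ("insertion", "deletion")]
    nonsyn = [v for v in coding
              if v.vtype == "substitution" and v.effect != "synonymous"]
    return {
        "n_pattern_variants": len(filtered),
        "n_noncoding": len(noncoding),
        "n_noncoding_regions": len({v.locus for v in noncoding}),
        "n_coding_loci": len({v.locus for v in coding}),
        "n_synonymous": len(synonymous),
        "n_nonsynonymous_substitutions": len(nonsyn),
        "n_indels": len(indels),
    }


def nominate_loci(filtered: list[Variant]) -> pd.DataFrame:
    """Candidate table: drop noncoding and synonymous variants, group by
    locus, rank by (non-synonymous substitutions + indels) descending,
    alphabetical on ties."""
    rows: dict[str, dict[str, int]] = {}
    for v in filtered:
        if v.effect in ("noncoding", "synonymous"):
            continue
        rec = rows.setdefault(v.locus, {"n_nonsyn_substitutions": 0, "n_indels": 0})
        if v.vtype == "substitution":
            rec["n_nonsyn_substitutions"] += 1
        elif v.vtype in ("insertion", "deletion"):
            rec["n_indels"] += 1
    df = pd.DataFrame(
        [{"locus": k, **v, "n_total": v["n_nonsyn_substitutions"] + v["n_indels"]}
         for k, v in rows.items()],
        columns=["locus", "n_nonsyn_substitutions", "n_indels", "n_total"],
    )
    if df.empty:
        return df
    return (df.sort_values(["n_total", "locus"], ascending=[False, True])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# TSV interchange (the difference-list emulation format)

_TSV_COLUMNS = ["ref_start_1based", "ref_end_1based", "type", "ref_allele",
                "alt_allele", "locus", "region", "effect"]


def write_variant_tsv(matrix: PresenceMatrix, path: str | Path) -> None:
    rows = []
    for v, pres in zip(matrix.variants, matrix.present):
        row = {
            "ref_start_1based": v.ref_start + 1,
            # insertions are between bases; report the 1-based base to the left
            "ref_end_1based": max(v.ref_end, v.ref_start + 1),
            "type": v.vtype,
            "ref_allele": v.ref_allele or ".",
            "alt_allele": v.alt_allele or ".",
            "locus": v.locus,
            "region": v.region,
            "effect": v.effect or ".",
        }
        for acc, p in zip(matrix.accessions, pres):
            row[acc] = int(p)
        rows.append(row)
    pd.DataFrame(rows, columns=_TSV_COLUMNS + matrix.accessions).to_csv(
        path, sep="\t", index=False
    )


def read_variant_tsv(path: str | Path,
                     phenotype: dict[str, str] | None = None) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"ref_allele": str, "alt_allele": str})
    accessions = [c for c in df.columns if c not in _TSV_COLUMNS]
    variants = []
    for _, r in df.iterrows():
        ref_allele = "" if r.ref_allele == "." else r.ref_allele
        alt_allele = "" if r.alt_allele == "." else r.alt_allele
        start = int(r.ref_start_1based) - 1
        end = start if r.type == "insertion" else int(r.ref_end_1based)
        variants.append(Variant(start, end, r.type, ref_allele, alt_allele,
                                r.locus, r.region,
                                "" if r.effect == "." else r.effect))
    present = df[accessions].to_numpy(dtype=bool)
    return PresenceMatrix(variants, accessions, present, phenotype or {})
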