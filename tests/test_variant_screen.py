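"""Variant calling, effect classification, and the candidate funnel."""

from itertools import product

import numpy as np
import pytest

from plastidcompat.io_formats import AnnotatedGenome, Feature, revcomp
from plastidcompat.synthetic_data import default_screen_config, gen_genome_panel
from plastidcompat.variant_screen import (
    NotColinearError,
    PresenceMatrix,
    Variant,
    align_and_call,
    classify_effect,
    funnel_counts,
    nominate_loci,
    pattern_filter,
    read_variant_tsv,
    translate_cds,
    write_variant_tsv,
)


def _genome(seq, features=(), gid="g"):
    return AnnotatedGenome(id=gid, seq=seq, features=list(features))


@pytest.fixture
def cds_genome():
    """120 bp: spacer(30) + CDS(60: ATG + 18 codons + TAA) + spacer(30)."""
    rng = np.random.default_rng(0)
    spacer1 = "".join(rng.choice(list("ACGT"), size=30))
    spacer2 = "".join(rng.choice(list("ACGT"), size=30))
    body = "GCT CAT AAA GAT CCT TGG TTT GGG CAA GCT CGT ACT AAT GTT CAC GGC TTA GTA"
    cds = "ATG" + body.replace(" ", "") + "TAA"
    seq = spacer1 + cds + spacer2
    feats = [
        Feature("igs_left", "intergenic_spacer", 0, 30, "+"),
        Feature("geneA", "CDS", 30, 30 + len(cds), "+"),
        Feature("igs_right", "intergenic_spacer", 30 + len(cds), len(seq), "+"),
    ]
    return _genome(seq, feats, "ref")


class TestAlignAndCall:
    def test_identical_genomes_yield_no_variants(self, cds_genome):
        assert align_and_call(cds_genome, _genome(cds_genome.seq)) == []

    def test_single_substitution_recovered_at_planted_position(self, cds_genome):
        pos = 45
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[cds_genome.seq[pos]]
        q = cds_genome.seq[:pos] + alt + cds_genome.seq[pos + 1:]
        (v,) = align_and_call(cds_genome, _genome(q))
        assert (v.ref_start, v.ref_end, v.vtype) == (pos, pos + 1, "substitution")
        assert v.alt_allele == alt
        assert v.locus == "geneA" and v.region == "CDS"

    def test_deletion_over_start_codon_is_start_loss(self, cds_genome):
        # 21 bp removing 9 bp of the upstream spacer plus the start codon
        q = cds_genome.seq[:21] + cds_genome.seq[42:]
        (v,) = align_and_call(cds_genome, _genome(q))
        assert v.vtype == "deletion" and len(v.ref_allele) == 21
        assert v.locus == "geneA"
        assert v.effect == "start_loss"

    def test_diverged_sequences_rejected(self, cds_genome):
        with pytest.raises(NotColinearError, match="not colinear"):
            align_and_call(cds_genome, _genome("A" * len(cds_genome)))

    def test_inverted_segment_flagged_not_classified(self):
        rng = np.random.default_rng(9)
        ref = "".join(rng.choice(list("ACGT"), size=3000))
        q = ref[:800] + revcomp(ref[800:1200]) + ref[1200:]
        (v,) = align_and_call(_genome(ref), _genome(q), annotate=False)
        assert v.vtype == "inversion"
        assert (v.ref_start, v.ref_end) == (800, 1200)


class TestClassifyEffect:
    def test_inframe_18bp_insertion_encodes_hexapeptide(self, cds_genome):
        ins = "ATATCAGATACAAATGAT"  # -> ISDTND
        assert translate_cds(ins) == "ISDTND"
        v = Variant(45, 45, "insertion", "", ins, "geneA", "CDS")
        assert classify_effect(v, cds_genome) == "inframe_indel"

    def test_intergenic_substitution_is_noncoding(self, cds_genome):
        v = Variant(5, 6, "substitution", cds_genome.seq[5], "A",
                    "igs_left", "intergenic_spacer")
        assert classify_effect(v, cds_genome) == "noncoding"

    def test_third_position_wobble_is_synonymous(self, cds_genome):
        # codon 2 of the CDS is GCT (Ala); GCT -> GCC stays Ala
        pos = 30 + 3 + 2
        assert cds_genome.seq[30 + 3: 30 + 6] == "GCT"
        v = Variant(pos, pos + 1, "substitution", "T", "C", "geneA", "CDS")
        assert classify_effect(v, cds_genome) == "synonymous"

    def test_first_position_change_is_nonsynonymous(self, cds_genome):
        pos = 30 + 3
        v = Variant(pos, pos + 1, "substitution", "G", "A", "geneA", "CDS")
        assert classify_effect(v, cds_genome) == "nonsynonymous"

    def test_stop_codon_substitution_is_stop_loss(self, cds_genome):
        feat = cds_genome.feature_by_locus("geneA")
        v = Variant(feat.end - 3, feat.end - 2, "substitution", "T", "C",
                    "geneA", "CDS")
        assert classify_effect(v, cds_genome) == "stop_loss_extension"

    def test_frameshift_vs_inframe_length_rule(self, cds_genome):
        d1 = Variant(45, 46, "deletion", cds_genome.seq[45], "", "geneA", "CDS")
        d3 = Variant(45, 48, "deletion", cds_genome.seq[45:48], "", "geneA", "CDS")
        assert classify_effect(d1, cds_genome) == "frameshift"
        assert classify_effect(d3, cds_genome) == "inframe_indel"


def _matrix(present, phenotype, accessions):
    variants = [Variant(10 * i, 10 * i + 1, "substitution", "A", "G",
                        f"locus{i}", "CDS", "nonsynonymous")
                for i in range(len(present))]
    return PresenceMatrix(variants, accessions, np.array(present, bool),
                          phenotype)


class TestPatternFilter:
    ACCS = ["w", "x", "y", "z"]
    PHENO = {"w": "incompatible_cytoplasm", "x": "incompatible_cytoplasm",
             "y": "compatible_cytoplasm", "z": "compatible_cytoplasm"}

    def test_matches_exhaustive_enumeration(self):
        # one variant per possible presence pattern over 4 accessions
        patterns = list(product([0, 1], repeat=4))
        mat = _matrix(patterns, self.PHENO, self.ACCS)
        kept = pattern_filter(mat)
        expected = [
            v for v, pat in zip(mat.variants, patterns)
            if pat[0] and pat[1] and not pat[2] and not pat[3]
        ]
        assert kept == expected
        assert len(kept) == 1  # exactly the (1,1,0,0) pattern

    def test_everywhere_present_variant_excluded(self):
        mat = _matrix([[1, 1, 1, 1]], self.PHENO, self.ACCS)
        assert pattern_filter(mat) == []

    def test_invariant_under_column_permutation(self):
        rng = np.random.default_rng(1)
        present = rng.integers(0, 2, size=(12, 4)).astype(bool)
        mat = _matrix(present.tolist(), self.PHENO, self.ACCS)
        kept = {v.key for v in pattern_filter(mat)}
        perm = [2, 0, 3, 1]
        mat2 = PresenceMatrix(mat.variants, [self.ACCS[i] for i in perm],
                              present[:, perm], self.PHENO)
        assert {v.key for v in pattern_filter(mat2)} == kept

    def test_requires_both_phenotype_classes(self):
        mat = _matrix([[1, 1, 0, 0]], {a: "reference" for a in self.ACCS},
                      self.ACCS)
        with pytest.raises(ValueError, match="incompatible_cytoplasm"):
            pattern_filter(mat)


class TestFunnelAndNomination:
    def test_funnel_bins_partition_filtered_set(self):
        panel = gen_genome_panel(default_screen_config(), seed=3)
        calls = {a: align_and_call(panel.reference, q)
                 for a, q in panel.queries.items()}
        mat = PresenceMatrix.from_calls(calls, panel.truth.phenotype)
        filtered = pattern_filter(mat)
        c = funnel_counts(filtered)
        assert (c["n_noncoding"] + c["n_synonymous"]
                + c["n_nonsynonymous_substitutions"] + c["n_indels"]
                ) == c["n_pattern_variants"]

    def test_nomination_ranks_and_drops(self):
        variants = [
            Variant(0, 1, "substitution", "A", "G", "locusX", "CDS",
                    "nonsynonymous"),
            Variant(10, 11, "substitution", "A", "G", "locusX", "CDS",
                    "nonsynonymous"),
            Variant(20, 21, "substitution", "A", "G", "locusY", "CDS",
                    "synonymous"),
        ]
        table = nominate_loci(variants)
        assert list(table["locus"]) == ["locusX"]
        assert int(table["n_nonsyn_substitutions"].iloc[0]) == 2

    def test_all_noncoding_gives_empty_table(self):
        variants = [Variant(0, 1, "substitution", "A", "G", "igs",
                            "intergenic_spacer", "noncoding")]
        assert nominate_loci(variants).empty


def test_variant_tsv_roundtrip(tmp_path):
    panel = gen_genome_panel(default_screen_config(), seed=5)
    path = tmp_path / "variants.tsv"
    write_variant_tsv(panel.truth, path)
    again = read_variant_tsv(path, panel.truth.phenotype)
    assert [v.key for v in again.variants] == [v.key for v in panel.truth.variants]
    assert (again.present == panel.truth.present).all()
    assert [v.effect for v in again.variants] == [
        v.effect for v in panel.truth.variants]
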