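"""The primary/secondary determinant rule engine and state inference."""

from itertools import product

import pytest

from plastidcompat import fixtures
from plastidcompat.compatibility_model import (
    FLAGS,
    CrossOutcome,
    DeterminantGenotype,
    cytoplasm_genotype_from_features,
    forward_panel,
    infer_states,
    predict_cross,
    read_cross_tsv,
    read_genotype_tsv,
    write_cross_tsv,
    write_genotype_tsv,
)
from plastidcompat.synthetic_data import gen_cross_panel, random_determinant_panel

ALL_STATES = [DeterminantGenotype("g", *flags)
              for flags in product([False, True], repeat=4)]


def _panel():
    return {g.accession: g for g in fixtures.paper_determinant_panel()}


class TestPredictCross:
    @pytest.mark.parametrize(
        "cyt,nuc,outcome",
        [(o.cytoplasm_donor, o.nuclear_donor, o.outcome)
         for o in fixtures.paper_example_crosses()],
    )
    def test_reproduces_observed_cross(self, cyt, nuc, outcome):
        panel = _panel()
        assert predict_cross(panel[cyt], panel[nuc]) == outcome

    def test_all_selfs_compatible_in_study_panel(self):
        panel = _panel()
        for g in panel.values():
            assert predict_cross(g, g) == "compatible"

    def test_self_cross_characterization_over_all_states(self):
        # genotypes whose binding sites fit their own determinants self
        # compatibly (partial when a vacant secondary site remains); a
        # mismatched genotype selfs incompatibly, which is why such states
        # cannot describe a real selfing accession
        for g in ALL_STATES:
            fitted = ((not g.cyt_primary or g.nuc_bind_primary)
                      and (g.cyt_primary or not g.cyt_secondary
                           or g.nuc_bind_secondary))
            vacant = (not g.cyt_primary and not g.cyt_secondary
                      and g.nuc_bind_secondary)
            got = predict_cross(g, g)
            if fitted:
                assert got == ("partial" if vacant else "compatible")
            else:
                assert got == "incompatible"

    def test_primary_masks_secondary_everywhere(self):
        for cyt, nuc in product(ALL_STATES, repeat=2):
            if not cyt.cyt_primary:
                continue
            flipped = DeterminantGenotype(
                cyt.accession, cyt.cyt_primary, not cyt.cyt_secondary,
                cyt.nuc_bind_primary, cyt.nuc_bind_secondary)
            assert predict_cross(cyt, nuc) == predict_cross(flipped, nuc)

    def test_unresolved_flags_rejected(self):
        g = DeterminantGenotype("x", True, None, True, True)
        ok = DeterminantGenotype("y", True, True, True, True)
        with pytest.raises(ValueError, match="unknown"):
            predict_cross(g, ok)


class TestForwardPanel:
    def test_closure_size_and_selfs(self):
        panel = list(_panel().values())
        outcomes = forward_panel(panel)
        assert len(outcomes) == 25
        for o in outcomes:
            if o.cytoplasm_donor == o.nuclear_donor:
                assert o.outcome == "compatible"

    def test_single_allfalse_accession(self):
        g = DeterminantGenotype("solo", False, False, False, False)
        assert forward_panel([g]) == [CrossOutcome("solo", "solo", "compatible")]


class TestCytoplasmFromFeatures:
    def test_study_accessions(self, accd_table):
        expected = {
            "VIR320": (True, True),
            "L100": (True, False),
            "721": (False, False),
            "JI1794": (False, True),
            "WL1238": (False, True),
        }
        for acc, flags in expected.items():
            assert cytoplasm_genotype_from_features(accd_table, acc) == flags

    def test_poly_e_predicate_agrees_on_duplication_carriers(
            self, accd_table, accd_alignment):
        from plastidcompat.protein_analysis import ungap
        for acc in fixtures.ACCESSIONS:
            seq = ungap(accd_alignment.row(acc))
            a = cytoplasm_genotype_from_features(accd_table, acc)
            b = cytoplasm_genotype_from_features(
                accd_table, acc, secondary_predicate="poly_e", protein_seq=seq)
            assert a == b

    def test_profile_missing_region_errors(self):
        from plastidcompat.protein_analysis import VariablePositionTable
        short = VariablePositionTable("accD", "WL1238", 100,
                                      list(fixtures.ACCESSIONS), [])
        with pytest.raises(ValueError, match="124-135"):
            cytoplasm_genotype_from_features(short, "WL1238")


class TestInferStates:
    def test_observed_crosses_identify_the_study_genotypes(self):
        res = infer_states(fixtures.paper_example_crosses(include_selfs=True))
        assert res.consistent
        assert len(res.solutions) == 4
        truth = {g.accession: g.flags for g in fixtures.paper_determinant_panel()}
        assert res.contains(truth)
        ident = res.identifiable()
        # cyt_secondary of the primary-determinant cytoplasms is masked,
        # hence free; every other flag is fixed
        for acc in fixtures.ACCESSIONS:
            for i, f in enumerate(FLAGS):
                if acc in ("VIR320", "L100") and f == "cyt_secondary":
                    assert ident[acc][f] is None
                else:
                    assert ident[acc][f] == truth[acc][i]

    def test_empty_outcomes_vacuously_consistent(self):
        res = infer_states([])
        assert res.consistent
        assert res.solutions == [{}]

    def test_inconsistent_observations_produce_minimal_core(self):
        obs = fixtures.paper_example_crosses(include_selfs=True)
        obs.append(CrossOutcome("VIR320", "L100", "incompatible"))
        res = infer_states(obs)
        assert not res.consistent
        assert res.conflict_core
        assert not infer_states(res.conflict_core,
                                res.accessions).consistent

    def test_forward_simulation_recovery(self):
        for seed in range(10):
            panel = random_determinant_panel(5, seed=seed)
            outcomes, truth = gen_cross_panel(panel)
            res = infer_states(outcomes)
            tr = {g.accession: g.flags for g in truth}
            assert res.contains(tr)
            ident = res.identifiable()
            for g in truth:
                for i, f in enumerate(FLAGS):
                    fixed = ident[g.accession][f]
                    if fixed is not None:
                        assert fixed == g.flags[i]


def test_genotype_and_cross_tsv_roundtrip(tmp_path):
    genos = fixtures.paper_determinant_panel()
    gpath = tmp_path / "geno.tsv"
    write_genotype_tsv(genos, gpath)
    assert read_genotype_tsv(gpath) == genos
    crosses = forward_panel(genos)
    cpath = tmp_path / "cross.tsv"
    write_cross_tsv(crosses, cpath)
    assert read_cross_tsv(cpath) == crosses
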