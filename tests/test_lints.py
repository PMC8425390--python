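"""The composability lint rules and generic-complex expansion."""

import itertools
import math

import pytest

from pdlint import fixtures as fx
from pdlint.lints import (
    DEFAULT_CANONICAL_SITES,
    RULE_CANONICAL_SITES,
    RULE_COMPLEX_VARIANT,
    RULE_GENERIC_SPECIFIC,
    RULE_STATE_SIGNATURE,
    RULE_UNANNOTATED_GENERIC,
    expand_generic_complex,
    lint_canonical_sites,
    lint_complex_variants,
    lint_generic_specific,
    lint_state_signature,
    run_all_lints,
)
from pdlint.model import (
    ComplexPool,
    MapModel,
    PHOSPHORYLATED,
    ProteinPool,
    StateVariable,
    UNSET,
)


class TestStateSignatureLint:
    def test_raf1_divergence_across_acsn_fragments(self, acsn_models):
        findings = [
            f
            for f in lint_state_signature(acsn_models)
            if f.protein_key == "P04049" and f.severity == "warning"
        ]
        assert len(findings) == 1
        assert findings[0].payload["n_distinct"] >= 3

    def test_consistent_single_map_is_clean(self):
        assert lint_state_signature([fx.build_fixture("acsn_canonical")]) == []

    def test_within_map_conflict_is_an_error(self):
        m = MapModel(map_name="m")
        m.add_protein(
            ProteinPool("a", "RAF1", "P04049", state={StateVariable("S338", UNSET)})
        )
        m.add_protein(ProteinPool("b", "RAF1", "P04049"))
        findings = lint_state_signature([m])
        assert [f.severity for f in findings] == ["error"]
        assert findings[0].payload["signatures"] == [[], ["S338"]]

    def test_model_order_does_not_change_findings(self, acsn_models):
        base = lint_state_signature(acsn_models)
        for perm in itertools.islice(itertools.permutations(acsn_models), 3):
            assert lint_state_signature(list(perm)) == base


class TestGenericSpecificLint:
    def test_member_and_specific_across_maps_flagged(self):
        models = [
            fx.build_fixture("acsn_canonical"),
            fx.build_fixture("acsn_emt_raf1_detailed"),
        ]
        keys = {
            f.protein_key
            for f in lint_generic_specific(models)
            if f.rule_id == RULE_GENERIC_SPECIFIC
        }
        assert {"Q02750", "P36507", "P27361", "P28482"} <= keys

    def test_unannotated_generic_reported_as_info(self):
        m = MapModel(map_name="m")
        m.add_protein(ProteinPool("g", "MEK", "MEK", is_generic=True))
        findings = lint_generic_specific([m])
        assert [(f.rule_id, f.severity) for f in findings] == [
            (RULE_UNANNOTATED_GENERIC, "info")
        ]

    def test_specific_only_maps_are_clean(self):
        assert lint_generic_specific([fx.build_fixture("reactome_l1cam_mek1")]) == []


class TestCanonicalSitesLint:
    def test_l1cam_mek1_superset_and_disjoint(self):
        m = fx.build_fixture("reactome_l1cam_mek1")
        findings = [
            f
            for f in lint_canonical_sites([m])
            if f.rule_id == RULE_CANONICAL_SITES and f.severity == "warning"
        ]
        relations = {f.payload["relation"] for f in findings}
        assert relations == {"superset", "disjoint"}

    def test_canonical_set_is_clean(self):
        m = fx.build_fixture("acsn_emt_raf1_detailed")
        warnings = [
            f for f in lint_canonical_sites([m]) if f.severity == "warning"
        ]
        assert warnings == []

    def test_stateless_and_unphosphorylated_pools_ignored(self):
        m = MapModel(map_name="m")
        m.add_protein(ProteinPool("a", "MEK1", "Q02750"))
        m.add_protein(
            ProteinPool("b", "MEK1", "Q02750", state={StateVariable("S218", UNSET)})
        )
        assert lint_canonical_sites([m]) == []

    def test_unknown_protein_gets_info_note(self):
        m = MapModel(map_name="m")
        m.add_protein(
            ProteinPool(
                "a", "NOVEL", "NOVEL", state={StateVariable("S1", PHOSPHORYLATED)}
            )
        )
        findings = lint_canonical_sites([m])
        assert [f.severity for f in findings] == ["info"]

    def test_reference_is_configurable(self):
        m = fx.build_fixture("reactome_l1cam_mek1")
        ref = {"Q02750": frozenset({"S218", "S222", "T286", "T292"})}
        relations = {
            f.payload["relation"]
            for f in lint_canonical_sites([m], reference=ref)
            if f.severity == "warning"
        }
        assert relations == {"other"}  # the 2-site pool intersects the 4-site ref


def _brute_force_count(k, m):
    """Distinct multisets from substituting an m-mer of a k-member generic."""
    return len({tuple(sorted(c)) for c in itertools.product(range(k), repeat=m)})


class TestGenericComplexExpansion:
    def test_mek_dimer_expands_to_three(self):
        model = fx.build_fixture("generic_mek_dimer")
        concrete = expand_generic_complex(model, model.complexes["mek_dimer"])
        assert sorted(c.label for c in concrete) == [
            "P36507-P36507",
            "P36507-Q02750",
            "Q02750-Q02750",
        ]

    def test_single_member_generic_dimer_expands_to_one(self):
        m = MapModel(map_name="m")
        m.add_protein(
            ProteinPool("g", "MEK", "MEK", is_generic=True, members={"Q02750"})
        )
        m.add_complex(ComplexPool("cx", ("g", "g")))
        assert len(expand_generic_complex(m, m.complexes["cx"])) == 1

    def test_trimer_of_two_member_generic_expands_to_four(self):
        m = MapModel(map_name="m")
        m.add_protein(
            ProteinPool(
                "g", "MEK", "MEK", is_generic=True, members={"Q02750", "P36507"}
            )
        )
        m.add_complex(ComplexPool("cx", ("g", "g", "g")))
        assert len(expand_generic_complex(m, m.complexes["cx"])) == 4

    @pytest.mark.parametrize("k", range(1, 6))
    @pytest.mark.parametrize("mult", range(1, 6))
    def test_count_matches_stars_and_bars_and_brute_force(self, k, mult):
        members = {f"M{i:02d}" for i in range(k)}
        m = MapModel(map_name="m")
        m.add_protein(ProteinPool("g", "G", "G", is_generic=True, members=members))
        m.add_complex(ComplexPool("cx", ("g",) * mult))
        n = len(expand_generic_complex(m, m.complexes["cx"]))
        assert n == math.comb(k + mult - 1, mult) == _brute_force_count(k, mult)

    def test_states_copied_to_members(self):
        m = MapModel(map_name="m")
        m.add_protein(
            ProteinPool(
                "g",
                "MEK",
                "MEK",
                is_generic=True,
                members={"Q02750", "P36507"},
                state={StateVariable("S222", PHOSPHORYLATED)},
            )
        )
        m.add_complex(ComplexPool("cx", ("g", "g")))
        for concrete in expand_generic_complex(m, m.complexes["cx"]):
            for pool in concrete.components:
                assert pool.value_of("S222") == PHOSPHORYLATED

    def test_unannotated_generic_cannot_expand(self):
        m = MapModel(map_name="m")
        m.add_protein(ProteinPool("g", "MEK", "MEK", is_generic=True))
        m.add_complex(ComplexPool("cx", ("g", "g")))
        with pytest.raises(ValueError, match="no annotated members"):
            expand_generic_complex(m, m.complexes["cx"])


class TestComplexVariantLint:
    def test_complex_vs_free_cascade_flagged(self):
        models = [
            fx.build_fixture("panther_bcell_complexes"),
            fx.build_fixture("panther_interleukin"),
        ]
        findings = lint_complex_variants(models)
        assert findings
        assert all(f.rule_id == RULE_COMPLEX_VARIANT for f in findings)
        texts = " | ".join(f.message for f in findings)
        assert "MEK" in texts and "RAF" in texts

    def test_identical_complexes_in_two_maps_clean(self):
        a = fx.build_fixture("generic_mek_dimer", "A")
        b = fx.build_fixture("generic_mek_dimer", "B")
        assert lint_complex_variants([a, b]) == []

    def test_disjoint_protein_sets_clean(self):
        models = [
            fx.build_fixture("acsn_raf1_stateless"),
            fx.build_fixture("reactome_raf_independent"),
        ]
        assert lint_complex_variants(models) == []

    def test_order_invariance(self, panther_models):
        base = lint_complex_variants(panther_models)
        assert lint_complex_variants(list(reversed(panther_models))) == base


class TestRunAllLints:
    @pytest.mark.parametrize(
        "preset_id", [p for p in fx.list_presets() if p != "reactome_l1cam_mek1"]
    )
    def test_self_consistent_presets_have_no_error_findings(self, preset_id):
        model = fx.build_fixture(preset_id)
        errors = [f for f in run_all_lints([model]) if f.severity == "error"]
        assert errors == []

    def test_l1cam_preset_has_the_expected_error(self):
        model = fx.build_fixture("reactome_l1cam_mek1")
        errors = [f for f in run_all_lints([model]) if f.severity == "error"]
        assert [f.rule_id for f in errors] == [RULE_STATE_SIGNATURE]

    def test_rule_selection(self, acsn_models):
        only_gs = run_all_lints(acsn_models, rules=[RULE_GENERIC_SPECIFIC])
        assert only_gs
        assert {f.rule_id for f in only_gs} == {RULE_GENERIC_SPECIFIC}

    def test_unknown_rule_rejected(self, acsn_models):
        with pytest.raises(ValueError, match="unknown lint rule"):
            run_all_lints(acsn_models, rules=["NOT_A_RULE"])

    def test_default_reference_covers_quoted_pairs(self):
        assert DEFAULT_CANONICAL_SITES["Q02750"] == {"S218", "S222"}
        assert DEFAULT_CANONICAL_SITES["P27361"] == {"T202", "Y204"}
        assert DEFAULT_CANONICAL_SITES["P28482"] == {"T185", "Y187"}
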