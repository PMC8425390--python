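"""Harmonization: propagation, generic replacement, guarded merging."""

import pytest

from pdlint import fixtures as fx
from pdlint.census import expand_events, extract_phospho_events, group_patterns
from pdlint.harmonize import (
    HarmonizeError,
    MergeOptions,
    merge_maps,
    propagate_state_variables,
    replace_generic_with_specific,
)
from pdlint.lints import lint_state_signature
from pdlint.model import UNSET, state_signature


def _universe(models, key):
    return {
        sv.site
        for m in models
        for p in m.protein_pools()
        if p.protein_key == key
        for sv in p.state
    }


class TestPropagateStateVariables:
    def test_stateless_pool_gains_unset_variable(self):
        m = fx.build_fixture("acsn_raf1_stateless")
        out = propagate_state_variables(m, "P04049", {"S338"})
        raf = next(p for p in out.protein_pools() if p.protein_key == "P04049")
        assert raf.value_of("S338") == UNSET

    def test_idempotent_when_universe_equals_current_sites(self):
        m = fx.build_fixture("acsn_emt_raf1_detailed")
        uni = _universe([m], "P04049")
        assert propagate_state_variables(m, "P04049", uni) == m

    def test_monotone_sites_only_grow(self):
        m = fx.build_fixture("acsn_canonical")
        out = propagate_state_variables(m, "P04049", {"activity", "S338"})
        for pool in out.protein_pools():
            if pool.protein_key == "P04049":
                assert set(state_signature(pool)) == {"activity", "S338"}

    def test_existing_values_preserved(self):
        m = fx.build_fixture("acsn_canonical")
        out = propagate_state_variables(m, "P04049", {"activity", "S338"})
        active = [
            p
            for p in out.protein_pools()
            if p.protein_key == "P04049" and p.value_of("activity") == "active"
        ]
        assert active

    def test_universe_missing_existing_site_rejected(self):
        m = fx.build_fixture("acsn_emt_raf1_detailed")
        with pytest.raises(HarmonizeError, match="lose information"):
            propagate_state_variables(m, "P04049", {"S338"})

    def test_cross_map_finding_disappears_after_union_propagation(self):
        can = fx.build_fixture("acsn_canonical")
        emt = fx.build_fixture("acsn_emt_raf1_detailed")
        uni = _universe([can, emt], "P04049")
        harmonized = [
            propagate_state_variables(m, "P04049", uni) for m in (can, emt)
        ]
        before = [
            f for f in lint_state_signature([can, emt]) if f.protein_key == "P04049"
        ]
        after = [
            f for f in lint_state_signature(harmonized) if f.protein_key == "P04049"
        ]
        assert before and not after


class TestReplaceGenericWithSpecific:
    def test_two_member_generic_doubles_touching_processes(self):
        m = fx.build_fixture("acsn_canonical")
        before = len(m.processes)
        out, tr = replace_generic_with_specific(m, "mek_u")
        # both MEK-touching processes cloned per member, others untouched
        assert len(out.processes) == before + 2
        assert tr.details["fanout_factor"] == 2
        assert tr.details["processes_fanned_out"] == 2
        out.validate()

    def test_double_replacement_gives_four_clones_of_shared_step(self):
        m = fx.build_fixture("acsn_canonical")
        out, _ = replace_generic_with_specific(m, "mek_u")
        erk_pool = next(
            p.pool_id for p in out.protein_pools() if p.protein_key == "ERK"
        )
        out, _ = replace_generic_with_specific(out, erk_pool)
        erk_steps = [
            p
            for p in out.processes.values()
            if p.process_id.startswith("p_erk_act")
        ]
        assert len(erk_steps) == 4  # 2 MEK kinases x 2 ERK targets

    def test_single_member_policy(self):
        m = fx.build_fixture("acsn_canonical")
        mek = m.pools["mek_u"]
        object.__setattr__(mek, "members", frozenset({"Q02750"}))
        object.__setattr__(m.pools["mek_p"], "members", frozenset({"Q02750"}))
        out, _ = replace_generic_with_specific(m, "mek_u", policy="keep_single_member")
        keys = {p.protein_key for p in out.protein_pools()}
        assert "MEK" not in keys and "Q02750" in keys

    def test_single_member_policy_rejects_multi_member(self):
        m = fx.build_fixture("acsn_canonical")
        with pytest.raises(HarmonizeError):
            replace_generic_with_specific(m, "mek_u", policy="keep_single_member")

    def test_unannotated_generic_rejected(self):
        m = fx.build_fixture("acsn_canonical")
        for pid in ("mek_u", "mek_p"):
            object.__setattr__(m.pools[pid], "members", frozenset())
        with pytest.raises(HarmonizeError, match="no annotated members"):
            replace_generic_with_specific(m, "mek_u")

    @pytest.mark.parametrize(
        "preset_id", ["acsn_canonical", "panther_fgf", "panther_bcell_complexes"]
    )
    def test_census_equals_expanded_census_of_original(self, preset_id):
        """Replacing generics preserves quadruplet semantics: the census of
        the transformed map equals the member-expanded census of the
        original."""
        m = fx.build_fixture(preset_id)
        expanded = expand_events(
            extract_phospho_events(m), {m.map_name: m}
        )
        expected = {
            (r.pattern.as_tuple(), r.total)
            for r in group_patterns(expanded)
        }
        out = m
        for key in ("MEK", "ERK", "RAF"):
            pools = [p for p in out.protein_pools() if p.protein_key == key]
            if pools and pools[0].is_generic:
                out, _ = replace_generic_with_specific(out, pools[0].pool_id)
        got = {
            (r.pattern.as_tuple(), r.total)
            for r in group_patterns(extract_phospho_events(out))
        }
        assert got == expected


class TestMergeMaps:
    def test_self_merge_deduplicates(self):
        a = fx.build_fixture("acsn_canonical", "A")
        b = fx.build_fixture("acsn_canonical", "B")
        report = merge_maps([a, b])
        assert report.ok
        assert len(report.merged.pools) == len(a.pools)
        assert len(report.merged.processes) == len(a.processes)

    def test_conflicting_maps_blocked_without_harmonization(self):
        report = merge_maps(
            [
                fx.build_fixture("acsn_canonical"),
                fx.build_fixture("acsn_emt_raf1_detailed"),
            ]
        )
        assert not report.ok and report.merged is None
        assert "P04049" in {f.protein_key for f in report.blocking}

    def test_auto_harmonize_unions_raf1_universe(self):
        report = merge_maps(
            [
                fx.build_fixture("acsn_canonical"),
                fx.build_fixture("acsn_emt_raf1_detailed"),
            ],
            MergeOptions(auto_harmonize=True),
        )
        assert report.ok
        sigs = {
            state_signature(p)
            for p in report.merged.protein_pools()
            if p.protein_key == "P04049"
        }
        assert len(sigs) == 1
        assert len(next(iter(sigs))) == 7

    def test_merged_map_has_no_within_map_errors(self):
        report = merge_maps(
            [
                fx.build_fixture("acsn_canonical"),
                fx.build_fixture("acsn_emt_raf1_detailed"),
            ],
            MergeOptions(auto_harmonize=True),
        )
        errors = [
            f
            for f in lint_state_signature([report.merged])
            if f.severity == "error"
        ]
        assert errors == []

    def test_remerging_result_with_input_subset_is_noop(self):
        can = fx.build_fixture("acsn_canonical")
        emt = fx.build_fixture("acsn_emt_raf1_detailed")
        merged = merge_maps([can, emt], MergeOptions(auto_harmonize=True)).merged
        again = merge_maps([merged, emt], MergeOptions(auto_harmonize=True))
        assert again.ok
        assert len(again.merged.pools) == len(merged.pools)
        assert len(again.merged.complexes) == len(merged.complexes)
        assert len(again.merged.processes) == len(merged.processes)

    def test_replace_generics_merge_is_clean(self):
        report = merge_maps(
            [
                fx.build_fixture("acsn_canonical"),
                fx.build_fixture("acsn_emt_raf1_detailed"),
            ],
            MergeOptions(auto_harmonize=True, replace_generics=True),
        )
        assert report.ok
        keys = {p.protein_key for p in report.merged.protein_pools()}
        assert "MEK" not in keys and "ERK" not in keys
        errors = [
            f
            for f in lint_state_signature([report.merged])
            if f.severity == "error"
        ]
        assert errors == []

    def test_merge_needs_two_maps(self):
        with pytest.raises(ValueError):
            merge_maps([fx.build_fixture("acsn_canonical")])
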