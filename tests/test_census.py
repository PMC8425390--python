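"""Quadruplet extraction, grouping, repeat filtering and divergence."""

import pytest

from pdlint import fixtures as fx
from pdlint.census import (
    ExtractionConfig,
    count_representation_versions,
    expand_events,
    extract_phospho_events,
    filter_repeated,
    find_divergent_representations,
    group_patterns,
)
from pdlint.model import (
    CATALYSIS,
    MapModel,
    PHOSPHORYLATED,
    Process,
    ProteinPool,
    StateVariable,
    UNSET,
)


def _two_pool_phospho_map(name="m", n_processes=1, catalyzed=True):
    m = MapModel(map_name=name)
    m.add_protein(
        ProteinPool("t_u", "SUB", "SUB", state={StateVariable("S100", UNSET)})
    )
    m.add_protein(
        ProteinPool("t_p", "SUB", "SUB", state={StateVariable("S100", PHOSPHORYLATED)})
    )
    m.add_protein(ProteinPool("k", "KIN", "KIN"))
    for i in range(n_processes):
        m.add_process(
            Process(
                f"p{i}",
                "state_transition",
                reactants=("t_u",),
                products=("t_p",),
                modulators=((("k", CATALYSIS),) if catalyzed else ()),
            )
        )
    return m.validate()


class TestExtraction:
    def test_detailed_mek1_step_yields_two_site_events(self):
        """A process gaining S218 and S222 emits one quadruplet per site."""
        m = fx.build_fixture("acsn_emt_raf1_detailed")
        events = [
            e for e in extract_phospho_events(m) if e.target == "Q02750"
        ]
        assert {(e.kinase, e.target, e.site) for e in events} == {
            ("P04049", "Q02750", "S218"),
            ("P04049", "Q02750", "S222"),
        }
        assert {e.process_id for e in events} == {"p_mek1"}

    def test_uncatalyzed_gain_is_not_an_event(self):
        m = _two_pool_phospho_map(catalyzed=False)
        assert extract_phospho_events(m) == []

    def test_map_without_processes_yields_nothing(self):
        m = fx.build_fixture("generic_mek_dimer")
        assert extract_phospho_events(m) == []

    def test_flag_gain_has_empty_site_token(self):
        m = fx.build_fixture("acsn_canonical")
        assert {e.site for e in extract_phospho_events(m)} == {""}

    def test_mode_restriction(self):
        m = fx.build_fixture("acsn_cell_survival_sef")
        free_only = extract_phospho_events(m, ExtractionConfig(mode="free"))
        cx_only = extract_phospho_events(m, ExtractionConfig(mode="complex"))
        assert {e.mode for e in free_only} == {"free"}
        assert {e.mode for e in cx_only} == {"in_complex"}

    def test_stimulation_arcs_only_with_config(self):
        m = _two_pool_phospho_map()
        proc = m.processes["p0"]
        m.processes["p0"] = Process(
            "p0",
            "state_transition",
            reactants=proc.reactants,
            products=proc.products,
            modulators=(("k", "stimulation"),),
        )
        assert extract_phospho_events(m) == []
        with_stim = extract_phospho_events(
            m, ExtractionConfig(include_stimulation=True)
        )
        assert len(with_stim) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_extraction_equals_embedded_ground_truth(self, seed):
        """The central oracle: planted events are recovered exactly."""
        model, ground_truth = fx.generate_random_map(
            fx.RandomMapSpec(seed=seed, n_processes=20)
        )
        assert set(extract_phospho_events(model)) == set(ground_truth)


class TestGrouping:
    def test_empty_events_give_empty_census(self):
        assert len(group_patterns([])) == 0

    def test_canonical_triplet_counted_across_three_maps(self, acsn_models):
        events = [e for m in acsn_models for e in extract_phospho_events(m)]
        census = group_patterns(events)
        row = census.row_for("P04049", "MEK", "")
        assert row is not None
        assert row.n_maps == 3
        assert row.total == 3

    def test_duplicate_processes_within_one_map_both_count(self):
        m = _two_pool_phospho_map(n_processes=2)
        census = group_patterns(extract_phospho_events(m))
        row = census.row_for("KIN", "SUB", "S100")
        assert row.per_map == (("m", 2),)
        assert row.total == 2

    def test_total_is_sum_of_per_map_counts(self, acsn_models):
        events = [e for m in acsn_models for e in extract_phospho_events(m)]
        for row in group_patterns(events):
            assert row.total == sum(n for _, n in row.per_map)

    def test_rows_sorted_by_triplet(self, acsn_models):
        events = [e for m in acsn_models for e in extract_phospho_events(m)]
        trips = [r.pattern.as_tuple() for r in group_patterns(events)]
        assert trips == sorted(trips)


class TestFilterRepeated:
    def test_all_singletons_filtered_out(self):
        m = fx.build_fixture("acsn_emt_raf1_detailed")
        census = group_patterns(extract_phospho_events(m))
        assert len(filter_repeated(census)) == 0

    def test_repeated_rows_retained_with_totals(self, acsn_models):
        events = [e for m in acsn_models for e in extract_phospho_events(m)]
        repeated = filter_repeated(group_patterns(events))
        assert repeated.row_for("P04049", "MEK", "").total == 3

    def test_matches_brute_force_filter(self, acsn_models, panther_models):
        events = [
            e
            for m in acsn_models + panther_models
            for e in extract_phospho_events(m)
        ]
        census = group_patterns(events)
        expected = {r.pattern for r in census if r.total >= 2}
        assert {r.pattern for r in filter_repeated(census)} == expected
        assert set(filter_repeated(census).rows) <= set(census.rows)


class TestExpandEvents:
    def test_generic_participants_fan_out_per_member(self):
        m = fx.build_fixture("acsn_canonical")
        models = {m.map_name: m}
        expanded = expand_events(extract_phospho_events(m), models)
        trips = {(e.kinase, e.target, e.site) for e in expanded}
        assert trips == {
            ("P04049", "Q02750", ""),
            ("P04049", "P36507", ""),
            ("Q02750", "P27361", ""),
            ("Q02750", "P28482", ""),
            ("P36507", "P27361", ""),
            ("P36507", "P28482", ""),
        }
        assert all(e.expanded for e in expanded)

    def test_specific_events_pass_through_unexpanded(self):
        m = fx.build_fixture("acsn_emt_raf1_detailed")
        events = [e for e in extract_phospho_events(m) if e.target == "Q02750"]
        out = expand_events(events, {m.map_name: m})
        assert out == events


class TestDivergence:
    def _repeated(self, models):
        events = [e for m in models for e in extract_phospho_events(m)]
        return filter_repeated(group_patterns(events))

    def test_generic_vs_specific_target_is_divergent(self, acsn_models):
        groups = find_divergent_representations(
            self._repeated(acsn_models), acsn_models
        )
        raf_mek1 = [g for g in groups if (g.kinase, g.target) == ("P04049", "Q02750")]
        assert raf_mek1
        reps = dict(raf_mek1[0].per_map)
        assert reps["Adaptive Immunity"].target_generic
        assert not reps["EMT and Senescence"].target_generic
        assert reps["EMT and Senescence"].sites == {"S218", "S222"}
        assert reps["Adaptive Immunity"].sites == {""}

    def test_identical_maps_under_two_names_not_divergent(self):
        models = [
            fx.build_fixture("acsn_canonical", "A"),
            fx.build_fixture("acsn_canonical", "B"),
        ]
        assert find_divergent_representations(self._repeated(models), models) == []

    def test_complex_vs_free_mode_is_divergent(self):
        models = [
            fx.build_fixture("panther_bcell_complexes"),
            fx.build_fixture("panther_interleukin"),
        ]
        groups = find_divergent_representations(self._repeated(models), models)
        assert groups
        for g in groups:
            modes = {
                mode for _, rep in g.per_map for mode in rep.modes
            }
            assert modes == {"free", "in_complex"}

    def test_three_panther_maps_give_three_versions(self, panther_models):
        groups = find_divergent_representations(
            self._repeated(panther_models), panther_models
        )
        assert count_representation_versions(groups) == 3


class TestMapRenamingInvariance:
    def test_totals_and_divergence_survive_renaming(self, acsn_models):
        renamed = []
        mapping = {}
        for i, m in enumerate(acsn_models):
            c = m.copy()
            c.map_name = f"map{i:02d}"
            mapping[m.map_name] = c.map_name
            renamed.append(c)
        ev_a = [e for m in acsn_models for e in extract_phospho_events(m)]
        ev_b = [e for m in renamed for e in extract_phospho_events(m)]
        census_a = group_patterns(ev_a)
        census_b = group_patterns(ev_b)
        totals_a = {r.pattern.as_tuple(): r.total for r in census_a}
        totals_b = {r.pattern.as_tuple(): r.total for r in census_b}
        assert totals_a == totals_b
        ga = find_divergent_representations(filter_repeated(census_a), acsn_models)
        gb = find_divergent_representations(filter_repeated(census_b), renamed)
        assert {(g.kinase, g.target, g.n_versions) for g in ga} == {
            (g.kinase, g.target, g.n_versions) for g in gb
        }
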