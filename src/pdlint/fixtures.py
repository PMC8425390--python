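"""Synthetic PD-map fixtures.

Two sources of test substrate, no downloads required:

* **Presets** — small programmatic reconstructions of the RAS–RAF–MEK–ERK
  fragments found in the ACSN, PANTHER and Reactome pathway resources, each
  exercising one published representation style (generic vs specific pools,
  site-level detail, complex-bound steps, conflicting state universes).
  Presets capture the *testable content* of those fragments — which pools
  exist, which state variables they show, which steps are catalyzed
  phosphorylations — not their layout or full species inventory.

* **Seeded random maps** — maps with controllable numbers of proteins,
  generics, complexes and processes, generated together with the exact list
  of catalyzed phosphorylation events planted in them.  That embedded
  ground truth is the oracle for the census extraction stage.

Placeholder conventions (counts are asserted by tests, site names are not
biological claims): the single unnamed RAF1 state of the canonical fragments
is the flag ``activity``; the six RAF1 phosphosites of the detailed fragment
are six literature-canonical regulatory sites; phosphorylation drawn without
a site is the flag ``phospho`` with value ``P``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Optional

from pdlint.census import FREE, IN_COMPLEX, PhosphoEvent
from pdlint.model import (
    ASSOCIATION,
    CATALYSIS,
    GENERIC_PROCESS,
    PHOSPHORYLATED,
    STATE_TRANSITION,
    UNSET,
    ComplexPool,
    MapModel,
    Process,
    ProteinPool,
    StateVariable,
    normalize_protein_identity,
    preferred_label,
)

__all__ = [
    "list_presets",
    "preset_description",
    "build_fixture",
    "RandomMapSpec",
    "generate_random_map",
    "RAF1_DETAILED_SITES",
    "ACSN_CANONICAL_MAP_NAMES",
]

#: Placeholder residue set for the six-phosphosite RAF1 of the detailed
#: EMT-style fragment (regulatory sites of RAF1; configurable, not asserted
#: as the figure's actual labels).
RAF1_DETAILED_SITES = ("S259", "S289", "S296", "S301", "S338", "S621")

#: The three maps sharing the canonical cascade representation.
ACSN_CANONICAL_MAP_NAMES = (
    "Adaptive Immunity",
    "Innate Immunity",
    "Cancer-Associated Fibroblasts",
)

_ACTIVITY = "activity"
_PHOSPHO_FLAG = "phospho"

_RAS_MEMBERS = frozenset({"P01112", "P01116", "P01111"})
_RAF_MEMBERS = frozenset({"P10398", "P15056", "P04049"})
_MEK_MEMBERS = frozenset({"Q02750", "P36507"})
_ERK_MEMBERS = frozenset({"P27361", "P28482"})

_COMP = "cytosol"


def _protein(
    model: MapModel,
    pool_id: str,
    label: str,
    sites: tuple[tuple[str, str], ...] = (),
    generic: bool = False,
    members: frozenset[str] = frozenset(),
    uniprot: Optional[str] = None,
) -> ProteinPool:
    ups = frozenset({uniprot}) if uniprot else frozenset()
    return model.add_protein(
        ProteinPool(
            pool_id=pool_id,
            label=label,
            protein_key=normalize_protein_identity(label, ups),
            uniprot_ids=ups,
            is_generic=generic,
            members=members,
            state=frozenset(StateVariable(s, v) for s, v in sites),
            compartment=_COMP,
        )
    )


def _phospho_step(
    model: MapModel,
    process_id: str,
    reactant: ProteinPool,
    product: ProteinPool,
    kinase: ProteinPool,
) -> Process:
    return model.add_process(
        Process(
            process_id=process_id,
            kind=STATE_TRANSITION,
            reactants=(reactant.pool_id,),
            products=(product.pool_id,),
            modulators=((kinase.pool_id, CATALYSIS),),
        )
    )


# -- preset builders -----------------------------------------------------------


def _acsn_canonical(map_name: str) -> MapModel:
    """Canonical RAS→RAF1→generic MEK→generic ERK cascade.

    RAF1 shows exactly one state variable; MEK/ERK are generic pools with
    annotated members; each activation is a catalyzed phosphorylation with
    an unspecified site (the ``phospho`` flag).
    """
    m = MapModel(map_name=map_name)
    ras = _protein(m, "ras", "RAS", generic=True, members=_RAS_MEMBERS)
    raf_u = _protein(m, "raf1_u", "RAF1", ((_ACTIVITY, UNSET),), uniprot="P04049")
    raf_a = _protein(m, "raf1_a", "RAF1", ((_ACTIVITY, "active"),), uniprot="P04049")
    mek_u = _protein(
        m, "mek_u", "MEK", ((_PHOSPHO_FLAG, UNSET),), generic=True, members=_MEK_MEMBERS
    )
    mek_p = _protein(
        m,
        "mek_p",
        "MEK",
        ((_PHOSPHO_FLAG, PHOSPHORYLATED),),
        generic=True,
        members=_MEK_MEMBERS,
    )
    erk_u = _protein(
        m, "erk_u", "ERK", ((_PHOSPHO_FLAG, UNSET),), generic=True, members=_ERK_MEMBERS
    )
    erk_p = _protein(
        m,
        "erk_p",
        "ERK",
        ((_PHOSPHO_FLAG, PHOSPHORYLATED),),
        generic=True,
        members=_ERK_MEMBERS,
    )
    _phospho_step(m, "p_raf_act", raf_u, raf_a, ras)  # activity gain, not a P-gain
    _phospho_step(m, "p_mek_act", mek_u, mek_p, raf_a)
    _phospho_step(m, "p_erk_act", erk_u, erk_p, mek_p)
    return m


def _acsn_raf1_stateless(map_name: str) -> MapModel:
    """A RAF1 pool with zero state variables, in an unrelated association."""
    m = MapModel(map_name=map_name)
    raf = _protein(m, "raf1", "RAF1", uniprot="P04049")
    bad = _protein(m, "bad", "BAD")
    cx = m.add_complex(
        ComplexPool(pool_id="cx_raf_bad", components=("raf1", "bad"), compartment=_COMP)
    )
    m.add_process(
        Process(
            process_id="p_bind",
            kind=ASSOCIATION,
            reactants=(raf.pool_id, bad.pool_id),
            products=(cx.pool_id,),
        )
    )
    return m


def _acsn_cell_survival_sef(map_name: str) -> MapModel:
    """Canonical MEK→ERK activation plus a SEF/IL17RD-bound complex variant."""
    m = MapModel(map_name=map_name)
    mek_p = _protein(
        m,
        "mek_p",
        "MEK",
        ((_PHOSPHO_FLAG, PHOSPHORYLATED),),
        generic=True,
        members=_MEK_MEMBERS,
    )
    erk_u = _protein(
        m, "erk_u", "ERK", ((_PHOSPHO_FLAG, UNSET),), generic=True, members=_ERK_MEMBERS
    )
    erk_p = _protein(
        m,
        "erk_p",
        "ERK",
        ((_PHOSPHO_FLAG, PHOSPHORYLATED),),
        generic=True,
        members=_ERK_MEMBERS,
    )
    sef = _protein(m, "sef", "SEF", uniprot="Q8NFM7")
    _phospho_step(m, "p_erk_free", erk_u, erk_p, mek_p)
    c_in = m.add_complex(
        ComplexPool(
            pool_id="cx_sef_in", components=("sef", "mek_p", "erk_u"), compartment=_COMP
        )
    )
    c_out = m.add_complex(
        ComplexPool(
            pool_id="cx_sef_out",
            components=("sef", "mek_p", "erk_p"),
            compartment=_COMP,
        )
    )
    m.add_process(
        Process(
            process_id="p_erk_in_sef",
            kind=STATE_TRANSITION,
            reactants=(c_in.pool_id,),
            products=(c_out.pool_id,),
            modulators=((mek_p.pool_id, CATALYSIS),),
        )
    )
    return m


def _acsn_emt_raf1_detailed(map_name: str) -> MapModel:
    """Detailed fragment: RAF1 with 7 state variables (6 phosphosites + one
    flag) and specific MEK1/MEK2/ERK1/ERK2 pools with their activating sites."""
    m = MapModel(map_name=map_name)
    ras = _protein(m, "ras", "RAS", generic=True, members=_RAS_MEMBERS)
    raf_all_unset = tuple((s, UNSET) for s in RAF1_DETAILED_SITES) + ((_ACTIVITY, UNSET),)
    raf_active = tuple(
        (s, PHOSPHORYLATED if s == "S338" else UNSET) for s in RAF1_DETAILED_SITES
    ) + ((_ACTIVITY, UNSET),)
    raf_u = _protein(m, "raf1_u", "RAF1", raf_all_unset, uniprot="P04049")
    raf_a = _protein(m, "raf1_a", "RAF1", raf_active, uniprot="P04049")
    mek1_u = _protein(m, "mek1_u", "MEK1", (("S218", UNSET), ("S222", UNSET)), uniprot="Q02750")
    mek1_p = _protein(
        m, "mek1_p", "MEK1", (("S218", PHOSPHORYLATED), ("S222", PHOSPHORYLATED)), uniprot="Q02750"
    )
    mek2_u = _protein(m, "mek2_u", "MEK2", (("S222", UNSET), ("S226", UNSET)), uniprot="P36507")
    mek2_p = _protein(
        m, "mek2_p", "MEK2", (("S222", PHOSPHORYLATED), ("S226", PHOSPHORYLATED)), uniprot="P36507"
    )
    erk1_u = _protein(m, "erk1_u", "ERK1", (("T202", UNSET), ("Y204", UNSET)), uniprot="P27361")
    erk1_p = _protein(
        m, "erk1_p", "ERK1", (("T202", PHOSPHORYLATED), ("Y204", PHOSPHORYLATED)), uniprot="P27361"
    )
    erk2_u = _protein(m, "erk2_u", "ERK2", (("T185", UNSET), ("Y187", UNSET)), uniprot="P28482")
    erk2_p = _protein(
        m, "erk2_p", "ERK2", (("T185", PHOSPHORYLATED), ("Y187", PHOSPHORYLATED)), uniprot="P28482"
    )
    _phospho_step(m, "p_raf_act", raf_u, raf_a, ras)
    _phospho_step(m, "p_mek1", mek1_u, mek1_p, raf_a)
    _phospho_step(m, "p_mek2", mek2_u, mek2_p, raf_a)
    _phospho_step(m, "p_erk1", erk1_u, erk1_p, mek1_p)
    _phospho_step(m, "p_erk2", erk2_u, erk2_p, mek2_p)
    return m


def _panther_interleukin(map_name: str) -> MapModel:
    """Canonical cascade, specific RAF1, site-unspecified phosphorylation."""
    m = MapModel(map_name=map_name)
    ras = _protein(m, "ras", "RAS", generic=True, members=_RAS_MEMBERS)
    raf_u = _protein(m, "raf1_u", "RAF1", ((_ACTIVITY, UNSET),), uniprot="P04049")
    raf_a = _protein(m, "raf1_a", "RAF1", ((_ACTIVITY, "active"),), uniprot="P04049")
    mek_u = _protein(
        m, "mek_u", "MEK", ((_PHOSPHO_FLAG, UNSET),), generic=True, members=_MEK_MEMBERS
    )
    mek_p = _protein(
        m, "mek_p", "MEK", ((_PHOSPHO_FLAG, PHOSPHORYLATED),), generic=True, members=_MEK_MEMBERS
    )
    erk_u = _protein(
        m, "erk_u", "ERK", ((_PHOSPHO_FLAG, UNSET),), generic=True, members=_ERK_MEMBERS
    )
    erk_p = _protein(
        m, "erk_p", "ERK", ((_PHOSPHO_FLAG, PHOSPHORYLATED),), generic=True, members=_ERK_MEMBERS
    )
    _phospho_step(m, "p_raf_act", raf_u, raf_a, ras)
    _phospho_step(m, "p_mek", mek_u, mek_p, raf_a)
    _phospho_step(m, "p_erk", erk_u, erk_p, mek_p)
    return m


def _panther_fgf(map_name: str) -> MapModel:
    """Canonical cascade, generic RAF, explicit phosphosite detail."""
    m = MapModel(map_name=map_name)
    raf = _protein(m, "raf", "RAF", generic=True, members=_RAF_MEMBERS)
    mek_u = _protein(
        m, "mek_u", "MEK", (("S218", UNSET), ("S222", UNSET)), generic=True, members=_MEK_MEMBERS
    )
    mek_p = _protein(
        m,
        "mek_p",
        "MEK",
        (("S218", PHOSPHORYLATED), ("S222", PHOSPHORYLATED)),
        generic=True,
        members=_MEK_MEMBERS,
    )
    erk_u = _protein(
        m, "erk_u", "ERK", (("T202", UNSET), ("Y204", UNSET)), generic=True, members=_ERK_MEMBERS
    )
    erk_p = _protein(
        m,
        "erk_p",
        "ERK",
        (("T202", PHOSPHORYLATED), ("Y204", PHOSPHORYLATED)),
        generic=True,
        members=_ERK_MEMBERS,
    )
    _phospho_step(m, "p_mek", mek_u, mek_p, raf)
    _phospho_step(m, "p_erk", erk_u, erk_p, mek_p)
    return m


def _panther_bcell_complexes(map_name: str) -> MapModel:
    """Complex-formation variant: phosphorylation happens in small complexes."""
    m = MapModel(map_name=map_name)
    ras = _protein(m, "ras", "RAS", generic=True, members=_RAS_MEMBERS)
    raf = _protein(m, "raf", "RAF", generic=True, members=_RAF_MEMBERS)
    mek_u = _protein(
        m, "mek_u", "MEK", ((_PHOSPHO_FLAG, UNSET),), generic=True, members=_MEK_MEMBERS
    )
    mek_p = _protein(
        m, "mek_p", "MEK", ((_PHOSPHO_FLAG, PHOSPHORYLATED),), generic=True, members=_MEK_MEMBERS
    )
    erk_u = _protein(
        m, "erk_u", "ERK", ((_PHOSPHO_FLAG, UNSET),), generic=True, members=_ERK_MEMBERS
    )
    erk_p = _protein(
        m, "erk_p", "ERK", ((_PHOSPHO_FLAG, PHOSPHORYLATED),), generic=True, members=_ERK_MEMBERS
    )
    c1 = m.add_complex(
        ComplexPool(pool_id="cx_rrm_u", components=("ras", "raf", "mek_u"), compartment=_COMP)
    )
    c2 = m.add_complex(
        ComplexPool(pool_id="cx_rrm_p", components=("ras", "raf", "mek_p"), compartment=_COMP)
    )
    c3 = m.add_complex(
        ComplexPool(pool_id="cx_me_u", components=("mek_p", "erk_u"), compartment=_COMP)
    )
    c4 = m.add_complex(
        ComplexPool(pool_id="cx_me_p", components=("mek_p", "erk_p"), compartment=_COMP)
    )
    m.add_process(
        Process(
            process_id="p_assemble",
            kind=ASSOCIATION,
            reactants=("ras", "raf", "mek_u"),
            products=(c1.pool_id,),
        )
    )
    m.add_process(
        Process(
            process_id="p_mek_in_cx",
            kind=STATE_TRANSITION,
            reactants=(c1.pool_id,),
            products=(c2.pool_id,),
            modulators=((raf.pool_id, CATALYSIS),),
        )
    )
    m.add_process(
        Process(
            process_id="p_bind_erk",
            kind=ASSOCIATION,
            reactants=(mek_p.pool_id, erk_u.pool_id),
            products=(c3.pool_id,),
        )
    )
    m.add_process(
        Process(
            process_id="p_erk_in_cx",
            kind=STATE_TRANSITION,
            reactants=(c3.pool_id,),
            products=(c4.pool_id,),
            modulators=((mek_p.pool_id, CATALYSIS),),
        )
    )
    return m


def _reactome_raf_map_kinase(map_name: str) -> MapModel:
    """Cascade with generic RAF ({ARAF,BRAF,RAF1}) and a generic MEK1/2 dimer."""
    m = MapModel(map_name=map_name)
    raf = _protein(m, "raf", "RAF", generic=True, members=_RAF_MEMBERS)
    mek_u = _protein(
        m, "mekg_u", "MEK", (("S218", UNSET), ("S222", UNSET)), generic=True, members=_MEK_MEMBERS
    )
    mek_p = _protein(
        m,
        "mekg_p",
        "MEK",
        (("S218", PHOSPHORYLATED), ("S222", PHOSPHORYLATED)),
        generic=True,
        members=_MEK_MEMBERS,
    )
    erk_u = _protein(
        m, "erk_u", "ERK", (("T185", UNSET), ("Y187", UNSET)), generic=True, members=_ERK_MEMBERS
    )
    erk_p = _protein(
        m,
        "erk_p",
        "ERK",
        (("T185", PHOSPHORYLATED), ("Y187", PHOSPHORYLATED)),
        generic=True,
        members=_ERK_MEMBERS,
    )
    d_u = m.add_complex(
        ComplexPool(pool_id="dimer_u", components=("mekg_u", "mekg_u"), compartment=_COMP)
    )
    d_p = m.add_complex(
        ComplexPool(pool_id="dimer_p", components=("mekg_p", "mekg_p"), compartment=_COMP)
    )
    m.add_process(
        Process(
            process_id="p_mek_dimer",
            kind=STATE_TRANSITION,
            reactants=(d_u.pool_id,),
            products=(d_p.pool_id,),
            modulators=((raf.pool_id, CATALYSIS),),
        )
    )
    m.add_process(
        Process(
            process_id="p_erk",
            kind=STATE_TRANSITION,
            reactants=(erk_u.pool_id,),
            products=(erk_p.pool_id,),
            modulators=((d_p.pool_id, CATALYSIS),),
        )
    )
    return m


def _reactome_raf_independent(map_name: str) -> MapModel:
    """RAF-independent ERK activation; MEK/ERK sites match the cascade map."""
    m = MapModel(map_name=map_name)
    mek_p = _protein(
        m,
        "mek_p",
        "MEK",
        (("S218", PHOSPHORYLATED), ("S222", PHOSPHORYLATED)),
        generic=True,
        members=_MEK_MEMBERS,
    )
    erk_u = _protein(
        m, "erk_u", "ERK", (("T185", UNSET), ("Y187", UNSET)), generic=True, members=_ERK_MEMBERS
    )
    erk_p = _protein(
        m,
        "erk_p",
        "ERK",
        (("T185", PHOSPHORYLATED), ("Y187", PHOSPHORYLATED)),
        generic=True,
        members=_ERK_MEMBERS,
    )
    _phospho_step(m, "p_erk", erk_u, erk_p, mek_p)
    return m


def _reactome_l1cam_mek1(map_name: str) -> MapModel:
    """Two MEK1 entities with conflicting phosphosite sets (the anomaly case)."""
    m = MapModel(map_name=map_name)
    mek1_full = _protein(
        m,
        "mek1_4p",
        "MEK1",
        (
            ("S218", PHOSPHORYLATED),
            ("S222", PHOSPHORYLATED),
            ("T286", PHOSPHORYLATED),
            ("T292", PHOSPHORYLATED),
        ),
        uniprot="Q02750",
    )
    mek1_tt = _protein(
        m,
        "mek1_2p",
        "MEK1",
        (("T286", PHOSPHORYLATED), ("T292", PHOSPHORYLATED)),
        uniprot="Q02750",
    )
    m.add_process(
        Process(
            process_id="p_link",
            kind=GENERIC_PROCESS,
            reactants=(mek1_tt.pool_id,),
            products=(mek1_full.pool_id,),
        )
    )
    return m


def _generic_mek_dimer(map_name: str) -> MapModel:
    """One dimer complex whose single generic component lumps MEK1 and MEK2."""
    m = MapModel(map_name=map_name)
    _protein(m, "mek", "MEK", generic=True, members=_MEK_MEMBERS)
    m.add_complex(
        ComplexPool(pool_id="mek_dimer", components=("mek", "mek"), compartment=_COMP)
    )
    return m


@dataclass(frozen=True)
class _Preset:
    preset_id: str
    description: str
    default_map_name: str
    builder: Callable[[str], MapModel]


_PRESETS: tuple[_Preset, ...] = (
    _Preset(
        "acsn_canonical",
        "Canonical RAS-RAF1-MEK-ERK cascade with generic MEK/ERK (instantiable "
        "under any map name; shared by three maps).",
        ACSN_CANONICAL_MAP_NAMES[0],
        _acsn_canonical,
    ),
    _Preset(
        "acsn_raf1_stateless",
        "RAF1 with no state variables, embedded in an unrelated association.",
        "Regulated Cell Death",
        _acsn_raf1_stateless,
    ),
    _Preset(
        "acsn_cell_survival_sef",
        "Canonical MEK-ERK activation plus a SEF/IL17RD-bound complex variant.",
        "Cell Survival",
        _acsn_cell_survival_sef,
    ),
    _Preset(
        "acsn_emt_raf1_detailed",
        "RAF1 with seven state variables (six phosphosites + activity flag) and "
        "specific MEK1/MEK2/ERK1/ERK2 with activating sites.",
        "EMT and Senescence",
        _acsn_emt_raf1_detailed,
    ),
    _Preset(
        "panther_interleukin",
        "Canonical cascade, specific RAF1, site-unspecified phosphorylation.",
        "Interleukin Signalling Pathway",
        _panther_interleukin,
    ),
    _Preset(
        "panther_fgf",
        "Canonical cascade, generic RAF, explicit phosphosite detail.",
        "FGF Signalling Pathway",
        _panther_fgf,
    ),
    _Preset(
        "panther_bcell_complexes",
        "RAS-RAF-MEK complex-formation variant with in-complex phosphorylation.",
        "B Cell Activation Pathway",
        _panther_bcell_complexes,
    ),
    _Preset(
        "reactome_raf_map_kinase",
        "Cascade with generic RAF {ARAF,BRAF,RAF1} and a generic MEK1/2 dimer.",
        "RAF-MAP Kinase Cascade",
        _reactome_raf_map_kinase,
    ),
    _Preset(
        "reactome_raf_independent",
        "RAF-independent ERK activation with consistent MEK/ERK phosphosites.",
        "RAF-independent MAPK1/3 Activation",
        _reactome_raf_independent,
    ),
    _Preset(
        "reactome_l1cam_mek1",
        "Two MEK1 entities with conflicting phosphosite sets (within-map clash).",
        "L1CAM Interactions",
        _reactome_l1cam_mek1,
    ),
    _Preset(
        "generic_mek_dimer",
        "A dimer complex of a single generic component with members MEK1, MEK2.",
        "MEK Dimer",
        _generic_mek_dimer,
    ),
)

_PRESET_INDEX = {p.preset_id: p for p in _PRESETS}


def list_presets() -> list[str]:
    """Stable list of available preset ids."""
    return [p.preset_id for p in _PRESETS]


def preset_description(preset_id: str) -> str:
    return _require(preset_id).description


def _require(preset_id: str) -> _Preset:
    if preset_id not in _PRESET_INDEX:
        raise ValueError(
            f"unknown preset {preset_id!r}; valid ids: {', '.join(list_presets())}"
        )
    return _PRESET_INDEX[preset_id]


def build_fixture(preset_id: str, map_name: Optional[str] = None) -> MapModel:
    """Build a preset map (deterministic; same preset twice compares equal)."""
    preset = _require(preset_id)
    model = preset.builder(map_name or preset.default_map_name)
    model.provenance = f"preset:{preset_id}"
    return model.validate()


def build_acsn_collection() -> list[MapModel]:
    """The six ACSN-style fragments: the canonical cascade under its three
    map names, plus the stateless, SEF and detailed variants."""
    models = [build_fixture("acsn_canonical", name) for name in ACSN_CANONICAL_MAP_NAMES]
    models += [
        build_fixture("acsn_raf1_stateless"),
        build_fixture("acsn_cell_survival_sef"),
        build_fixture("acsn_emt_raf1_detailed"),
    ]
    return models


def build_panther_collection() -> list[MapModel]:
    return [
        build_fixture("panther_interleukin"),
        build_fixture("panther_fgf"),
        build_fixture("panther_bcell_complexes"),
    ]


# -- random maps ---------------------------------------------------------------


@dataclass(frozen=True)
class RandomMapSpec:
    """Parameters of a seeded random PD map.

    ``p_phospho`` is the fraction of processes that are catalyzed
    phosphorylations; ``p_in_complex`` the fraction of those whose target is
    placed inside a complex.
    """

    seed: int
    n_proteins: int = 8
    n_generic: int = 2
    max_states_per_protein: int = 3
    n_complexes: int = 2
    n_processes: int = 12
    p_phospho: float = 0.5
    p_in_complex: float = 0.25

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_generic", "max_states_per_protein", "n_complexes", "n_processes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_phospho", "p_in_complex"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_generic > self.n_proteins:
            raise ValueError("n_generic cannot exceed n_proteins")
        if self.n_proteins < 2 and self.n_processes > 0:
            raise ValueError("need at least 2 proteins to build processes")
        if self.p_in_complex > 0 and self.n_complexes == 0:
            raise ValueError(
                "infeasible spec: p_in_complex > 0 requires n_complexes > 0"
            )


@dataclass(frozen=True)
class _RandomProtein:
    key: str
    label: str
    sites: tuple[str, ...]
    is_generic: bool
    members: frozenset[str]


def generate_random_map(spec: RandomMapSpec) -> tuple[MapModel, list[PhosphoEvent]]:
    """Generate a seeded random PD map plus its planted ground truth.

    The returned event list records exactly the catalyzed phosphorylation
    quadruplets built into the map (free and in-complex), so it is the
    oracle against which census extraction is checked.  Distractor processes
    (associations, dephosphorylations, uncatalyzed gains) are planted too
    and must produce no events.
    """
    rng = random.Random(spec.seed)
    model = MapModel(
        map_name=f"random-{spec.seed}", provenance=f"random:seed={spec.seed}"
    )
    ground_truth: list[PhosphoEvent] = []

    # protein universe: specific proteins first, then generics over them
    n_specific = spec.n_proteins - spec.n_generic
    specifics: list[_RandomProtein] = []
    pos_counter = 0
    for i in range(n_specific):
        n_sites = rng.randint(1, max(1, spec.max_states_per_protein))
        sites = []
        for _ in range(n_sites):
            pos_counter += 1
            if rng.random() < 0.15:
                sites.append(f"flag{pos_counter}")
            else:
                sites.append(f"{rng.choice('STY')}{100 + pos_counter}")
        key = f"PROT{i:03d}"
        specifics.append(
            _RandomProtein(key, key, tuple(sorted(sites)), False, frozenset())
        )
    generics: list[_RandomProtein] = []
    for i in range(spec.n_generic):
        n_sites = rng.randint(0, max(0, spec.max_states_per_protein - 1))
        sites = []
        for _ in range(n_sites):
            pos_counter += 1
            sites.append(f"{rng.choice('STY')}{100 + pos_counter}")
        members = frozenset(
            p.key for p in rng.sample(specifics, k=min(len(specifics), rng.randint(1, 3)))
        ) if specifics else frozenset()
        key = f"GEN{i:03d}"
        generics.append(_RandomProtein(key, key, tuple(sorted(sites)), True, members))
    proteins = specifics + generics

    counters = {"pool": 0, "cx": 0, "proc": 0}
    pool_cache: dict[tuple, str] = {}

    def make_pool(prot: _RandomProtein, values: dict[str, str]) -> str:
        state = tuple(sorted((s, values.get(s, UNSET)) for s in prot.sites))
        cache_key = (prot.key, state)
        if cache_key in pool_cache:
            return pool_cache[cache_key]
        counters["pool"] += 1
        pid = f"pool{counters['pool']:03d}"
        model.add_protein(
            ProteinPool(
                pool_id=pid,
                label=prot.label,
                protein_key=prot.key,
                is_generic=prot.is_generic,
                members=prot.members,
                state=frozenset(StateVariable(s, v) for s, v in state),
                compartment=_COMP,
            )
        )
        pool_cache[cache_key] = pid
        return pid

    def make_complex(component_ids: tuple[str, ...]) -> str:
        counters["cx"] += 1
        cid = f"cx{counters['cx']:03d}"
        model.add_complex(
            ComplexPool(pool_id=cid, components=component_ids, compartment=_COMP)
        )
        return cid

    def next_proc() -> str:
        counters["proc"] += 1
        return f"proc{counters['proc']:03d}"

    def random_values(prot: _RandomProtein, exclude: tuple[str, ...] = ()) -> dict[str, str]:
        return {
            s: (PHOSPHORYLATED if rng.random() < 0.3 else UNSET)
            for s in prot.sites
            if s not in exclude
        }

    # distractor complexes
    for _ in range(spec.n_complexes):
        if not proteins:
            break
        comps = tuple(
            make_pool(p, random_values(p))
            for p in [rng.choice(proteins) for _ in range(rng.randint(1, 3))]
        )
        make_complex(comps)

    from pdlint.model import is_residue_site

    for _ in range(spec.n_processes):
        if rng.random() < spec.p_phospho:
            target = rng.choice([p for p in proteins if p.sites])
            kinase = rng.choice([p for p in proteins if p.key != target.key])
            gained = tuple(
                sorted(rng.sample(target.sites, k=rng.randint(1, min(2, len(target.sites)))))
            )
            base = random_values(target, exclude=gained)
            r_vals = dict(base, **{s: UNSET for s in gained})
            p_vals = dict(base, **{s: PHOSPHORYLATED for s in gained})
            r_id = make_pool(target, r_vals)
            p_id = make_pool(target, p_vals)
            k_id = make_pool(kinase, random_values(kinase))
            proc_id = next_proc()
            in_complex = rng.random() < spec.p_in_complex
            if in_complex:
                partners = [
                    p for p in proteins if p.key not in (target.key, kinase.key)
                ]
                chosen = rng.sample(partners, k=min(len(partners), rng.randint(1, 2)))
                partner_ids = tuple(make_pool(p, random_values(p)) for p in chosen)
                rc = make_complex((r_id,) + partner_ids)
                pc = make_complex((p_id,) + partner_ids)
                model.add_process(
                    Process(
                        process_id=proc_id,
                        kind=STATE_TRANSITION,
                        reactants=(rc,),
                        products=(pc,),
                        modulators=((k_id, CATALYSIS),),
                    )
                )
                mode = IN_COMPLEX
            else:
                model.add_process(
                    Process(
                        process_id=proc_id,
                        kind=STATE_TRANSITION,
                        reactants=(r_id,),
                        products=(p_id,),
                        modulators=((k_id, CATALYSIS),),
                    )
                )
                mode = FREE
            site_tokens: list[str] = []
            for s in gained:
                token = s if is_residue_site(s) else ""
                if token not in site_tokens:
                    site_tokens.append(token)
            for token in site_tokens:
                ground_truth.append(
                    PhosphoEvent(
                        kinase=kinase.key,
                        target=target.key,
                        site=token,
                        map_name=model.map_name,
                        mode=mode,
                        process_id=proc_id,
                        kinase_pool=k_id,
                        target_pool=p_id,
                    )
                )
        else:
            choice = rng.random()
            if choice < 0.4 and len(proteins) >= 2:
                # association distractor
                a, b = rng.sample(proteins, k=2)
                a_id = make_pool(a, random_values(a))
                b_id = make_pool(b, random_values(b))
                cid = make_complex((a_id, b_id))
                model.add_process(
                    Process(
                        process_id=next_proc(),
                        kind=ASSOCIATION,
                        reactants=(a_id, b_id),
                        products=(cid,),
                    )
                )
            elif choice < 0.7:
                # catalyzed dephosphorylation distractor (site lost, no event)
                target = rng.choice([p for p in proteins if p.sites])
                enzyme = rng.choice([p for p in proteins if p.key != target.key])
                site = rng.choice(target.sites)
                base = random_values(target, exclude=(site,))
                r_id = make_pool(target, dict(base, **{site: PHOSPHORYLATED}))
                p_id = make_pool(target, dict(base, **{site: UNSET}))
                e_id = make_pool(enzyme, random_values(enzyme))
                model.add_process(
                    Process(
                        process_id=next_proc(),
                        kind=STATE_TRANSITION,
                        reactants=(r_id,),
                        products=(p_id,),
                        modulators=((e_id, CATALYSIS),),
                    )
                )
            else:
                # uncatalyzed phospho gain distractor (no catalysis arc)
                target = rng.choice([p for p in proteins if p.sites])
                site = rng.choice(target.sites)
                base = random_values(target, exclude=(site,))
                r_id = make_pool(target, dict(base, **{site: UNSET}))
                p_id = make_pool(target, dict(base, **{site: PHOSPHORYLATED}))
                model.add_process(
                    Process(
                        process_id=next_proc(),
                        kind=STATE_TRANSITION,
                        reactants=(r_id,),
                        products=(p_id,),
                    )
                )
    return model.validate(), ground_truth
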