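"""Typed in-memory model of SBGN-style process description (PD) maps.

A PD map is a bipartite graph: stateful *entity pools* (proteins, possibly
lumped "generic" groups, and complexes of proteins) connected through
*processes* (state transitions, associations, dissociations), which in turn
may carry *modulation* arcs such as catalysis.  Pools carry *state
variables* — residue phosphosites like ``S218`` or named flags like
``activity`` — whose values distinguish e.g. phosphorylated from
unphosphorylated forms of the same protein.

This module replaces an external property-graph store with a plain typed
graph: every map is a :class:`MapModel` holding dictionaries of frozen pool
and process records, validated for referential integrity.  All downstream
stages (census, lints, harmonization) operate on these objects only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "StateVariable",
    "ProteinPool",
    "ComplexPool",
    "Process",
    "MapModel",
    "MapValidationError",
    "normalize_protein_identity",
    "state_signature",
    "complex_composition_signature",
    "complex_label",
    "is_residue_site",
    "DEFAULT_PROTEIN_ALIASES",
    "PREFERRED_LABELS",
    "PHOSPHORYLATED",
    "UNSET",
    "CATALYSIS",
    "STIMULATION",
    "UNKNOWN_MODULATION",
    "STATE_TRANSITION",
    "ASSOCIATION",
    "DISSOCIATION",
    "GENERIC_PROCESS",
]

# State-variable values.  UNSET means the variable is shown but carries no
# value (an unmodified site); PHOSPHORYLATED is the "P" token of SBGN-PD.
PHOSPHORYLATED = "P"
UNSET = ""

# Modulation classes.
CATALYSIS = "catalysis"
STIMULATION = "stimulation"
UNKNOWN_MODULATION = "unknown"
MODULATION_CLASSES = frozenset({CATALYSIS, STIMULATION, UNKNOWN_MODULATION})

# Process kinds.
STATE_TRANSITION = "state_transition"
ASSOCIATION = "association"
DISSOCIATION = "dissociation"
GENERIC_PROCESS = "generic_process"
PROCESS_KINDS = frozenset(
    {STATE_TRANSITION, ASSOCIATION, DISSOCIATION, GENERIC_PROCESS}
)

# Residue token: one amino-acid letter followed by a 1-based position in
# UniProt canonical numbering, e.g. "S218".  Anything else is a named flag.
RESIDUE_TOKEN_RE = re.compile(r"^([A-Z])([0-9]+)$")


class MapValidationError(ValueError):
    """A map (or one of its records) violates a structural invariant."""


def is_residue_site(site: str) -> bool:
    """True if *site* is a residue token (letter + 1-based position)."""
    m = RESIDUE_TOKEN_RE.match(site)
    return bool(m) and int(m.group(2)) >= 1


@dataclass(frozen=True)
class StateVariable:
    """One site/value annotation on an entity pool.

    ``site`` is either a residue token (``S218``) or a named flag
    (``activity``); ``value`` is ``""`` (unset), ``"P"`` (phosphorylated) or
    any other string (e.g. ``"active"``).
    """

    site: str
    value: str = UNSET

    def __post_init__(self) -> None:
        if not self.site:
            raise MapValidationError("state variable site token must be non-empty")
        m = RESIDUE_TOKEN_RE.match(self.site)
        if m and int(m.group(2)) < 1:
            raise MapValidationError(
                f"residue position must be >= 1, got {self.site!r}"
            )

    @property
    def is_residue(self) -> bool:
        return is_residue_site(self.site)

    @property
    def is_phosphorylated(self) -> bool:
        return self.value == PHOSPHORYLATED


def _freeze_state(state: Iterable[StateVariable]) -> frozenset[StateVariable]:
    fs = frozenset(state)
    sites = [sv.site for sv in fs]
    if len(sites) != len(set(sites)):
        dup = sorted({s for s in sites if sites.count(s) > 1})
        raise MapValidationError(f"duplicate state-variable site(s): {dup}")
    return fs


@dataclass(frozen=True)
class ProteinPool:
    """A stateful protein entity pool (specific or generic).

    A *generic* pool stands for a group of proteins (``is_generic=True``);
    its ``members`` are the protein keys of the lumped specific proteins and
    should be annotated, though unmembered generics are legal (they are
    flagged by the UNANNOTATED_GENERIC lint, not rejected here).
    """

    pool_id: str
    label: str
    protein_key: str
    uniprot_ids: frozenset[str] = frozenset()
    is_generic: bool = False
    members: frozenset[str] = frozenset()
    state: frozenset[StateVariable] = frozenset()
    compartment: str = "default"

    def __post_init__(self) -> None:
        object.__setattr__(self, "uniprot_ids", frozenset(self.uniprot_ids))
        object.__setattr__(self, "members", frozenset(self.members))
        object.__setattr__(self, "state", _freeze_state(self.state))
        if not self.pool_id:
            raise MapValidationError("pool_id must be non-empty")
        if not self.protein_key:
            raise MapValidationError(f"pool {self.pool_id}: empty protein_key")
        if not self.is_generic and self.members:
            raise MapValidationError(
                f"pool {self.pool_id}: specific pool must not list members"
            )

    def value_of(self, site: str) -> Optional[str]:
        """Value of *site* on this pool, or None if the variable is absent."""
        for sv in self.state:
            if sv.site == site:
                return sv.value
        return None

    def phospho_sites(self) -> frozenset[str]:
        """Residue sites currently carrying the phosphorylated value."""
        return frozenset(
            sv.site for sv in self.state if sv.is_residue and sv.is_phosphorylated
        )


@dataclass(frozen=True)
class ComplexPool:
    """A complex entity pool: a multiset of protein-pool components."""

    pool_id: str
    components: tuple[str, ...]  # pool_ids of ProteinPools in the same map
    compartment: str = "default"

    def __post_init__(self) -> None:
        # components form a multiset; canonicalize order so equal complexes
        # compare equal regardless of construction order
        object.__setattr__(self, "components", tuple(sorted(self.components)))
        if not self.pool_id:
            raise MapValidationError("pool_id must be non-empty")
        if len(self.components) < 1:
            raise MapValidationError(
                f"complex {self.pool_id}: needs at least one component"
            )


@dataclass(frozen=True)
class Process:
    """A process node with role-tagged participants and modulators."""

    process_id: str
    kind: str
    reactants: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    modulators: tuple[tuple[str, str], ...] = ()  # (pool_id, modulation class)

    def __post_init__(self) -> None:
        # participant lists are multisets; canonicalize order
        object.__setattr__(self, "reactants", tuple(sorted(self.reactants)))
        object.__setattr__(self, "products", tuple(sorted(self.products)))
        object.__setattr__(
            self, "modulators", tuple(sorted(tuple(m) for m in self.modulators))
        )
        if not self.process_id:
            raise MapValidationError("process_id must be non-empty")
        if self.kind not in PROCESS_KINDS:
            raise MapValidationError(
                f"process {self.process_id}: unknown kind {self.kind!r}"
            )
        if self.kind == STATE_TRANSITION and (
            not self.reactants or not self.products
        ):
            raise MapValidationError(
                f"process {self.process_id}: state transitions need reactants "
                "and products"
            )
        for _, cls in self.modulators:
            if cls not in MODULATION_CLASSES:
                raise MapValidationError(
                    f"process {self.process_id}: unknown modulation class {cls!r}"
                )

    def participant_ids(self) -> tuple[str, ...]:
        return (
            self.reactants
            + self.products
            + tuple(pid for pid, _ in self.modulators)
        )


@dataclass
class MapModel:
    """One PD map: pools, complexes, processes, compartments, name.

    ``map_name`` is the fourth field of the phosphorylation quadruplet, so it
    must be non-empty.  ``provenance`` is a free-form source tag (fixture
    preset id or file path) and is ignored by equality comparisons.
    """

    map_name: str
    pools: dict[str, ProteinPool] = field(default_factory=dict)
    complexes: dict[str, ComplexPool] = field(default_factory=dict)
    processes: dict[str, Process] = field(default_factory=dict)
    compartments: set[str] = field(default_factory=set)
    provenance: str = field(default="", compare=False)

    # -- construction helpers -------------------------------------------------

    def add_protein(self, pool: ProteinPool) -> ProteinPool:
        self._claim_id(pool.pool_id)
        self.pools[pool.pool_id] = pool
        self.compartments.add(pool.compartment)
        return pool

    def add_complex(self, cx: ComplexPool) -> ComplexPool:
        self._claim_id(cx.pool_id)
        self.complexes[cx.pool_id] = cx
        self.compartments.add(cx.compartment)
        return cx

    def add_process(self, proc: Process) -> Process:
        if proc.process_id in self.processes or proc.process_id in self._entity_ids():
            raise MapValidationError(f"duplicate id {proc.process_id!r}")
        self.processes[proc.process_id] = proc
        return proc

    def _claim_id(self, pool_id: str) -> None:
        if pool_id in self._entity_ids() or pool_id in self.processes:
            raise MapValidationError(f"duplicate id {pool_id!r}")

    def _entity_ids(self) -> set[str]:
        return set(self.pools) | set(self.complexes)

    # -- access ---------------------------------------------------------------

    def entity(self, pool_id: str) -> Union[ProteinPool, ComplexPool]:
        if pool_id in self.pools:
            return self.pools[pool_id]
        if pool_id in self.complexes:
            return self.complexes[pool_id]
        raise KeyError(pool_id)

    def protein_pools(self) -> list[ProteinPool]:
        return [self.pools[k] for k in sorted(self.pools)]

    def complex_pools(self) -> list[ComplexPool]:
        return [self.complexes[k] for k in sorted(self.complexes)]

    def components_of(self, cx: ComplexPool) -> tuple[ProteinPool, ...]:
        return tuple(self.pools[cid] for cid in cx.components)

    def copy(self) -> "MapModel":
        return MapModel(
            map_name=self.map_name,
            pools=dict(self.pools),
            complexes=dict(self.complexes),
            processes=dict(self.processes),
            compartments=set(self.compartments),
            provenance=self.provenance,
        )

    # -- validation -----------------------------------------------------------

    def validate(self) -> "MapModel":
        """Assert referential integrity; returns self so calls can chain."""
        if not self.map_name:
            raise MapValidationError("map_name must be non-empty")
        entity_ids = self._entity_ids()
        if len(entity_ids) != len(self.pools) + len(self.complexes):
            raise MapValidationError("pool and complex ids overlap")
        clash = entity_ids & set(self.processes)
        if clash:
            raise MapValidationError(f"process ids clash with pool ids: {sorted(clash)}")
        for pid, pool in self.pools.items():
            if pid != pool.pool_id:
                raise MapValidationError(f"pool key {pid!r} != pool_id {pool.pool_id!r}")
            if pool.compartment not in self.compartments:
                raise MapValidationError(
                    f"pool {pid}: unknown compartment {pool.compartment!r}"
                )
        for cid, cx in self.complexes.items():
            if cid != cx.pool_id:
                raise MapValidationError(f"complex key {cid!r} != pool_id")
            for comp in cx.components:
                if comp not in self.pools:
                    raise MapValidationError(
                        f"complex {cid}: component {comp!r} is not a protein pool "
                        "of this map"
                    )
        for xid, proc in self.processes.items():
            if xid != proc.process_id:
                raise MapValidationError(f"process key {xid!r} != process_id")
            for ref in proc.participant_ids():
                if ref not in entity_ids:
                    raise MapValidationError(
                        f"process {xid}: dangling reference {ref!r}"
                    )
        return self


# -- identity ------------------------------------------------------------------

#: Synonym table mapping upper-cased display labels to canonical protein keys
#: (UniProt primary accessions for the proteins of the RAS-RAF-MEK-ERK
#: cascade and its neighbours).  User tables can extend or replace this.
DEFAULT_PROTEIN_ALIASES: Mapping[str, str] = {
    "MEK1": "Q02750",
    "MAP2K1": "Q02750",
    "MEK2": "P36507",
    "MAP2K2": "P36507",
    "ERK1": "P27361",
    "MAPK3": "P27361",
    "ERK2": "P28482",
    "MAPK1": "P28482",
    "RAF1": "P04049",
    "CRAF": "P04049",
    "BRAF": "P15056",
    "ARAF": "P10398",
    "KRAS": "P01116",
    "HRAS": "P01112",
    "NRAS": "P01111",
    "SEF": "Q8NFM7",
    "IL17RD": "Q8NFM7",
    "KSR1": "Q8IVT5",
    "L1CAM": "P32004",
}

#: Preferred display labels for canonical keys (inverse of the alias table).
PREFERRED_LABELS: Mapping[str, str] = {
    "Q02750": "MEK1",
    "P36507": "MEK2",
    "P27361": "ERK1",
    "P28482": "ERK2",
    "P04049": "RAF1",
    "P15056": "BRAF",
    "P10398": "ARAF",
    "P01116": "KRAS",
    "P01112": "HRAS",
    "P01111": "NRAS",
    "Q8NFM7": "SEF",
    "Q8IVT5": "KSR1",
    "P32004": "L1CAM",
}


def normalize_protein_identity(
    label: str,
    uniprot_ids: Iterable[str] = (),
    alias_table: Optional[Mapping[str, str]] = None,
) -> str:
    """Resolve a pool label to a canonical protein key.

    Precedence: UniProt accession (lowest sorted, for determinism when a pool
    carries several) > alias-table hit on the normalized label > the
    upper-cased, trimmed label itself.  Total and idempotent.
    """
    table = DEFAULT_PROTEIN_ALIASES if alias_table is None else alias_table
    accessions = sorted(str(a).strip().upper() for a in uniprot_ids if str(a).strip())
    if accessions:
        return accessions[0]
    norm = label.strip().upper()
    return table.get(norm, norm)


def preferred_label(protein_key: str) -> str:
    """Human-readable label for a protein key (falls back to the key)."""
    return PREFERRED_LABELS.get(protein_key, protein_key)


# -- signatures ----------------------------------------------------------------

Signature = tuple[str, ...]


def state_signature(pool: ProteinPool) -> Signature:
    """Ordered, duplicate-free list of site tokens present on *pool*.

    The signature records which variables are *shown* on the pool, not their
    values: a pool with ``S218`` unset and one with ``S218:P`` share a
    signature, while a stateless pool has the empty signature.
    """
    return tuple(sorted({sv.site for sv in pool.state}))


def complex_composition_signature(
    model: MapModel, cx: ComplexPool
) -> tuple[tuple[str, Signature], ...]:
    """Order-independent multiset of (protein_key, signature) for a complex."""
    pairs = [
        (pool.protein_key, state_signature(pool))
        for pool in model.components_of(cx)
    ]
    return tuple(sorted(pairs))


def complex_label(model: MapModel, cx: ComplexPool) -> str:
    """Deterministic display label for a complex, e.g. ``[MEK@S218,S222|MEK@S218,S222]``."""
    parts = []
    for key, sig in complex_composition_signature(model, cx):
        parts.append(key + ("@" + ",".join(sig) if sig else ""))
    return "[" + "|".join(parts) + "]"
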