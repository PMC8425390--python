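"""Harmonization remedies: state-variable propagation, generic→specific
replacement, and lint-guarded map merging.

Merging two PD maps is only sound when the state variables of every shared
protein are handled identically and when generic/specific representations
do not collide; these are exactly the blocking findings of the state
signature and generic/specific lints.  ``merge_maps`` refuses to merge
while blocking findings exist unless auto-harmonization is requested, in
which case every conflicting protein is propagated to the union of its
state-variable universes (and generics optionally replaced by their
members) before pools, complexes and processes are unioned by identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from pdlint.lints import (
    RULE_GENERIC_SPECIFIC,
    RULE_STATE_SIGNATURE,
    SEVERITY_ERROR,
    LintFinding,
    lint_generic_specific,
    lint_state_signature,
)
from pdlint.model import (
    UNSET,
    ComplexPool,
    MapModel,
    MapValidationError,
    Process,
    ProteinPool,
    StateVariable,
    preferred_label,
    state_signature,
)

__all__ = [
    "HarmonizeError",
    "propagate_state_variables",
    "replace_generic_with_specific",
    "Transformation",
    "MergeOptions",
    "MergeReport",
    "merge_maps",
]


class HarmonizeError(ValueError):
    """A harmonization step would lose information or is not applicable."""


def propagate_state_variables(
    model: MapModel, protein_key: str, variable_universe: Iterable[str]
) -> MapModel:
    """Give every pool of *protein_key* exactly *variable_universe* as sites.

    Existing values are preserved; newly added variables are unset.  The
    universe must cover every site already present (dropping a variable
    would lose information).  Idempotent and monotone; processes untouched.
    """
    universe = frozenset(variable_universe)
    out = model.copy()
    for pool_id, pool in list(out.pools.items()):
        if pool.protein_key != protein_key:
            continue
        existing = {sv.site for sv in pool.state}
        missing = existing - universe
        if missing:
            raise HarmonizeError(
                f"pool {pool_id}: universe is missing existing site(s) "
                f"{sorted(missing)}; propagation would lose information"
            )
        values = {sv.site: sv.value for sv in pool.state}
        new_state = frozenset(
            StateVariable(site, values.get(site, UNSET)) for site in universe
        )
        out.pools[pool_id] = replace(pool, state=new_state)
    return out.validate()


@dataclass(frozen=True)
class Transformation:
    """Log entry for one applied harmonization step."""

    op: str
    details: dict = field(hash=False)

    def __str__(self) -> str:
        return f"{self.op}: " + ", ".join(
            f"{k}={v}" for k, v in sorted(self.details.items())
        )


def _member_pool(pool: ProteinPool, member: str, suffix: str) -> ProteinPool:
    return ProteinPool(
        pool_id=f"{pool.pool_id}__{suffix}",
        label=preferred_label(member),
        protein_key=member,
        uniprot_ids=frozenset(),
        is_generic=False,
        members=frozenset(),
        state=pool.state,
        compartment=pool.compartment,
    )


def replace_generic_with_specific(
    model: MapModel,
    generic: Union[str, ProteinPool],
    policy: str = "duplicate_processes",
) -> tuple[MapModel, Transformation]:
    """Replace a generic entity (all pools sharing its protein key) by its
    specific members.

    ``duplicate_processes``: one specific pool per member per generic pool;
    every process and complex touching the generic is cloned per member
    (states copied, all occurrences substituted consistently).
    ``keep_single_member``: only legal for a single-member generic; the
    pools are relabelled in place.
    """
    if isinstance(generic, str):
        generic = model.pools[generic]
    key = generic.protein_key
    targets = {
        pid: pool
        for pid, pool in model.pools.items()
        if pool.protein_key == key and pool.is_generic
    }
    if not targets:
        raise HarmonizeError(f"no generic pools with key {key!r} in map")
    members = sorted(next(iter(targets.values())).members)
    if not members:
        raise HarmonizeError(f"generic {key!r} has no annotated members")
    if policy == "keep_single_member":
        if len(members) != 1:
            raise HarmonizeError(
                "keep_single_member requires exactly one member, got "
                f"{len(members)}"
            )
    elif policy != "duplicate_processes":
        raise HarmonizeError(f"unknown policy {policy!r}")

    suffix_of = {m: preferred_label(m) for m in members}
    out = MapModel(map_name=model.map_name, provenance=model.provenance)
    out.compartments.update(model.compartments)

    # pools
    sub: dict[str, dict[str, str]] = {m: {} for m in members}  # member -> old id -> new id
    for pid, pool in sorted(model.pools.items()):
        if pid in targets:
            for m in members:
                new = _member_pool(pool, m, suffix_of[m])
                out.add_protein(new)
                sub[m][pid] = new.pool_id
        else:
            out.add_protein(pool)
    # complexes: clone per member when touching the generic
    touched_cx: set[str] = set()
    for cid, cx in sorted(model.complexes.items()):
        if any(c in targets for c in cx.components):
            touched_cx.add(cid)
            for m in members:
                out.add_complex(
                    ComplexPool(
                        pool_id=f"{cid}__{suffix_of[m]}",
                        components=tuple(sub[m].get(c, c) for c in cx.components),
                        compartment=cx.compartment,
                    )
                )
                sub[m][cid] = f"{cid}__{suffix_of[m]}"
        else:
            out.add_complex(cx)
    # processes
    fanout = 0
    for xid, proc in sorted(model.processes.items()):
        ids = set(proc.participant_ids())
        if ids & (set(targets) | touched_cx):
            fanout += 1
            for m in members:
                mp = sub[m]
                out.add_process(
                    Process(
                        process_id=f"{xid}__{suffix_of[m]}",
                        kind=proc.kind,
                        reactants=tuple(mp.get(r, r) for r in proc.reactants),
                        products=tuple(mp.get(p, p) for p in proc.products),
                        modulators=tuple(
                            (mp.get(pid, pid), cls) for pid, cls in proc.modulators
                        ),
                    )
                )
        else:
            out.add_process(proc)
    out.validate()
    return out, Transformation(
        op="replace_generic_with_specific",
        details={
            "protein_key": key,
            "members": members,
            "policy": policy,
            "processes_fanned_out": fanout,
            "fanout_factor": len(members),
        },
    )


# -- merging -------------------------------------------------------------------


@dataclass(frozen=True)
class MergeOptions:
    auto_harmonize: bool = False
    replace_generics: bool = False
    merged_name: Optional[str] = None


@dataclass
class MergeReport:
    ok: bool
    merged: Optional[MapModel]
    blocking: list[LintFinding]
    transformations: list[Transformation]
    findings: list[LintFinding]


def _pool_identity(pool: ProteinPool) -> tuple:
    return (
        "pool",
        pool.protein_key,
        tuple(sorted((sv.site, sv.value) for sv in pool.state)),
        pool.compartment,
        pool.is_generic,
        tuple(sorted(pool.members)),
    )


def _blocking(findings: Sequence[LintFinding]) -> list[LintFinding]:
    return [
        f
        for f in findings
        if f.rule_id in (RULE_STATE_SIGNATURE, RULE_GENERIC_SPECIFIC)
    ]


def merge_maps(
    models: Sequence[MapModel], options: MergeOptions = MergeOptions()
) -> MergeReport:
    """Merge maps by identity, guarded by the merge-blocking lints.

    Without ``auto_harmonize`` the merge fails (with the findings) whenever
    state-variable or generic/specific conflicts exist.  With it, conflicting
    proteins are propagated to their union universes first (and generics
    replaced by members when ``replace_generics`` is set); pools then merge
    on (protein key, state, compartment), complexes on composition, and
    processes on (kind, participant identities, modulators).  The merged map
    must validate and be free of within-map errors; failures never yield a
    silent partial merge.
    """
    if len(models) < 2:
        raise ValueError("merge needs at least two maps")
    models = [m.copy() for m in models]
    transformations: list[Transformation] = []

    findings = lint_state_signature(models) + lint_generic_specific(models)
    blocking = _blocking(findings)
    if blocking and not options.auto_harmonize:
        return MergeReport(
            ok=False,
            merged=None,
            blocking=blocking,
            transformations=transformations,
            findings=findings,
        )

    if options.auto_harmonize and blocking:
        # 1. propagate union universes for every state-signature conflict
        state_keys = sorted(
            {f.protein_key for f in blocking if f.rule_id == RULE_STATE_SIGNATURE}
        )
        for key in state_keys:
            universe: set[str] = set()
            for m in models:
                for pool in m.protein_pools():
                    if pool.protein_key == key:
                        universe.update(sv.site for sv in pool.state)
            models = [propagate_state_variables(m, key, universe) for m in models]
            transformations.append(
                Transformation(
                    op="propagate_state_variables",
                    details={"protein_key": key, "universe": sorted(universe)},
                )
            )
        # 2. optionally replace conflicting generics by their members
        if options.replace_generics:
            conflict_members = {
                f.protein_key
                for f in blocking
                if f.rule_id == RULE_GENERIC_SPECIFIC
            }
            for i, m in enumerate(models):
                generic_keys = sorted(
                    {
                        pool.protein_key
                        for pool in m.protein_pools()
                        if pool.is_generic and pool.members & conflict_members
                    }
                )
                for gkey in generic_keys:
                    gpool = next(
                        p for p in m.protein_pools() if p.protein_key == gkey
                    )
                    m, tr = replace_generic_with_specific(m, gpool)
                    transformations.append(tr)
                models[i] = m
            # replacement may reintroduce signature conflicts between copied
            # generic states and pre-existing specific pools
            for key in sorted(
                {
                    f.protein_key
                    for f in _blocking(lint_state_signature(models))
                }
            ):
                universe = {
                    sv.site
                    for m in models
                    for pool in m.protein_pools()
                    if pool.protein_key == key
                    for sv in pool.state
                }
                models = [
                    propagate_state_variables(m, key, universe) for m in models
                ]
                transformations.append(
                    Transformation(
                        op="propagate_state_variables",
                        details={"protein_key": key, "universe": sorted(universe)},
                    )
                )

    merged = MapModel(
        map_name=options.merged_name or " + ".join(m.map_name for m in models),
        provenance="merge:" + ";".join(m.provenance or m.map_name for m in models),
    )
    pool_ids: dict[tuple, str] = {}
    cx_ids: dict[tuple, str] = {}
    proc_ids: dict[tuple, str] = {}

    def pool_key_for(model: MapModel, entity_id: str) -> tuple:
        entity = model.entity(entity_id)
        if isinstance(entity, ProteinPool):
            return _pool_identity(entity)
        return _cx_identity(model, entity)

    def _cx_identity(model: MapModel, cx: ComplexPool) -> tuple:
        return (
            "complex",
            tuple(
                sorted(
                    _pool_identity(model.pools[c]) for c in cx.components
                )
            ),
            cx.compartment,
        )

    for m in models:
        merged.compartments.update(m.compartments)
        for pool in m.protein_pools():
            ident = _pool_identity(pool)
            if ident not in pool_ids:
                new_id = f"mp{len(pool_ids) + 1:04d}"
                pool_ids[ident] = new_id
                merged.add_protein(replace(pool, pool_id=new_id))
    for m in models:
        for cx in m.complex_pools():
            ident = _cx_identity(m, cx)
            if ident not in cx_ids:
                new_id = f"mc{len(cx_ids) + 1:04d}"
                cx_ids[ident] = new_id
                merged.add_complex(
                    ComplexPool(
                        pool_id=new_id,
                        components=tuple(
                            pool_ids[_pool_identity(m.pools[c])]
                            for c in cx.components
                        ),
                        compartment=cx.compartment,
                    )
                )
    for m in models:
        for proc in (m.processes[k] for k in sorted(m.processes)):

            def translate(entity_id: str) -> str:
                ident = pool_key_for(m, entity_id)
                return pool_ids[ident] if ident[0] == "pool" else cx_ids[ident]

            ident = (
                proc.kind,
                tuple(sorted(translate(r) for r in proc.reactants)),
                tuple(sorted(translate(p) for p in proc.products)),
                tuple(sorted((translate(pid), cls) for pid, cls in proc.modulators)),
            )
            if ident not in proc_ids:
                new_id = f"mx{len(proc_ids) + 1:04d}"
                proc_ids[ident] = new_id
                merged.add_process(
                    Process(
                        process_id=new_id,
                        kind=proc.kind,
                        reactants=tuple(translate(r) for r in proc.reactants),
                        products=tuple(translate(p) for p in proc.products),
                        modulators=tuple(
                            (translate(pid), cls) for pid, cls in proc.modulators
                        ),
                    )
                )

    try:
        merged.validate()
    except MapValidationError as exc:  # pragma: no cover - defensive
        return MergeReport(
            ok=False,
            merged=None,
            blocking=blocking,
            transformations=transformations,
            findings=findings + [
                LintFinding(
                    rule_id=RULE_STATE_SIGNATURE,
                    severity=SEVERITY_ERROR,
                    protein_key=None,
                    pools=("merged:*",),
                    maps=(merged.map_name,),
                    message=f"merged model failed validation: {exc}",
                )
            ],
        )
    post = [
        f
        for f in lint_state_signature([merged])
        if f.severity == SEVERITY_ERROR
    ]
    if post:
        return MergeReport(
            ok=False,
            merged=None,
            blocking=post,
            transformations=transformations,
            findings=findings + post,
        )
    return MergeReport(
        ok=True,
        merged=merged,
        blocking=[],
        transformations=transformations,
        findings=findings,
    )
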