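"""Composability lints: the four barriers as machine-checkable rules.

Rules over one map or a map collection:

* ``STATE_SIGNATURE`` — "once a variable, always a variable": within one
  map, every entity pool of a protein must show the same set of state
  variables (violations are errors — they block merging); across maps,
  differing per-map variable universes are warnings.
* ``GENERIC_SPECIFIC`` — the same protein appears both lumped inside a
  generic pool and as a specific pool; ``UNANNOTATED_GENERIC`` flags
  generic pools whose membership is not annotated at all.
* ``CANONICAL_SITES`` — a pool's phosphorylated sites neither match the
  configured canonical activating set for that protein nor are empty.
* ``COMPLEX_VARIANT`` — a protein set drawn as a complex in one map is
  drawn as free-pool interactions (or a differently composed complex) in
  another.

Severities follow the merge semantics: within-map signature clashes are
errors, cross-map divergences are warnings, missing annotations are info.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence

from pdlint.model import (
    ComplexPool,
    MapModel,
    ProteinPool,
    Signature,
    StateVariable,
    complex_composition_signature,
    state_signature,
)

__all__ = [
    "LintFinding",
    "RULE_STATE_SIGNATURE",
    "RULE_GENERIC_SPECIFIC",
    "RULE_CANONICAL_SITES",
    "RULE_COMPLEX_VARIANT",
    "RULE_UNANNOTATED_GENERIC",
    "ALL_RULES",
    "DEFAULT_CANONICAL_SITES",
    "lint_state_signature",
    "lint_generic_specific",
    "lint_canonical_sites",
    "lint_complex_variants",
    "run_all_lints",
    "expand_generic_complex",
    "ConcreteComplex",
]

RULE_STATE_SIGNATURE = "STATE_SIGNATURE"
RULE_GENERIC_SPECIFIC = "GENERIC_SPECIFIC"
RULE_CANONICAL_SITES = "CANONICAL_SITES"
RULE_COMPLEX_VARIANT = "COMPLEX_VARIANT"
RULE_UNANNOTATED_GENERIC = "UNANNOTATED_GENERIC"
ALL_RULES = (
    RULE_STATE_SIGNATURE,
    RULE_GENERIC_SPECIFIC,
    RULE_CANONICAL_SITES,
    RULE_COMPLEX_VARIANT,
    RULE_UNANNOTATED_GENERIC,
)

SEVERITY_ERROR = "error"
SEVERITY_WARNING = "warning"
SEVERITY_INFO = "info"

#: Canonical activating phosphosites per protein key.  MEK1/ERK1/ERK2 pairs
#: are the conventional activation-loop sites; MEK2's pair is a configurable
#: default, not sourced from the same reference sentences as the others.
DEFAULT_CANONICAL_SITES: Mapping[str, frozenset[str]] = {
    "Q02750": frozenset({"S218", "S222"}),  # MEK1
    "P36507": frozenset({"S222", "S226"}),  # MEK2 (default; configurable)
    "P27361": frozenset({"T202", "Y204"}),  # ERK1
    "P28482": frozenset({"T185", "Y187"}),  # ERK2
}


@dataclass(frozen=True)
class LintFinding:
    """One machine-readable composability finding."""

    rule_id: str
    severity: str
    protein_key: Optional[str]
    pools: tuple[str, ...]  # offending pool ids, prefixed with "map:" scope
    maps: tuple[str, ...]
    message: str
    payload: Mapping[str, Any] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if not self.pools or not self.maps:
            raise ValueError("a finding must cite at least one pool and one map")


def _scoped(map_name: str, pool_id: str) -> str:
    return f"{map_name}:{pool_id}"


def _check_names(models: Sequence[MapModel]) -> None:
    names = [m.map_name for m in models]
    if len(names) != len(set(names)):
        raise ValueError("duplicate map names in model collection")


def lint_state_signature(models: Sequence[MapModel]) -> list[LintFinding]:
    """Enforce "once a variable, always a variable" within and across maps."""
    models = sorted(models, key=lambda m: m.map_name)
    _check_names(models)
    findings: list[LintFinding] = []
    per_map_universe: dict[str, dict[str, frozenset[str]]] = {}
    for model in models:
        by_key: dict[str, list[ProteinPool]] = {}
        for pool in model.protein_pools():
            by_key.setdefault(pool.protein_key, []).append(pool)
        for key in sorted(by_key):
            pools = by_key[key]
            sigs = sorted({state_signature(p) for p in pools})
            universe = frozenset(s for sig in sigs for s in sig)
            per_map_universe.setdefault(key, {})[model.map_name] = universe
            if len(sigs) > 1:
                findings.append(
                    LintFinding(
                        rule_id=RULE_STATE_SIGNATURE,
                        severity=SEVERITY_ERROR,
                        protein_key=key,
                        pools=tuple(
                            _scoped(model.map_name, p.pool_id) for p in pools
                        ),
                        maps=(model.map_name,),
                        message=(
                            f"{key}: {len(sigs)} different state-variable sets "
                            f"within map '{model.map_name}'"
                        ),
                        payload={"signatures": [list(s) for s in sigs]},
                    )
                )
    for key in sorted(per_map_universe):
        universes = per_map_universe[key]
        if len(universes) < 2:
            continue
        distinct = sorted({tuple(sorted(u)) for u in universes.values()})
        if len(distinct) > 1:
            pools = tuple(
                _scoped(name, p.pool_id)
                for model in models
                for name, p in (
                    (model.map_name, pool)
                    for pool in model.protein_pools()
                    if pool.protein_key == key
                )
            )
            findings.append(
                LintFinding(
                    rule_id=RULE_STATE_SIGNATURE,
                    severity=SEVERITY_WARNING,
                    protein_key=key,
                    pools=pools,
                    maps=tuple(sorted(universes)),
                    message=(
                        f"{key}: represented with {len(distinct)} distinct "
                        f"state-variable signatures across {len(universes)} maps"
                    ),
                    payload={
                        "signatures": [list(s) for s in distinct],
                        "n_distinct": len(distinct),
                        "per_map": {m: sorted(u) for m, u in universes.items()},
                    },
                )
            )
    return findings


def lint_generic_specific(models: Sequence[MapModel]) -> list[LintFinding]:
    """Flag proteins appearing both inside a generic pool and as specific
    pools, plus generic pools without annotated members."""
    models = sorted(models, key=lambda m: m.map_name)
    _check_names(models)
    findings: list[LintFinding] = []
    as_member: dict[str, list[tuple[str, str]]] = {}
    as_specific: dict[str, list[tuple[str, str]]] = {}
    for model in models:
        for pool in model.protein_pools():
            if pool.is_generic:
                if not pool.members:
                    findings.append(
                        LintFinding(
                            rule_id=RULE_UNANNOTATED_GENERIC,
                            severity=SEVERITY_INFO,
                            protein_key=pool.protein_key,
                            pools=(_scoped(model.map_name, pool.pool_id),),
                            maps=(model.map_name,),
                            message=(
                                f"generic pool '{pool.label}' in map "
                                f"'{model.map_name}' has no annotated members"
                            ),
                            payload={},
                        )
                    )
                for member in pool.members:
                    as_member.setdefault(member, []).append(
                        (model.map_name, pool.pool_id)
                    )
            else:
                as_specific.setdefault(pool.protein_key, []).append(
                    (model.map_name, pool.pool_id)
                )
    for key in sorted(set(as_member) & set(as_specific)):
        occ = sorted(set(as_member[key])), sorted(set(as_specific[key]))
        maps = tuple(sorted({m for m, _ in occ[0]} | {m for m, _ in occ[1]}))
        findings.append(
            LintFinding(
                rule_id=RULE_GENERIC_SPECIFIC,
                severity=SEVERITY_WARNING,
                protein_key=key,
                pools=tuple(
                    _scoped(m, p) for m, p in occ[0] + occ[1]
                ),
                maps=maps,
                message=(
                    f"{key}: lumped into a generic pool and drawn as a "
                    f"specific pool across {len(maps)} map(s)"
                ),
                payload={
                    "generic_occurrences": [list(o) for o in occ[0]],
                    "specific_occurrences": [list(o) for o in occ[1]],
                },
            )
        )
    return findings


def lint_canonical_sites(
    models: Sequence[MapModel],
    reference: Optional[Mapping[str, frozenset[str]]] = None,
) -> list[LintFinding]:
    """Compare each pool's phosphorylated sites with the canonical active set.

    A pool whose phosphorylated residue set is non-empty and differs from
    the reference is flagged, classified as superset / disjoint / other.
    Stateless or unphosphorylated pools are never flagged here.  Proteins
    with phosphosites but no reference entry yield a single info note.
    """
    reference = DEFAULT_CANONICAL_SITES if reference is None else reference
    models = sorted(models, key=lambda m: m.map_name)
    _check_names(models)
    findings: list[LintFinding] = []
    unknown: dict[str, list[str]] = {}
    for model in models:
        for pool in model.protein_pools():
            observed = pool.phospho_sites()
            if not observed:
                continue
            if pool.protein_key not in reference:
                unknown.setdefault(pool.protein_key, []).append(
                    _scoped(model.map_name, pool.pool_id)
                )
                continue
            ref = reference[pool.protein_key]
            if observed == ref:
                continue
            if observed > ref:
                relation = "superset"
            elif not observed & ref:
                relation = "disjoint"
            else:
                relation = "other"
            findings.append(
                LintFinding(
                    rule_id=RULE_CANONICAL_SITES,
                    severity=SEVERITY_WARNING,
                    protein_key=pool.protein_key,
                    pools=(_scoped(model.map_name, pool.pool_id),),
                    maps=(model.map_name,),
                    message=(
                        f"{pool.protein_key} pool '{pool.pool_id}' in map "
                        f"'{model.map_name}': phosphorylated at "
                        f"{sorted(observed)}, canonical active set is "
                        f"{sorted(ref)} ({relation})"
                    ),
                    payload={
                        "observed": sorted(observed),
                        "reference": sorted(ref),
                        "relation": relation,
                    },
                )
            )
    for key in sorted(unknown):
        findings.append(
            LintFinding(
                rule_id=RULE_CANONICAL_SITES,
                severity=SEVERITY_INFO,
                protein_key=key,
                pools=tuple(sorted(unknown[key])),
                maps=tuple(sorted({p.split(":", 1)[0] for p in unknown[key]})),
                message=(
                    f"{key}: phosphorylated pools observed but no canonical "
                    "site reference configured; skipped"
                ),
                payload={"relation": "unknown_reference"},
            )
        )
    return findings


# -- generic complex expansion -------------------------------------------------


@dataclass(frozen=True)
class ConcreteComplex:
    """One concrete complex implied by a complex with generic components."""

    components: tuple[ProteinPool, ...]

    @property
    def composition(self) -> tuple[tuple[str, Signature], ...]:
        return tuple(
            sorted((p.protein_key, state_signature(p)) for p in self.components)
        )

    @property
    def label(self) -> str:
        return "-".join(key for key, _ in self.composition)


def expand_generic_complex(
    model: MapModel, cx: ComplexPool
) -> list[ConcreteComplex]:
    """Enumerate the concrete complexes implied by generic components.

    Every generic component with ``k`` annotated members is substituted by
    each member in turn; order-equivalent results collapse, so a single
    ``m``-mer of one ``k``-member generic yields C(k+m-1, m) complexes.
    State variables on the generic are copied to each member instance.
    Generic components without members cannot be expanded (error).
    """
    from pdlint.model import preferred_label

    option_lists: list[list[ProteinPool]] = []
    for comp in model.components_of(cx):
        if not comp.is_generic:
            option_lists.append([comp])
            continue
        if not comp.members:
            raise ValueError(
                f"complex {cx.pool_id}: generic component {comp.pool_id!r} has "
                "no annotated members; cannot expand"
            )
        options = []
        for member in sorted(comp.members):
            options.append(
                ProteinPool(
                    pool_id=f"{comp.pool_id}__{member}",
                    label=preferred_label(member),
                    protein_key=member,
                    uniprot_ids=frozenset(),
                    is_generic=False,
                    members=frozenset(),
                    state=comp.state,
                    compartment=comp.compartment,
                )
            )
        option_lists.append(options)
    seen: dict[tuple, ConcreteComplex] = {}
    for combo in itertools.product(*option_lists):
        key = tuple(sorted((p.protein_key, tuple(sorted((sv.site, sv.value) for sv in p.state))) for p in combo))
        if key not in seen:
            seen[key] = ConcreteComplex(components=tuple(combo))
    return [seen[k] for k in sorted(seen)]


# -- complex variants ----------------------------------------------------------


def _component_families(model: MapModel, cx: ComplexPool) -> list[frozenset[str]]:
    fams = []
    for comp in model.components_of(cx):
        if comp.is_generic and comp.members:
            fams.append(frozenset(comp.members | {comp.protein_key}))
        else:
            fams.append(frozenset({comp.protein_key}))
    return fams


def _protein_family(pool: ProteinPool) -> frozenset[str]:
    if pool.is_generic and pool.members:
        return frozenset(pool.members | {pool.protein_key})
    return frozenset({pool.protein_key})


def _match_families(
    families: list[frozenset[str]], elements: list[frozenset[str]]
) -> Optional[list[int]]:
    """Greedy bijection between two equal-length family lists (sets are tiny)."""
    if len(families) != len(elements):
        return None
    for perm in itertools.permutations(range(len(elements))):
        if all(families[i] & elements[j] for i, j in enumerate(perm)):
            return list(perm)
    return None


def lint_complex_variants(
    models: Sequence[MapModel], subset_match: bool = False
) -> list[LintFinding]:
    """Flag protein sets drawn as a complex in one map and differently in
    another (free-pool processes, or a complex with different states).

    Matching uses exact protein-set equality up to generic-family overlap;
    ``subset_match`` additionally reports complexes whose protein set is a
    strict subset of another map's complex (higher recall, more noise).
    """
    models = sorted(models, key=lambda m: m.map_name)
    _check_names(models)
    if len(models) < 2:
        return []
    findings: list[LintFinding] = []
    reported: set[tuple] = set()
    for model_a in models:
        for cx in model_a.complex_pools():
            families = _component_families(model_a, cx)
            sig_a = complex_composition_signature(model_a, cx)
            key_multiset = tuple(sorted(key for key, _ in sig_a))
            for model_b in models:
                if model_b.map_name == model_a.map_name:
                    continue
                # (1) differently composed complex with the same protein set
                for cx_b in model_b.complex_pools():
                    sig_b = complex_composition_signature(model_b, cx_b)
                    same_keys = tuple(sorted(k for k, _ in sig_b)) == key_multiset
                    subset_keys = subset_match and set(
                        k for k, _ in sig_b
                    ) < set(key_multiset)
                    if (same_keys and sig_b != sig_a) or subset_keys:
                        mark = (
                            "complex_vs_complex",
                            key_multiset,
                            frozenset({model_a.map_name, model_b.map_name}),
                        )
                        if mark in reported:
                            continue
                        reported.add(mark)
                        findings.append(
                            LintFinding(
                                rule_id=RULE_COMPLEX_VARIANT,
                                severity=SEVERITY_WARNING,
                                protein_key=None,
                                pools=(
                                    _scoped(model_a.map_name, cx.pool_id),
                                    _scoped(model_b.map_name, cx_b.pool_id),
                                ),
                                maps=tuple(
                                    sorted({model_a.map_name, model_b.map_name})
                                ),
                                message=(
                                    f"complex over {list(key_multiset)} composed "
                                    f"differently in maps '{model_a.map_name}' "
                                    f"and '{model_b.map_name}'"
                                ),
                                payload={
                                    "composition_a": [list(map(list, sig_a))],
                                    "composition_b": [list(map(list, sig_b))],
                                },
                            )
                        )
                # (2) same interactions drawn with free pools
                if any(
                    _match_families(
                        families, _component_families(model_b, cx_b)
                    )
                    is not None
                    for cx_b in model_b.complex_pools()
                ):
                    continue  # model_b has an equivalent complex; handled above
                covering: list[str] = []
                covered: set[int] = set()
                for proc in (model_b.processes[k] for k in sorted(model_b.processes)):
                    parts = [
                        model_b.pools[pid]
                        for pid in proc.participant_ids()
                        if pid in model_b.pools
                    ]
                    if len({p.protein_key for p in parts}) < 2:
                        continue
                    hits: set[int] = set()
                    ok = True
                    for pool in parts:
                        fam = _protein_family(pool)
                        matched = [
                            i for i, f in enumerate(families) if f & fam
                        ]
                        if not matched:
                            ok = False
                            break
                        hits.update(matched)
                    if ok:
                        covering.append(proc.process_id)
                        covered.update(hits)
                if covering and covered == set(range(len(families))):
                    mark = (
                        "complex_vs_free",
                        key_multiset,
                        frozenset({model_a.map_name, model_b.map_name}),
                    )
                    if mark in reported:
                        continue
                    reported.add(mark)
                    findings.append(
                        LintFinding(
                            rule_id=RULE_COMPLEX_VARIANT,
                            severity=SEVERITY_WARNING,
                            protein_key=None,
                            pools=(_scoped(model_a.map_name, cx.pool_id),),
                            maps=tuple(sorted({model_a.map_name, model_b.map_name})),
                            message=(
                                f"proteins {list(key_multiset)} form a complex in "
                                f"map '{model_a.map_name}' but interact as free "
                                f"pools in map '{model_b.map_name}'"
                            ),
                            payload={
                                "complex_map": model_a.map_name,
                                "free_map": model_b.map_name,
                                "free_processes": sorted(covering),
                            },
                        )
                    )
    return sorted(
        findings, key=lambda f: (f.maps, f.message)
    )


def run_all_lints(
    models: Sequence[MapModel],
    reference: Optional[Mapping[str, frozenset[str]]] = None,
    rules: Optional[Iterable[str]] = None,
) -> list[LintFinding]:
    """Run the selected lint rules (all by default) over a map collection."""
    selected = set(rules) if rules is not None else set(ALL_RULES)
    unknown = selected - set(ALL_RULES)
    if unknown:
        raise ValueError(f"unknown lint rule(s): {sorted(unknown)}")
    findings: list[LintFinding] = []
    if selected & {RULE_STATE_SIGNATURE}:
        findings += lint_state_signature(models)
    if selected & {RULE_GENERIC_SPECIFIC, RULE_UNANNOTATED_GENERIC}:
        gs = lint_generic_specific(models)
        findings += [f for f in gs if f.rule_id in selected]
    if selected & {RULE_CANONICAL_SITES}:
        findings += lint_canonical_sites(models, reference=reference)
    if selected & {RULE_COMPLEX_VARIANT} and len(models) >= 2:
        findings += lint_complex_variants(models)
    return findings
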