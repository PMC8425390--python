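"""Phosphorylation-event census over PD maps.

The auditable record of a catalyzed phosphorylation is the quadruplet
⟨kinase, target, site, map⟩.  This module extracts quadruplets from maps
(both for free proteins and for proteins inside complexes), groups them into
map-free triplets ⟨kinase, target, site⟩, counts per-map occurrences,
filters out unrepeated patterns and flags repeated patterns that are
*represented differently* across maps — the raw material of composability
auditing.

Site tokens: a residue token (``S218``) when the gained variable is a
phosphosite; the empty string when the gained variable is a named flag
(phosphorylation shown without a site).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from pdlint.model import (
    CATALYSIS,
    PHOSPHORYLATED,
    STIMULATION,
    ComplexPool,
    MapModel,
    ProteinPool,
    Signature,
    complex_label,
    state_signature,
)

__all__ = [
    "PhosphoEvent",
    "PhosphoPattern",
    "CensusRow",
    "PatternCensus",
    "ExtractionConfig",
    "extract_phospho_events",
    "expand_events",
    "group_patterns",
    "filter_repeated",
    "find_divergent_representations",
    "representation_versions",
    "count_representation_versions",
    "Representation",
    "DivergenceGroup",
    "FREE",
    "IN_COMPLEX",
]

FREE = "free"
IN_COMPLEX = "in_complex"


@dataclass(frozen=True)
class PhosphoEvent:
    """One catalyzed phosphorylation quadruplet plus provenance."""

    kinase: str
    target: str
    site: str  # residue token, or "" for a site-unspecified (flag) gain
    map_name: str
    mode: str  # FREE or IN_COMPLEX
    process_id: str
    kinase_pool: str = ""
    target_pool: str = ""
    expanded: bool = False

    @property
    def pattern(self) -> "PhosphoPattern":
        return PhosphoPattern(self.kinase, self.target, self.site)


@dataclass(frozen=True)
class PhosphoPattern:
    """The map-free triplet ⟨kinase, target, site⟩."""

    kinase: str
    target: str
    site: str

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.kinase, self.target, self.site)


@dataclass(frozen=True)
class CensusRow:
    pattern: PhosphoPattern
    per_map: tuple[tuple[str, int], ...]  # sorted (map_name, count)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.per_map)

    @property
    def n_maps(self) -> int:
        return len(self.per_map)


@dataclass(frozen=True)
class PatternCensus:
    rows: tuple[CensusRow, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def row_for(self, kinase: str, target: str, site: str) -> Optional[CensusRow]:
        for row in self.rows:
            if row.pattern.as_tuple() == (kinase, target, site):
                return row
        return None

    def to_dataframe(self) -> pd.DataFrame:
        records = [
            {
                "kinase": r.pattern.kinase,
                "target": r.pattern.target,
                "site": r.pattern.site,
                "n_maps": r.n_maps,
                "total": r.total,
                "maps": ";".join(f"{m}:{n}" for m, n in r.per_map),
            }
            for r in self.rows
        ]
        return pd.DataFrame(
            records, columns=["kinase", "target", "site", "n_maps", "total", "maps"]
        )


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction switches.

    ``include_stimulation`` also accepts stimulation arcs as the catalytic
    modulation; ``mode`` restricts matching to free proteins, in-complex
    proteins, or both.
    """

    include_stimulation: bool = False
    mode: str = "both"  # "free" | "complex" | "both"


def _kinase_classes(config: ExtractionConfig) -> frozenset[str]:
    if config.include_stimulation:
        return frozenset({CATALYSIS, STIMULATION})
    return frozenset({CATALYSIS})


def _diff_states(
    r: ProteinPool, p: ProteinPool
) -> tuple[tuple[str, ...], bool]:
    """Sites newly phosphorylated going r -> p, and whether the change is clean.

    Clean means nothing else changed: no site dropped, no value changed other
    than a gain of "P", no non-phospho variable appearing.
    """
    rmap = {sv.site: sv.value for sv in r.state}
    pmap = {sv.site: sv.value for sv in p.state}
    gained = tuple(
        sorted(
            site
            for site, val in pmap.items()
            if val == PHOSPHORYLATED and rmap.get(site) != PHOSPHORYLATED
        )
    )
    for site, val in rmap.items():
        if site not in pmap:
            return gained, False
        if site in gained:
            continue
        if pmap[site] != val:
            return gained, False
    for site, val in pmap.items():
        if site not in rmap and site not in gained:
            return gained, False
    return gained, True


def _event_sites(pool: ProteinPool, gained: Sequence[str]) -> list[str]:
    """Map gained variables to event site tokens ("" for flags, de-duplicated)."""
    from pdlint.model import is_residue_site

    sites: list[str] = []
    for site in gained:
        token = site if is_residue_site(site) else ""
        if token not in sites:
            sites.append(token)
    return sites


def _match_complex_transition(
    model: MapModel, rc: ComplexPool, pc: ComplexPool
) -> list[tuple[ProteinPool, ProteinPool, tuple[str, ...]]]:
    """Match a complex-to-complex transition component-wise.

    Returns the (reactant component, product component, gained sites) pairs
    of an assignment in which every component pair shares a protein key and
    is either identical or a clean phospho gain, with at least one gain.
    Returns [] when no such assignment exists.
    """
    rcomps = model.components_of(rc)
    pcomps = model.components_of(pc)
    if len(rcomps) != len(pcomps):
        return []
    n = len(rcomps)
    for perm in itertools.permutations(range(n)):
        pairs = []
        ok = True
        for i, j in enumerate(perm):
            a, b = rcomps[i], pcomps[j]
            if a.protein_key != b.protein_key:
                ok = False
                break
            gained, clean = _diff_states(a, b)
            if not clean:
                ok = False
                break
            pairs.append((a, b, gained))
        if ok and any(g for _, _, g in pairs):
            return [(a, b, g) for a, b, g in pairs if g]
    return []


def extract_phospho_events(
    model: MapModel, config: ExtractionConfig = ExtractionConfig()
) -> list[PhosphoEvent]:
    """Extract all catalyzed phosphorylation quadruplets from one map.

    Free mode: a reactant and a product protein pool share a protein key and
    the product cleanly gains phosphorylated site(s).  In-complex mode: a
    reactant and a product complex match component-wise except for clean
    gains.  In both modes the process must carry a catalysis modulator (or
    stimulation, if enabled); the kinase is that modulator's protein key, or
    the complex composition label when the catalyst is a complex.

    One event is emitted per gained site (a process adding two sites yields
    two quadruplets); duplicate quadruplets from a single process are
    de-duplicated.  Unmatched processes are ignored.
    """
    classes = _kinase_classes(config)
    events: list[PhosphoEvent] = []
    seen: set[tuple] = set()

    def emit(kinase_pool_id, target_pool, sites, mode, process_id):
        kin_entity = model.entity(kinase_pool_id)
        if isinstance(kin_entity, ComplexPool):
            kinase = complex_label(model, kin_entity)
        else:
            kinase = kin_entity.protein_key
        for site in sites:
            ev = PhosphoEvent(
                kinase=kinase,
                target=target_pool.protein_key,
                site=site,
                map_name=model.map_name,
                mode=mode,
                process_id=process_id,
                kinase_pool=kinase_pool_id,
                target_pool=target_pool.pool_id,
            )
            key = (ev.kinase, ev.target, ev.site, ev.mode, ev.process_id)
            if key not in seen:
                seen.add(key)
                events.append(ev)

    for proc in (model.processes[k] for k in sorted(model.processes)):
        kin_ids = [pid for pid, cls in proc.modulators if cls in classes]
        if not kin_ids:
            continue
        if config.mode in ("free", "both"):
            for rid in proc.reactants:
                if rid not in model.pools:
                    continue
                r = model.pools[rid]
                for pid in proc.products:
                    if pid not in model.pools:
                        continue
                    p = model.pools[pid]
                    if r.protein_key != p.protein_key:
                        continue
                    gained, clean = _diff_states(r, p)
                    if not gained or not clean:
                        continue
                    sites = _event_sites(p, gained)
                    for kid in kin_ids:
                        emit(kid, p, sites, FREE, proc.process_id)
        if config.mode in ("complex", "both"):
            for rid in proc.reactants:
                if rid not in model.complexes:
                    continue
                rc = model.complexes[rid]
                for pid in proc.products:
                    if pid not in model.complexes:
                        continue
                    pc = model.complexes[pid]
                    for _, target, gained in _match_complex_transition(model, rc, pc):
                        sites = _event_sites(target, gained)
                        for kid in kin_ids:
                            emit(kid, target, sites, IN_COMPLEX, proc.process_id)
    return events


def _family(model: MapModel, pool_id: str, key: str) -> frozenset[str]:
    """Identity family of an event participant: the member keys of an
    annotated generic pool, else the key itself."""
    if pool_id in model.pools:
        pool = model.pools[pool_id]
        if pool.is_generic and pool.members:
            return frozenset(pool.members)
    return frozenset({key})


def expand_events(
    events: Iterable[PhosphoEvent], models: Mapping[str, MapModel]
) -> list[PhosphoEvent]:
    """Rewrite events over generic pools into per-member events.

    Each generic participant with annotated members fans out into one event
    per member (cross-product when both kinase and target are generic),
    flagged ``expanded=True``.  Events over specific pools, complex-catalyst
    labels, or unannotated generics pass through unchanged.
    """
    out: list[PhosphoEvent] = []
    for ev in events:
        model = models[ev.map_name]
        kfam = sorted(_family(model, ev.kinase_pool, ev.kinase))
        tfam = sorted(_family(model, ev.target_pool, ev.target))
        if kfam == [ev.kinase] and tfam == [ev.target]:
            out.append(ev)
            continue
        for k, t in itertools.product(kfam, tfam):
            out.append(
                PhosphoEvent(
                    kinase=k,
                    target=t,
                    site=ev.site,
                    map_name=ev.map_name,
                    mode=ev.mode,
                    process_id=ev.process_id,
                    kinase_pool=ev.kinase_pool,
                    target_pool=ev.target_pool,
                    expanded=True,
                )
            )
    return out


def group_patterns(events: Iterable[PhosphoEvent]) -> PatternCensus:
    """Group quadruplets by their triplet and count per-map occurrences.

    The per-map count is the number of distinct processes in that map
    yielding the triplet; rows are ordered lexicographically by triplet.
    """
    buckets: dict[tuple[str, str, str], dict[str, set[str]]] = {}
    for ev in events:
        trip = (ev.kinase, ev.target, ev.site)
        buckets.setdefault(trip, {}).setdefault(ev.map_name, set()).add(ev.process_id)
    rows = []
    for trip in sorted(buckets):
        per_map = tuple(
            sorted((m, len(pids)) for m, pids in buckets[trip].items())
        )
        rows.append(CensusRow(pattern=PhosphoPattern(*trip), per_map=per_map))
    return PatternCensus(rows=tuple(rows))


def filter_repeated(census: PatternCensus) -> PatternCensus:
    """Discard patterns that are not repeated (total occurrence < 2)."""
    return PatternCensus(rows=tuple(r for r in census.rows if r.total >= 2))


# -- divergence ----------------------------------------------------------------


@dataclass(frozen=True)
class Representation:
    """How a kinase→target step is drawn in one map."""

    sites: frozenset[str]
    modes: frozenset[str]
    target_generic: bool
    target_signatures: frozenset[Signature]


@dataclass(frozen=True)
class DivergenceGroup:
    """A repeated kinase→target pair drawn differently across maps."""

    kinase: str
    target: str
    per_map: tuple[tuple[str, Representation], ...]  # sorted by map name

    @property
    def n_versions(self) -> int:
        return len({rep for _, rep in self.per_map})

    @property
    def maps(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.per_map)


def find_divergent_representations(
    census: PatternCensus,
    models: Sequence[MapModel],
    config: ExtractionConfig = ExtractionConfig(),
) -> list[DivergenceGroup]:
    """Find repeated kinase→target pairs that are represented differently.

    Pairs are formed over generic-member expansion, so a generic "MEK"
    target and a specific MEK1 pool contribute to the same pair.  A pair
    qualifies when a triplet of the (already filtered) census maps onto it;
    its evidence collects, per map, the representation tuple (site tokens
    gained, free/in-complex mode, generic vs specific target, target
    signatures).  Only pairs with more than one distinct representation are
    returned, ordered by (kinase, target).
    """
    by_name = {m.map_name: m for m in models}
    if len(by_name) != len(models):
        raise ValueError("duplicate map names in model collection")
    events_by_map = {
        name: extract_phospho_events(m, config) for name, m in by_name.items()
    }

    def pairs_of(ev: PhosphoEvent) -> set[tuple[str, str]]:
        model = by_name[ev.map_name]
        kfam = _family(model, ev.kinase_pool, ev.kinase)
        tfam = _family(model, ev.target_pool, ev.target)
        return set(itertools.product(sorted(kfam), sorted(tfam)))

    # which expanded pairs are backed by a repeated triplet
    repeated_trips = {row.pattern.as_tuple() for row in census.rows}
    qualified: set[tuple[str, str]] = set()
    pair_events: dict[tuple[str, str], dict[str, list[PhosphoEvent]]] = {}
    for name, events in events_by_map.items():
        for ev in events:
            for pair in pairs_of(ev):
                pair_events.setdefault(pair, {}).setdefault(name, []).append(ev)
                if (ev.kinase, ev.target, ev.site) in repeated_trips:
                    qualified.add(pair)

    groups: list[DivergenceGroup] = []
    for pair in sorted(qualified):
        per_map = []
        for name in sorted(pair_events.get(pair, {})):
            evs = pair_events[pair][name]
            model = by_name[name]
            target_pools = [
                model.pools[e.target_pool] for e in evs if e.target_pool in model.pools
            ]
            rep = Representation(
                sites=frozenset(e.site for e in evs),
                modes=frozenset(e.mode for e in evs),
                target_generic=any(p.is_generic for p in target_pools),
                target_signatures=frozenset(
                    state_signature(p) for p in target_pools
                ),
            )
            per_map.append((name, rep))
        group = DivergenceGroup(kinase=pair[0], target=pair[1], per_map=tuple(per_map))
        if group.n_versions > 1:
            groups.append(group)
    return groups


def representation_versions(
    groups: Sequence[DivergenceGroup],
) -> dict[str, frozenset]:
    """Per-map representation profiles over a set of divergent groups.

    Two maps share a profile exactly when every divergent step they both
    show is drawn identically in both; the number of distinct profiles is
    the number of representation versions of the pathway across the maps.
    """
    profiles: dict[str, set] = {}
    for g in groups:
        for name, rep in g.per_map:
            profiles.setdefault(name, set()).add((g.kinase, g.target, rep))
    return {name: frozenset(items) for name, items in profiles.items()}


def count_representation_versions(groups: Sequence[DivergenceGroup]) -> int:
    return len(set(representation_versions(groups).values()))
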