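# Methods

## The map model

A process description (PD) map is represented as a typed in-memory graph
(`MapModel`): protein pools, complex pools, and processes with role-tagged
participants (reactants, products, modulators).  This replaces an external
property-graph database; the phosphorylation queries are re-expressed as
native structural matching, which removes a server dependency without
changing what is matched.

**State variables.**  A pool carries a set of `(site, value)` pairs.  Sites
are residue tokens (amino-acid letter + 1-based position in UniProt
canonical numbering, `S218`) or named flags (`activity`, `phospho`).  Values
are `""` (shown but unset), `"P"` (phosphorylated) or any other string
(e.g. `"active"`).  A pool's *signature* is the set of sites it shows,
irrespective of values — this is the quantity governed by the "once a
variable, always a variable" rule, under which a variable introduced for a
protein must appear on every pool of that protein in a map.

**Identity.**  Protein pools resolve to a canonical `protein_key` with
precedence: UniProt accession (lowest sorted when several) > alias-table hit
on the normalized label > the upper-cased trimmed label.  The shipped alias
table covers the RAS–RAF–MEK–ERK neighbourhood (MEK1→Q02750, MEK2→P36507,
ERK1→P27361, ERK2→P28482, …) and is user-replaceable.  The function is total
and idempotent.  Generic pools (lumping several proteins) keep their label
as key and carry their member keys; generics without annotated members are
legal but flagged by a lint, since membership annotation is what makes
lumped entities machine-comparable.

**Multiset canonicalization.**  Complex components and process participant
lists are multisets; they are stored sorted so that structurally equal
objects compare equal regardless of construction order.

## Phosphorylation census

An event is emitted for a process when (a) a reactant and a product protein
pool share a protein key and the product *cleanly gains* phosphorylated
sites — nothing else about the state may change (no site dropped, no other
value changed); or (b) a reactant and a product complex match component-wise
with every component pair either identical or a clean gain.  The process
must carry a catalysis modulator (stimulation arcs are accepted only behind
a config switch); the kinase is the modulator's protein key, or a
deterministic composition label when the catalyst is a complex.  One
quadruplet is emitted per gained residue site; gains of named flags emit a
single quadruplet with the empty site token (phosphorylation drawn without a
site).  Dephosphorylation is not an event.

Two deliberate interpretations:

* The in-complex matcher allows *any number* of clean-gain component pairs
  (all other pairs must be identical), not exactly one: a homodimer
  transition phosphorylates both protomers in one process, and restricting
  to a single gaining component would silently drop such events.
* Within a map, duplicate processes each count once (per-map counts are
  distinct-process counts); exact duplicate quadruplets from one process are
  de-duplicated.

Grouping by the triplet ⟨kinase, target, site⟩ gives the census; repeat
filtering keeps rows with total occurrence ≥ 2.

**Divergence.**  Repeated steps are grouped by (kinase, target) *over
generic-member expansion*: a generic participant with annotated members
contributes one pair per member, so a generic "MEK" target and a specific
MEK1 pool land in the same group.  (Without this, generic-vs-specific
divergence — the most common conflict — would be structurally invisible.)
For each group and map, the representation tuple records the site tokens
gained, the free/in-complex modes, whether the target is generic, and the
target signatures; a group is divergent when maps disagree.  The number of
*representation versions* across a collection is the number of distinct
per-map profiles over all divergent groups — two maps share a version
exactly when every divergent step they both show is drawn identically.

## Lints

* `STATE_SIGNATURE` — within-map signature conflicts are **errors** (they
  make a map internally inconsistent and block merging); cross-map
  universe differences are **warnings** (merge-blockers only when a merge is
  attempted).  The payload lists the distinct signatures.
* `GENERIC_SPECIFIC` (warning) — a protein key occurs both as a generic
  member and as a specific pool; `UNANNOTATED_GENERIC` (info) — a generic
  without members.
* `CANONICAL_SITES` (warning) — a pool's phosphorylated residue set is
  non-empty and differs from the configured canonical activating set,
  classified superset / disjoint / other.  Unphosphorylated and stateless
  pools are never flagged (their handling belongs to `STATE_SIGNATURE`).
  The reference table is data, not hard-coded biology; the shipped default
  covers MEK1 {S218,S222}, ERK1 {T202,Y204}, ERK2 {T185,Y187} and
  MEK2 {S222,S226}, the last being a package default rather than a quoted
  reference value.
* `COMPLEX_VARIANT` (warning, ≥ 2 maps) — a protein set drawn as a complex
  in one map and, in another, as free-pool processes jointly covering the
  same set, or as a complex with the same proteins but different states.
  Matching is per-protein with generic-family overlap (RAF1 matches a
  generic RAF whose members include it); exact-set equality by default,
  subset matching behind an opt-in flag because it trades precision for
  recall.

## Generic-complex expansion

`expand_generic_complex` substitutes every generic component by each of its
members and collapses order-equivalent results, copying the generic's state
onto each member instance.  For an *m*-mer of one *k*-member generic the
count is the multiset coefficient C(k+m−1, m); the tests verify this against
brute-force enumeration for all k, m ≤ 5.

## Harmonization and merging

`propagate_state_variables` extends every pool of a protein to a given site
universe (existing values preserved, new variables unset) and refuses
universes that would drop an existing site.  It is idempotent and monotone.
`replace_generic_with_specific` replaces all generic pools of one key by
per-member pools and clones every touching process and complex per member —
fan-out factor = member count — so the census of the transformed map equals
the member-expanded census of the original (a tested invariant).

`merge_maps` runs the two merge-blocking lints first.  Without
auto-harmonization any blocking finding aborts the merge with the findings
attached (never a silent partial merge).  With it, conflicting proteins are
propagated to their union universes (and generics optionally replaced, with
a follow-up propagation pass, since copied generic states can reintroduce
signature conflicts against pre-existing specific pools).  Pools then merge
on (protein key, full state, compartment, genericity, members), complexes on
component-identity multisets, processes on (kind, participant identities,
modulator identities); the merged map must validate and be free of
within-map errors.  These identity keys are the minimal ones consistent with
accession-based entity identification; no attempt is made to compute a
consensus variant — variant *detection* is the census/lint layer's job, and
choosing which variant to keep needs literature judgement.

## File formats

The native JSON document is the interchange of record: canonical
serialization (sorted keys and arrays, fixed indentation) makes
`write∘read` byte-stable, and a hand-written structural validator reports
violations with JSON paths (the same rules ship as a schema document for
reference).  The CellDesigner-flavoured SBML writer targets Level 2 with the
4.x extension namespace and a version-tolerant subset: proteins with
modification residues, species with per-species modification states
(`phosphorylated` ↔ `P`, `empty` ↔ unset, other values verbatim), complex
species, and reactions with reactant/product/modifier lists and modification
types.  Per-species modification lists (including explicit `empty` states)
are what preserves deliberately inconsistent maps — a map violating the
state-variable rule must survive a round-trip so it can be linted.
Constructs beyond plain CellDesigner (generic membership, complex
composition by pool id, exact process kinds) travel in a small auxiliary
annotation namespace; unsupported constructs are skipped with a logged
warning.  Map-name precedence on read: explicit override > model name >
file stem.

## Fixtures and the synthetic ground truth

The presets reconstruct the *testable content* of eleven RAS–RAF–MEK–ERK
fragment styles — which pools exist, their state universes, which steps are
catalyzed phosphorylations, what is generic and what sits in complexes — not
layout or full species inventories.  Conventions: phosphorylation drawn
without a site is the flag `phospho` with value `P`; the single unnamed
RAF1 state of the canonical fragments is the flag `activity` (the same token
used as the seventh variable of the detailed fragment, so the harmonized
union universe has exactly seven variables); the six detailed RAF1
phosphosites are literature-canonical regulatory sites (S259, S289, S296,
S301, S338, S621) used as configurable placeholders — only the counts
(six residues, seven variables) are asserted, not the names.  Upstream
activation by RAS is modelled as a catalyzed transition setting
`activity=active`, which deliberately does **not** count as a
phosphorylation event (the gained value is not `P`).  A KSR1-scaffold
variant is not included; the SEF-bound complex stands in for scaffold-type
variation.

The random generator plants three kinds of distractors alongside its
phospho events — associations, catalyzed dephosphorylations, and
uncatalyzed gains — all of which must yield no events.  It emulates the
structural variety that matters to extraction (generic/specific targets,
flags and residues, free and in-complex steps, shared pools between
processes); it does not emulate curation noise such as misannotated
identifiers, nested complexes or cross-compartment transport, so a green
oracle suite demonstrates correctness of the matching semantics, not
robustness to dirty real-world exports.  Default sizes (8 proteins, 12
processes, ~50 % phospho, ~25 % of those in complexes) keep each map small
enough that the whole 100-seed oracle suite runs in seconds.

## Reproduction script

`scripts/acceptance.py` recomputes, from freshly built fixtures: the number
of distinct RAF1 signatures across the six ACSN-style fragments (3), the
number of maps carrying the canonical RAF1→MEK triplet (3), the
generic-dimer expansion count (3), the detailed RAF1 variable/phosphosite
counts (7 / 6), the representation-version count over the three
PANTHER-style fragments (3), and agreement percentages for the oracle,
expansion, round-trip, merge-guard and rename-invariance suites.  The 100
random-map seeds are derived from `--seed`; everything else is
deterministic.

## Known limitations

* The CellDesigner subset is write-biased: foreign files are read on a
  best-effort basis (identity falls back to label normalization; species
  without a recognized identity are skipped with a warning).
* Catalyst complexes are recorded under a composition label; no attempt is
  made to identify the catalytic subunit.
* Complex-variant matching is set-based; stoichiometry differences between
  a complex and its free-pool counterpart are not scored.
* Divergence evidence stops at the representation tuples; deciding whether
  two variants are "the same mechanism drawn differently" or genuinely
  different biology is left to the reader of the report.
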