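# pdlint

**Composability auditing for process description pathway maps.**

Disease maps and pathway databases (ACSN, PANTHER, Reactome and kin) describe
signalling as SBGN-style *process description* (PD) diagrams: stateful entity
pools — proteins with phosphosite/flag state variables, lumped "generic"
groups, complexes — connected through processes with catalysis arcs.  Reusing
a fragment from one map inside another is only possible when both draw shared
entities the same way, and in practice they rarely do: the same kinase step
appears with and without named phosphosites, with generic "MEK" or specific
MEK1/MEK2, free or buried inside a complex, with different state-variable
universes on the same protein.

`pdlint` is a library (plus a thin CLI) for curators and systems biologists
who need to find and fix those conflicts before composing maps:

- **Census** — every catalyzed phosphorylation is recorded as a quadruplet
  ⟨kinase, target, site, map⟩ (two matching modes: free proteins, and
  proteins inside complexes).  Quadruplets are grouped by their map-free
  triplet ⟨kinase, target, site⟩, counted per map, singletons discarded, and
  repeated patterns whose representations differ across maps are reported
  with per-map evidence (site detail, generic vs specific target, free vs
  in-complex mode, target signatures).
- **Lints** — the recurring composability barriers as machine-checkable
  rules: `STATE_SIGNATURE` ("once a variable, always a variable": a state
  variable introduced for a protein must appear on every pool of that
  protein), `GENERIC_SPECIFIC` / `UNANNOTATED_GENERIC`, `CANONICAL_SITES`
  (phosphorylated sites vs the canonical activating set, e.g. MEK1 S218/S222,
  ERK1 T202/Y204, ERK2 T185/Y187), and `COMPLEX_VARIANT`.
- **Expansion** — a complex containing a generic component with *k* annotated
  members used *m* times implies C(k+m−1, m) concrete complexes
  (multiset combinations); `expand_generic_complex` enumerates them.
- **Harmonization** — `propagate_state_variables` (extend every pool of a
  protein to a union universe, preserving values), `replace_generic_with_specific`
  (fan processes out per member), and `merge_maps`, which refuses to merge
  while blocking findings exist unless auto-harmonization is requested.
- **I/O** — a CellDesigner-flavoured SBML Level 2 subset (read/write) and a
  canonical, schema-documented JSON interchange format; both round-trip
  losslessly.
- **Fixtures** — programmatic reconstructions of eleven RAS–RAF–MEK–ERK
  fragment styles, and a seeded random-map generator that returns its maps
  together with the exact phosphorylation events planted in them (the oracle
  used throughout the test suite).

## Worked example

```python
from pdlint import fixtures as fx
from pdlint.census import extract_phospho_events, filter_repeated, group_patterns

models = fx.build_acsn_collection()   # six ACSN-style fragments
events = [e for m in models for e in extract_phospho_events(m)]
print(filter_repeated(group_patterns(events)).to_dataframe().to_string(index=False))
```

```
kinase target site  n_maps  total                                                                                  maps
   MEK    ERK            4      5 Adaptive Immunity:1;Cancer-Associated Fibroblasts:1;Cell Survival:2;Innate Immunity:1
P04049    MEK            3      3                 Adaptive Immunity:1;Cancer-Associated Fibroblasts:1;Innate Immunity:1
```

An empty `site` means the map draws phosphorylation without naming a residue.
The RAF1 (UniProt P04049) → generic-MEK step recurs in exactly the three maps
that share the canonical cascade; the MEK → ERK step additionally recurs
inside the SEF-scaffold variant of the Cell Survival fragment (count 2 there:
once free, once in the complex).  Running the lints over the same collection
reports, among others, that RAF1 is drawn with three distinct state-variable
signatures (none / one flag / seven variables) — the conflict `merge_maps`
refuses to cross until the universes are propagated to their union:

```python
from pdlint.harmonize import MergeOptions, merge_maps
can, emt = fx.build_fixture("acsn_canonical"), fx.build_fixture("acsn_emt_raf1_detailed")
merge_maps([can, emt]).ok                                        # False (blocked)
merge_maps([can, emt], MergeOptions(auto_harmonize=True)).ok     # True
```

The `examples/` directory holds one short narrative script per capability;
each prints the numbers it computes and a line on what they mean.

## Command line

```sh
pdlint fixtures --preset acsn_emt_raf1_detailed --out emt.xml
pdlint census  maps/*.xml --out census.tsv
pdlint lint    maps/*.xml --out findings.json      # exit 2 on error findings
pdlint expand  mek_dimer.xml --out expansion.json
pdlint merge   a.xml b.xml --auto-harmonize --out merged.xml --report report.json
pdlint run     maps/*.xml --out-dir out/           # full pipeline, atomic artifacts
```

Exit codes: 0 clean, 2 error-severity findings, 64 usage error.

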