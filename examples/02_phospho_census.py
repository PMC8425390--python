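"""Extract phosphorylation quadruplets and count repeated patterns.

Runs the census over the six ACSN-style fragments: every catalyzed
phosphorylation becomes a quadruplet (kinase, target, site, map); grouping
by the first three fields and discarding singletons leaves the patterns
that recur across maps.
"""

from pdlint import fixtures as fx
from pdlint.census import extract_phospho_events, filter_repeated, group_patterns

models = fx.build_acsn_collection()
events = [e for m in models for e in extract_phospho_events(m)]
print(f"{len(events)} quadruplets from {len(models)} maps")

repeated = filter_repeated(group_patterns(events))
print(repeated.to_dataframe().to_string(index=False))

# 'site' is empty when the map draws phosphorylation without naming a
# residue.  The RAF1 (P04049) -> generic MEK step appears in exactly the
# three maps that share the canonical cascade; the MEK -> ERK step also
# recurs in the SEF-scaffold variant.
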