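"""Merge two conflicting fragments, first blocked, then auto-harmonized.

The canonical fragment shows RAF1 with one state variable; the detailed
fragment shows seven.  Merging is refused until the state-variable
universes are propagated to their union.
"""

from pdlint import fixtures as fx
from pdlint.harmonize import MergeOptions, merge_maps
from pdlint.model import state_signature

can = fx.build_fixture("acsn_canonical")
emt = fx.build_fixture("acsn_emt_raf1_detailed")

blocked = merge_maps([can, emt])
print("merge without harmonization ok?", blocked.ok)
for f in blocked.blocking[:3]:
    print("  blocking:", f.message)

report = merge_maps([can, emt], MergeOptions(auto_harmonize=True))
print("\nmerge with auto-harmonization ok?", report.ok)
for t in report.transformations:
    print("  applied:", t)
raf_sig = next(
    state_signature(p)
    for p in report.merged.protein_pools()
    if p.protein_key == "P04049"
)
print(f"merged RAF1 now shows {len(raf_sig)} variables: {list(raf_sig)}")

# After propagation every RAF1 pool carries the 7-variable union (six
# phosphosites + the activity flag), so the merged map passes the
# within-map state-variable rule.
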