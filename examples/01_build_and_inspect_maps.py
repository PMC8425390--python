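"""Build fixture maps and inspect how the same protein is represented.

Constructs the bundled RAS-RAF-MEK-ERK fragments and prints, per map, the
state-variable signature RAF1 carries — the incompatibility that makes the
fragments hard to merge.
"""

from pdlint import fixtures as fx
from pdlint.model import state_signature

for preset_id in (
    "acsn_canonical",
    "acsn_raf1_stateless",
    "acsn_emt_raf1_detailed",
):
    model = fx.build_fixture(preset_id)
    raf_signatures = {
        state_signature(p)
        for p in model.protein_pools()
        if p.protein_key == "P04049"  # RAF1
    }
    for sig in sorted(raf_signatures):
        print(f"{model.map_name:25s} RAF1 shows {len(sig)} variable(s): {list(sig)}")

# Each line is one way RAF1 is drawn: no variables, a single activity flag,
# or seven variables (six phosphosites plus the flag).  Pools must agree on
# this set before two maps can be composed.
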