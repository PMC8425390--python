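"""Enumerate the concrete complexes hidden inside a generic dimer.

A dimer whose single component is a generic pool lumping MEK1 and MEK2
implies three concrete species: both homodimers and the heterodimer —
the combinatorial cost of expanding lumped complexes, C(k+m-1, m) for an
m-mer of a k-member generic.
"""

from math import comb

from pdlint import fixtures as fx
from pdlint.lints import expand_generic_complex

model = fx.build_fixture("generic_mek_dimer")
dimer = model.complexes["mek_dimer"]
concrete = expand_generic_complex(model, dimer)

print(f"generic dimer expands into {len(concrete)} concrete complexes "
      f"(closed form C(2+2-1, 2) = {comb(3, 2)}):")
for cx in concrete:
    print(" ", cx.label)
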