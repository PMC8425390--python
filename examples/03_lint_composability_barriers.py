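"""Lint a map collection for the recurring composability barriers.

Checks the "once a variable, always a variable" rule, generic-vs-specific
clashes, non-canonical phosphosite sets and complex-vs-free variants over
the bundled fragments, and prints each finding.
"""

from pdlint import fixtures as fx
from pdlint.lints import run_all_lints

models = fx.build_acsn_collection() + [
    fx.build_fixture("panther_bcell_complexes"),
    fx.build_fixture("reactome_l1cam_mek1"),
]
findings = run_all_lints(models)

for f in findings:
    print(f"[{f.severity:7s}] {f.rule_id:19s} {f.message}")
print(f"\n{len(findings)} findings; "
      f"{sum(1 for f in findings if f.severity == 'error')} error(s)")

# Errors are within-map clashes that block merging outright (here: the two
# MEK1 entities with different phosphosite sets).  Warnings are cross-map
# divergences that must be harmonized before fragments can be composed.
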