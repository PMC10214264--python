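"""Enumerate the preprocessing-workflow space and validate a few workflows.

Every workflow chains one compensation, one transformation, one
normalization and one signal-cleaning method (NON = skip the step).  The
space differs between flow (FC) and mass (MC) cytometry because some
methods only make sense for one technique.
"""

from cytobench import enumerate_workflows, parse_workflow, validate_workflow

fc = enumerate_workflows("FC")
mc = enumerate_workflows("MC")
both = enumerate_workflows("both")

print(f"FC workflows:     {len(fc)}")     # 720
print(f"MC workflows:     {len(mc)}")     # 540
print(f"usable on both:   {len(both)}")   # 135
union = set(fc.strings()) | set(mc.strings())
print(f"distinct overall: {len(union)}")  # 720 + 540 - 135 = 1125

print("\nfirst five FC workflows:")
for wf in fc.strings()[:5]:
    print(" ", wf)

# applicability checking: CTS unmixing is a mass-cytometry method
ok, reasons = validate_workflow(parse_workflow("CTS+BOX+GSN+NON"), "FC")
print(f"\nCTS+BOX+GSN+NON valid on FC? {ok}  ({'; '.join(reasons)})")
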