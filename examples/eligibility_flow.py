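"""Eligibility screening of synthetic patient metadata with cohort flow.

Each patient passes or fails seven criteria in a fixed order (alive, adult,
consented, no dementia/psychosis indicator, contactable, English without an
interpreter, coordinator-approved when active); the flow records how many
patients survive each stage.
"""

from msit import SimConfig, filter_eligible, flow_percentages
from msit.synthdata import generate_metadata

records = generate_metadata(SimConfig(n_patients=1000, seed=2))
eligible, flow = filter_eligible(records)

for stage in flow_percentages(flow):
    print(f"{stage.stage_name:32s} {stage.count_in:5d} -> {stage.count_out:5d} "
          f"({stage.percent:.1f}% retained)")
print(f"\neligible: {len(eligible)} / {len(records)}")

# Consent dominates attrition at the default exclusion rates; the product of
# the per-stage retention fractions equals the overall eligibility fraction.
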