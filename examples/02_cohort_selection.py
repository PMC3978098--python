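"""Select the incident patch cohort from a tiny hand-built dataset.

Each exclusion criterion is planted exactly once in the toy fixture, so
the attrition table doubles as a readable specification of the cohort
rules: adults, >=183 days of baseline, >=14 days of follow-up, no prior
patch, no non-patch NRT more than two weeks before index, no prior
bupropion/varenicline.
"""

from nrt_pathways import build_attrition_table, select_cohort
from nrt_pathways.synth import generate_toy_fixture

dataset = generate_toy_fixture()
results = select_cohort(dataset)
table = build_attrition_table(results)

print(table.to_frame().to_string(index=False))
print()
for pid, res in results.items():
    reasons = ",".join(res.exclusion_reasons) or "-"
    print(f"{pid:22s} {res.status:15s} {reasons}")

# The six excl_* patients each trigger exactly one exclusion; the six
# inc_* patients form the study population; the nonpatch_* patient is
# described in the non-patch breakdown and then set aside.
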