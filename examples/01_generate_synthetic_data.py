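"""Generate a small synthetic prescribing dataset and write it to CSV.

The generator emulates a UK primary-care prescription stream: an incident
nicotine-patch cohort with year-dependent combination-therapy rates,
repeat treatment episodes at least 91 days apart, a non-patch-only arm,
and planted patients that each cohort exclusion will catch.
"""

from nrt_pathways import SynthConfig, write_dataset
from nrt_pathways.synth import generate

config = SynthConfig(n_patients=1000, n_practices=5)
dataset = generate(config, seed=7)
paths = write_dataset(dataset, "scratch/example_data")

print(f"practices:     {len(dataset.practices)}")
print(f"patients:      {len(dataset.patients)}")
print(f"prescriptions: {len(dataset.prescriptions)}")
for name, path in paths.items():
    print(f"wrote {name} -> {path}")

# Expect ~24% of patients to receive only non-patch NRT, and most of the
# rest to carry one to three dated NRT episodes anchored on a patch.
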