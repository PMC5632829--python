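"""Generate a synthetic wearable-camera study and look at what it contains.

The generator reproduces the study design: 9 ethnicity x school-decile
strata, 28 PPS-sampled schools, 6 children per school (n = 168), four 10-h
wear days photographed every 7 s, and marketing exposures arising as a
marked episode process calibrated to observed per-day rates.
"""

from camexposure import GeneratorConfig, simulate_cohort

# a smaller-than-default study so the example runs in a couple of seconds
cfg = GeneratorConfig(seed=11, schools_per_stratum=2, children_per_school=4, wear_days=2)
cohort = simulate_cohort(cfg)

print(f"sampling frame: {len(cohort.frame)} schools in 9 strata")
print(f"sampled schools: {len(cohort.schools)} (PPS within stratum)")
print(f"children: {len(cohort.children)}, weights sum to {cohort.children.sampling_weight.sum():.0f}")
print(f"coded image rows: {len(cohort.coded):,} "
      f"({(cohort.coded.medium != '').sum():,} carry a marketing code)")
print(f"true marketing episodes in the ground-truth log: {len(cohort.truth):,}")
print()
print(cohort.coded[cohort.coded.medium != ""].head(5).to_string(index=False))
print()
print("Each coded row is one image bearing one (setting, medium, product) code;")
print("the truth log records the underlying episodes, for recovery testing.")
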