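"""Full analysis: per-day rates with design-based CIs, and rate-ratio models.

Runs the whole pipeline on a synthetic study and prints the headline
estimates: overall core and non-core exposure rates per 10-h day, the
setting margins with their percentage shares, and the adjusted rate-ratio
model with the ethnicity x decile interaction test.
"""

from camexposure import GeneratorConfig, run_pipeline, simulate_cohort

cohort = simulate_cohort(GeneratorConfig(seed=42))
results = run_pipeline(cohort.coded, cohort.children)

for status in ("core", "noncore"):
    row = results[f"rates_{status}"].loc[f"{status}_total"]
    print(f"{status:8s} total: {row['rate']:5.1f} episodes/day "
          f"(95% CI {row['ci_low']:.1f}, {row['ci_high']:.1f})")

print("\nnon-core rate by aggregate setting (share of all non-core exposures):")
nc = results["rates_noncore"]
for m in nc.index:
    if m.startswith("noncore_setting_"):
        r = nc.loc[m]
        print(f"  {m.removeprefix('noncore_setting_'):20s} {r['rate']:5.1f}/day  {r['share']:5.1f}%")

w = results["interaction_noncore"]
print(f"\nethnicity x decile interaction (non-core): "
      f"F({w.df_num}, {w.df_den}) = {w.f_stat:.2f}, p = {w.p_value:.3f}")
print("\nmodel 2 rate ratios (non-core), reference NZE / female / medium decile:")
print(results["models_noncore"][2].drop(index="intercept").round(3).to_string())
print("\nA rate ratio near 1 is expected here: the generator gave every stratum")
print("the same intensity, so remaining variation is sampling noise.")
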