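"""Generate a synthetic admission cohort with known miscalibration.

The generator produces one row per admission: a predicted malnutrition
probability, the dietitian-confirmed outcome, subgroup attributes, a
temporal train/holdout label and the admitting site's decision threshold.
Miscalibration is planted per gender on the logit scale, so every number a
downstream calibration fit reports has a known truth.
"""

from calaudit import default_config, generate_cohort

config = default_config(n=20_000, seed=1)
cohort = generate_cohort(config)

print(cohort.head(5).to_string())
print()
print(f"admissions:       {len(cohort)}")
print(f"event rate:       {cohort['outcome'].mean():.3f}   (target 0.24)")
print(f"female share:     {(cohort['gender'] == 'Female').mean():.3f}   (target 0.499)")
print(f"train share:      {(cohort['sample'] == 'train').mean():.3f}")
print(f"site thresholds:  {sorted(cohort['threshold'].unique())}")
print()
for label, truth in config.group_truth.items():
    print(f"planted truth {label}: intercept {truth.a:+.2f}, slope {truth.b:.2f}")
print("\nA logistic fit of outcome on logit(p_hat) inside each gender should "
      "recover these intercepts and slopes; that is what the other examples "
      "and the audit pipeline verify.")
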