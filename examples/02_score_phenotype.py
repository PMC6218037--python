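"""Score the physical-frailty phenotype on a raw-measurement cohort.

Raw mode draws grip strength, walk time, PASE and anthropometry from
continuous distributions with no latent state: the five component flags and
the robust / pre-frail / frail classification emerge entirely from the
cohort-relative quintile thresholds, as they would on real data.
"""

from frailtrans import GeneratorConfig, generate_baseline, derive_thresholds, score_cohort
from frailtrans.scoring import FLAG_COLUMNS

cfg = GeneratorConfig(n_baseline=2000, mode="raw", seed=3)
cohort = generate_baseline(cfg)

thresholds = derive_thresholds(cohort)
scored = score_cohort(cohort, thresholds)

print("derived cut-offs:")
print(f"  PASE 20th percentile        : {thresholds.pase_cutoff:.1f}")
print(f"  grip cut-offs (man, by BMI quartile): "
      f"{[round(thresholds.grip_cutoff[('man', q)], 1) for q in range(4)]}")
print(f"  walk 80th percentile (woman, short/tall): "
      f"{thresholds.walk_cutoff[('woman', 'short')]:.2f} / "
      f"{thresholds.walk_cutoff[('woman', 'tall')]:.2f} s")

print("\ncomponent prevalence (%):")
for c in FLAG_COLUMNS:
    print(f"  {c:18s} {scored[c].mean() * 100:5.1f}")
print("\nfrailty states (%):")
print((scored["frailty_state"].value_counts(normalize=True) * 100).round(1))

# Each quintile component flags ~20% by construction of the cut-offs; the
# frail share is far below any single component's because frailty requires
# three components to co-occur.
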