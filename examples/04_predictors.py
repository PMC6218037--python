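"""Screen and model predictors of worsened and improved transitions.

The workflow mirrors standard epidemiological practice: univariate logistic
screening at p < 0.25, then a multivariable model always adjusted for age
group and gender with backward elimination at p >= 0.05. Here a binary
low-activity exposure is simulated with a true odds ratio of 2.9 on the
worsened outcome, and the pipeline recovers it.
"""

import numpy as np

from frailtrans import fit_logistic, simulate_binary_exposure_outcome, \
    univariate_screen, build_multivariate

rng = np.random.default_rng(5)
df = simulate_binary_exposure_outcome(
    n=1855, prevalence=0.242, marginal=0.229, odds_ratio=2.9, rng=rng)
df["activity_level"] = np.where(df["exposure"] == 1, "low", "active")
df["age_group"] = rng.choice(["60-69", "70-79", "80+"], len(df), p=[.48, .39, .13])
df["gender"] = rng.choice(["man", "woman"], len(df), p=[.38, .62])

uni = fit_logistic(df, "outcome", ["activity_level"],
                   references={"activity_level": "active"})
t = uni.term("activity_level")
print(f"univariate OR (low vs active): {t.odds_ratio:.2f} "
      f"(95% CI {t.ci_low:.2f}-{t.ci_high:.2f}), p={t.p_value:.1e}")

selected, log = univariate_screen(
    df, "outcome", ["activity_level", "age_group", "gender"],
    references={"activity_level": "active"})
print(f"\nscreen at p<0.25 retained: {selected}")

multi = build_multivariate(df, "outcome", selected,
                           references={"activity_level": "active"})
print("\nmultivariable model (adjusted for age group and gender):")
for term in multi.terms:
    print(f"  {term.variable}={term.level:6s} OR {term.odds_ratio:.2f} "
          f"({term.ci_low:.2f}-{term.ci_high:.2f}) p={term.p_value:.3f}")

# The recovered low-activity OR sits near the configured 2.9; the null
# age/gender adjusters hover near 1, as they should.
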