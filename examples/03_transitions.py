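"""Classify 12-month frailty-state transitions and tabulate the 3x3 matrix.

Transitions are improved (strictly less frail), worsened (strictly more
frail) or unchanged. The matrix reports raw counts, weighted row-conditional
proportions with cluster-robust 95% CIs, and the category proportions.
"""

from frailtrans import (GeneratorConfig, SurveyDesign, compute_weights,
                        build_transition_matrix, generate_baseline,
                        generate_followup, reference_thresholds, score_cohort)
from frailtrans.transitions import join_waves

cfg = GeneratorConfig(seed=11)
baseline = generate_baseline(cfg)
followup = generate_followup(baseline, cfg)

thr = reference_thresholds(cfg)   # state-mode cohorts classify against these
b_scored = score_cohort(baseline, thr)
f_scored = score_cohort(followup, thr)

design = SurveyDesign(eb_selected=156, eb_total=254,
                      lq_selected_per_eb=16, lq_total_per_eb=100)
b_scored = compute_weights(design, b_scored)

joined = join_waves(b_scored, f_scored)
matrix = build_transition_matrix(joined, cluster_col="eb_id")

print(f"participants with both waves: {matrix.n}")
print(f"lost to follow-up           : {len(matrix.attrition)}\n")
print("transition counts (rows = baseline state):")
print(matrix.counts)
print("\ncategory proportions (weighted, with 95% CI):")
for cat, est in matrix.category_props.items():
    print(f"  {cat:9s} {est['estimate'] * 100:5.1f}%  "
          f"({est['ci_low'] * 100:.1f}-{est['ci_high'] * 100:.1f})")

# Most participants stay in their baseline state; the single largest move is
# robust -> pre-frail, mirroring the configured transition matrix.
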