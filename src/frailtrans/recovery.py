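"""Round-trip recovery experiments: generator -> pipeline -> recovered estimates.

Because the package's headline quantities are defined on cohort data it does
not ship, calibration is assessed by round trips: configure the generator
with known population values (state distribution, transition rows, exposure
odds ratios), run the full classification/analysis pipeline on the synthetic
cohorts, and check the pipeline's estimates against the configured truth.
These functions power both the validation suite and scripts/acceptance.py.
"""

from __future__ import annotations

import numpy as np

from .states import STATES, ROBUST, PREFRAIL, FRAIL
from .scoring import score_cohort
from .simulate import (GeneratorConfig, generate_baseline, generate_followup,
                       reference_thresholds, simulate_binary_exposure_outcome)
from .transitions import build_transition_matrix, join_waves, UNCHANGED
from .models import fit_logistic

#: Baseline frailty-state distribution (robust, prefrail, frail) of the
#: emulated cohort.
BASELINE_STATE_PROBS = (0.327, 0.579, 0.094)

#: Weighted row-conditional 12-month transition proportions (rows: baseline
#: robust/prefrail/frail); rows are renormalised from the printed one-decimal
#: percentages.
TRANSITION_MATRIX = (
    (0.475, 0.496, 0.029),
    (0.281, 0.629, 0.089),
    (0.061, 0.449, 0.489),
)

#: Baseline row totals of the two-wave contingency table (n = 1,855).
ROW_TOTALS = (605, 1072, 178)

#: Low-physical-activity prevalence used in the odds-ratio recovery runs.
LOW_ACTIVITY_PREVALENCE = 0.242

#: Marginal transition-category proportions (worsened, improved).
WORSENED_MARGINAL = 0.229
IMPROVED_MARGINAL = 0.199

#: Univariate odds ratios of low activity on each transition outcome.
OR_WORSENED = 2.9
OR_IMPROVED = 0.3


def _spawn(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), label)))


def recover_baseline_states(n: int = 2324, probs=BASELINE_STATE_PROBS,
                            replicates: int = 100, seed: int = 0) -> dict[str, float]:
    """Mean classifier-recovered state proportions over seeded replicates.

    Generates state-mode cohorts, scores them with the generator's reference
    thresholds, and averages the recovered robust/prefrail/frail fractions.
    """
    rng = _spawn(seed, 1)
    sums = {s: 0.0 for s in STATES}
    for _ in range(replicates):
        cfg = GeneratorConfig(n_baseline=n, state_probs=tuple(probs),
                              seed=int(rng.integers(2**31)))
        scored = score_cohort(generate_baseline(cfg), reference_thresholds(cfg))
        freqs = scored["frailty_state"].value_counts(normalize=True)
        for s in STATES:
            sums[s] += float(freqs.get(s, 0.0))
    return {s: sums[s] / replicates for s in STATES}


def recover_robust_row(n_robust: int = ROW_TOTALS[0], replicates: int = 200,
                       seed: int = 0) -> dict[str, float]:
    """Mean recovered robust-row conditional transition proportions.

    All-baseline-robust cohorts transition per the robust row; both waves run
    through the phenotype classifier and the transition tabulation.
    """
    rng = _spawn(seed, 2)
    sums = {s: 0.0 for s in STATES}
    for _ in range(replicates):
        cfg = GeneratorConfig(
            n_baseline=n_robust, state_probs=(1.0, 0.0, 0.0),
            transition_matrix=TRANSITION_MATRIX, attrition_rate=0.0,
            seed=int(rng.integers(2**31)))
        base = generate_baseline(cfg)
        fup = generate_followup(base, cfg)
        thr = reference_thresholds(cfg)
        joined = join_waves(score_cohort(base, thr), score_cohort(fup, thr))
        matrix = build_transition_matrix(joined, weight_col=None)
        for s in STATES:
            sums[s] += matrix.conditional_props.loc[ROBUST, s]["estimate"]
    return {s: sums[s] / replicates for s in STATES}


def recover_unchanged_proportion(n: int = 1855, replicates: int = 200,
                                 seed: int = 0) -> float:
    """Mean recovered proportion in the unchanged transition category.

    Baseline margins follow the contingency-table row totals; follow-up
    states follow the row-conditional transition proportions.
    """
    rng = _spawn(seed, 3)
    margins = np.asarray(ROW_TOTALS, dtype=float)
    margins = margins / margins.sum()
    total = 0.0
    for _ in range(replicates):
        cfg = GeneratorConfig(
            n_baseline=n, state_probs=tuple(margins),
            transition_matrix=TRANSITION_MATRIX, attrition_rate=0.0,
            seed=int(rng.integers(2**31)))
        base = generate_baseline(cfg)
        fup = generate_followup(base, cfg)
        thr = reference_thresholds(cfg)
        joined = join_waves(score_cohort(base, thr), score_cohort(fup, thr))
        matrix = build_transition_matrix(joined, weight_col=None)
        total += matrix.category_props_unweighted[UNCHANGED]
    return total / replicates


def recover_exposure_or(outcome: str, n: int = 1855, replicates: int = 200,
                        seed: int = 0) -> float:
    """Mean recovered univariate OR of low activity on a transition outcome.

    The outcome indicator is assigned from a logistic model at the configured
    marginal proportion and odds ratio; the pipeline's logistic regression is
    then fitted and the OR averaged over replicates.
    """
    if outcome == "worsened":
        marginal, odds_ratio = WORSENED_MARGINAL, OR_WORSENED
        label = 4
    elif outcome == "improved":
        marginal, odds_ratio = IMPROVED_MARGINAL, OR_IMPROVED
        label = 5
    else:
        raise ValueError("outcome must be 'worsened' or 'improved'")
    rng = _spawn(seed, label)
    total = 0.0
    for _ in range(replicates):
        df = simulate_binary_exposure_outcome(
            n, LOW_ACTIVITY_PREVALENCE, marginal, odds_ratio, rng)
        total += fit_logistic(df, "outcome", ["exposure"]).term("exposure").odds_ratio
    return total / replicates
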