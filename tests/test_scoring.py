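"""Phenotype component rules, threshold derivation and state classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from frailtrans.scoring import (
    ThresholdSet, classify_state, derive_thresholds, flag_exhaustion,
    flag_low_activity, flag_slowness, flag_weakness, flag_weight_loss,
    score_cohort, summarize_grip, summarize_walk, FLAG_COLUMNS,
)
from frailtrans.states import ROBUST, PREFRAIL, FRAIL

from conftest import quantile_oracle, make_measurement_cohort


NA = float("nan")


@pytest.mark.parametrize("current,at25,expected", [
    (85, 100, 1),      # exactly 15% counts as "at least 15%"
    (86, 100, 0),      # 14% is below the threshold
    (70, 85, 1),       # 15/85 = 17.6%
    (NA, 100, NA),
    (85, NA, NA),
])
def test_weight_loss_rule(current, at25, expected):
    got = flag_weight_loss(current, at25)
    assert got == expected or (np.isnan(got) and np.isnan(expected))


def test_weight_loss_rejects_nonpositive_weight():
    with pytest.raises(ValueError):
        flag_weight_loss(-1, 80)


@pytest.mark.parametrize("answer,expected", [
    ("no", 1), ("yes", 0), ("No", 1), (None, NA),
])
def test_exhaustion_from_energy_item(answer, expected):
    got = flag_exhaustion(answer)
    assert got == expected or (np.isnan(got) and np.isnan(expected))


def test_exhaustion_rejects_garbage():
    with pytest.raises(ValueError):
        flag_exhaustion("maybe")


@pytest.mark.parametrize("trials,expected", [
    ((20, 22, 25, 27), 26.0),       # mean of best side: max(21, 26)
    ((30, 30, 30, 30), 30.0),
    ((NA, NA, 18, 20), 19.0),       # left side has no trials
])
def test_grip_best_side_mean(trials, expected):
    assert summarize_grip(*trials) == pytest.approx(expected)


def test_grip_alternative_max_trial_summary():
    assert summarize_grip(20, 22, 25, 27, method="max_trial") == 27.0
    with pytest.raises(ValueError):
        summarize_grip(20, 22, 25, 27, method="median")


@pytest.mark.parametrize("times,expected", [
    ((5.1, 4.8), 4.8), ((6.0, 6.0), 6.0), ((NA, 7.2), 7.2),
])
def test_walk_best_is_fastest(times, expected):
    assert summarize_walk(*times) == pytest.approx(expected)


def test_walk_rejects_nonpositive():
    with pytest.raises(ValueError):
        summarize_walk(0.0, 4.0)


@pytest.mark.parametrize("score,state", [
    (0, ROBUST), (1, PREFRAIL), (2, PREFRAIL), (3, FRAIL), (5, FRAIL),
])
def test_state_cutpoints(score, state):
    assert classify_state(score) == state


def test_missing_score_refuses_to_classify():
    with pytest.raises(ValueError):
        classify_state(np.nan)


@given(st.lists(st.integers(0, 1), min_size=5, max_size=5))
@settings(derandomize=True, max_examples=64)
def test_classification_is_monotone_in_flags(flags):
    """Adding a component never moves a participant toward robust."""
    order = {ROBUST: 0, PREFRAIL: 1, FRAIL: 2}
    base = order[classify_state(sum(flags))]
    for i in range(5):
        if flags[i] == 0:
            bumped = flags.copy()
            bumped[i] = 1
            assert order[classify_state(sum(bumped))] >= base


# ---------------------------------------------------------------------------
# quintile thresholds against the brute-force oracle
# ---------------------------------------------------------------------------

def _pool_oracle(sizes, min_size):
    """Independent restatement of the documented adjacent-pooling rule."""
    groups = [[i] for i in range(len(sizes))]
    gs = list(sizes)
    while len(groups) > 1 and any(s < min_size for s in gs):
        i = next(k for k, s in enumerate(gs) if s < min_size)
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            j = i - 1 if gs[i - 1] <= gs[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        groups[lo] += groups[hi]
        gs[lo] += gs[hi]
        del groups[hi], gs[hi]
    out = [0] * len(sizes)
    for gid, members in enumerate(groups):
        for mm in members:
            out[mm] = gid
    return out


def _expected_flags(df):
    """Brute-force sort-and-count expectation for all three quintile flags."""
    exp = {}
    pase_cut = quantile_oracle(df["pase_score"], 0.2)
    exp["flag_lowactivity"] = (df["pase_score"] <= pase_cut).astype(float)

    grip = df["grip_left_1"].to_numpy(float)   # trials equal by construction
    walk = df["walk_time_1"].to_numpy(float)
    bmi = df["weight_current"] / (df["height"] / 100) ** 2
    weak = np.empty(len(df))
    slow = np.empty(len(df))
    for g in ("man", "woman"):
        gm = (df["gender"] == g).to_numpy()
        if not gm.any():
            continue
        bounds = [quantile_oracle(bmi[gm], q) for q in (0.25, 0.5, 0.75)]
        quart = np.array([sum(x > b for b in bounds) for x in bmi[gm]])
        sizes = [(quart == q).sum() for q in range(4)]
        gids = _pool_oracle(sizes, 20)
        cuts = {}
        for gid in set(gids):
            pooled = np.concatenate([grip[gm][quart == q] for q in range(4) if gids[q] == gid])
            cuts[gid] = quantile_oracle(pooled, 0.2)
        weak[gm] = [1.0 if grip[gm][i] <= cuts[gids[quart[i]]] else 0.0
                    for i in range(gm.sum())]

        med = float(np.median(df["height"][gm]))
        short = df["height"][gm].to_numpy() <= med
        if min(short.sum(), (~short).sum()) < 20:
            cut_s = cut_t = quantile_oracle(walk[gm], 0.8)
        else:
            cut_s = quantile_oracle(walk[gm][short], 0.8)
            cut_t = quantile_oracle(walk[gm][~short], 0.8)
        slow[gm] = np.where(walk[gm] >= np.where(short, cut_s, cut_t), 1.0, 0.0)
    exp["flag_weakness"] = weak
    exp["flag_slowness"] = slow
    return exp


@pytest.mark.parametrize("n", [50, 173, 800, 2000])
def test_quintile_flags_match_bruteforce_oracle(n, rng):
    df = make_measurement_cohort(n, rng)
    scored = score_cohort(df)
    for col, expected in _expected_flags(df).items():
        np.testing.assert_array_equal(scored[col].to_numpy(float), np.asarray(expected))


def test_flagged_fraction_near_twenty_percent(rng):
    """Distinct values: within each estimation cell the flagged share is ~20%."""
    df = make_measurement_cohort(3000, rng)
    scored = score_cohort(df)
    frac = scored["flag_lowactivity"].mean()
    assert abs(frac - 0.20) <= 1 / len(df) + 1e-12


def test_degenerate_all_equal_pase_flags_everyone(rng):
    df = make_measurement_cohort(100, rng)
    df["pase_score"] = 80.0
    scored = score_cohort(df)
    assert (scored["flag_lowactivity"] == 1).all()


def test_pase_cutoff_counts_exactly_twenty_of_one_hundred(rng):
    df = make_measurement_cohort(100, rng)
    df["pase_score"] = np.arange(1.0, 101.0)
    scored = score_cohort(df)
    assert scored["flag_lowactivity"].sum() == 20


def test_thresholds_are_permutation_invariant(rng):
    df = make_measurement_cohort(300, rng)
    t1 = derive_thresholds(df)
    t2 = derive_thresholds(df.sample(frac=1, random_state=7).reset_index(drop=True))
    assert t1.pase_cutoff == t2.pase_cutoff
    assert t1.grip_cutoff == t2.grip_cutoff
    assert t1.walk_cutoff == t2.walk_cutoff


def test_empty_cohort_raises():
    with pytest.raises(ValueError):
        derive_thresholds(pd.DataFrame(columns=["pase_score"]))


def test_tie_rule_flags_values_at_cutoff():
    thr = ThresholdSet(
        pase_cutoff=64.0,
        bmi_quartile_bounds={"man": (20, 23, 26), "woman": (20, 23, 26)},
        grip_cutoff={(g, q): 25.0 for g in ("man", "woman") for q in range(4)},
        height_median={"man": 160.0, "woman": 150.0},
        walk_cutoff={(g, s): 6.0 for g in ("man", "woman") for s in ("short", "tall")},
    )
    assert flag_low_activity(64.0, thr) == 1
    assert flag_low_activity(64.01, thr) == 0
    assert flag_weakness(25.0, "man", 22.0, thr) == 1
    assert flag_weakness(25.5, "man", 22.0, thr) == 0
    assert flag_slowness(6.0, "woman", 148.0, thr) == 1
    assert flag_slowness(5.99, "woman", 148.0, thr) == 0
    # out-of-range BMI falls into the nearest boundary quartile, not an error
    assert flag_weakness(25.0, "man", 55.0, thr) == 1


def test_score_cohort_missing_inputs_propagate(rng):
    df = make_measurement_cohort(60, rng)
    df.loc[0, "pase_score"] = np.nan
    df.loc[1, "gds_energy"] = None
    scored = score_cohort(df)
    assert np.isnan(scored.loc[0, "flag_lowactivity"])
    assert np.isnan(scored.loc[0, "frailty_score"])
    assert scored.loc[0, "frailty_state"] is None
    assert np.isnan(scored.loc[1, "flag_exhaustion"])
    # rows with complete inputs still classify
    assert scored["frailty_state"].notna().sum() >= 58


def test_threshold_set_roundtrips_through_dict(rng):
    t = derive_thresholds(make_measurement_cohort(200, rng))
    t2 = ThresholdSet.from_dict(t.to_dict())
    assert t2.pase_cutoff == t.pase_cutoff
    assert t2.grip_cutoff == t.grip_cutoff
    assert t2.walk_cutoff == t.walk_cutoff
    assert t2.bmi_quartile_bounds == t.bmi_quartile_bounds
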