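"""Synthetic cohort generator: round trips, transitions, attrition, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frailtrans.simulate import (
    ConfigurationError, ExposureEffect, GeneratorConfig, draw_component_flags,
    generate_baseline, generate_followup, inject_missingness,
    make_components_for_state, reference_thresholds,
)
from frailtrans.scoring import score_cohort
from frailtrans.states import STATES, ROBUST, PREFRAIL, FRAIL
from frailtrans.transitions import classify_transition


def test_empty_cohort():
    df = generate_baseline(GeneratorConfig(n_baseline=0))
    assert len(df) == 0


def test_invalid_config_names_field():
    with pytest.raises(ConfigurationError, match="attrition_rate"):
        GeneratorConfig(attrition_rate=1.0).validate()
    with pytest.raises(ConfigurationError, match="state_probs"):
        GeneratorConfig(state_probs=(0.5, 0.2, 0.2)).validate()
    with pytest.raises(ConfigurationError, match="n_eb"):
        GeneratorConfig(n_eb=300).validate()
    with pytest.raises(ConfigurationError, match="missing_rates"):
        GeneratorConfig(missing_rates={"pase_score": 1.0}).validate()


def test_degenerate_distribution_all_robust():
    cfg = GeneratorConfig(n_baseline=1000, state_probs=(1.0, 0.0, 0.0), seed=2)
    df = generate_baseline(cfg)
    scored = score_cohort(df, reference_thresholds(cfg))
    assert (scored["frailty_score"] == 0).all()
    assert (scored["frailty_state"] == ROBUST).all()


def test_state_mode_roundtrip_is_exact_per_record():
    cfg = GeneratorConfig(n_baseline=2324, seed=11)
    df = generate_baseline(cfg)
    scored = score_cohort(df, reference_thresholds(cfg))
    assert (scored["frailty_state"] == df["latent_state"]).all()


def test_recovered_state_frequencies_match_configured():
    cfg = GeneratorConfig(n_baseline=2324, state_probs=(0.327, 0.579, 0.094), seed=5)
    scored = score_cohort(generate_baseline(cfg), reference_thresholds(cfg))
    freqs = scored["frailty_state"].value_counts(normalize=True)
    for s, p in zip(STATES, (0.327, 0.579, 0.094)):
        assert abs(freqs.get(s, 0.0) - p) < 3.5 * np.sqrt(p * (1 - p) / 2324)


@pytest.mark.parametrize("state,lo,hi", [
    (ROBUST, 0, 0), (PREFRAIL, 1, 2), (FRAIL, 3, 5),
])
def test_component_counts_match_state(state, lo, hi, rng):
    for _ in range(30):
        flags = make_components_for_state(state, rng)
        assert lo <= sum(flags) <= hi


def test_component_weights_bias_which_flags_are_set(rng):
    heavy = (0.01, 0.01, 0.96, 0.01, 0.01)
    flags = draw_component_flags(np.array([PREFRAIL] * 4000, dtype=object), rng, heavy)
    assert flags[:, 2].mean() > 0.9


def test_same_seed_identical_different_seed_not():
    a = generate_baseline(GeneratorConfig(n_baseline=400, seed=9))
    b = generate_baseline(GeneratorConfig(n_baseline=400, seed=9))
    c = generate_baseline(GeneratorConfig(n_baseline=400, seed=10))
    pd.testing.assert_frame_equal(a, b)
    assert not a["pase_score"].equals(c["pase_score"])


def test_attrition_count_matches_rate():
    cfg = GeneratorConfig(n_baseline=2324, attrition_rate=0.202, seed=3)
    base = generate_baseline(cfg)
    fup = generate_followup(base, cfg)
    assert len(fup) == 1855


def test_raw_mode_baseline_rejected_for_followup():
    cfg = GeneratorConfig(n_baseline=100, mode="raw", seed=1)
    base = generate_baseline(cfg)
    with pytest.raises(ConfigurationError):
        generate_followup(base, cfg)


def test_identity_transition_matrix_keeps_states():
    ident = ((1.0, 0, 0), (0, 1.0, 0), (0, 0, 1.0))
    cfg = GeneratorConfig(n_baseline=800, transition_matrix=ident, seed=4)
    base = generate_baseline(cfg)
    fup = generate_followup(base, cfg)
    merged = base.set_index("id").loc[fup["id"]]
    assert (merged["latent_state"].to_numpy() == fup["latent_state"].to_numpy()).all()
    scored = score_cohort(fup, reference_thresholds(cfg))
    assert (scored["frailty_state"].to_numpy() == merged["latent_state"].to_numpy()).all()


def test_followup_row_frequencies_match_multinomial_oracle():
    """Robust-row draws agree with direct multinomial sampling from the row."""
    row = (0.475, 0.496, 0.029)
    cfg = GeneratorConfig(
        n_baseline=10000, state_probs=(1.0, 0.0, 0.0),
        transition_matrix=(row, (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
        attrition_rate=0.0, seed=21)
    fup = generate_followup(generate_baseline(cfg), cfg)
    obs = np.array([(fup["latent_state"] == s).sum() for s in STATES])
    chi2, p = stats.chisquare(obs, np.array(row) / sum(row) * len(fup))[:2]
    assert p > 0.01
    # independent multinomial oracle at the same n lands in the same band
    oracle = np.random.default_rng(77).multinomial(len(fup), np.array(row) / sum(row))
    assert stats.chisquare(oracle, np.array(row) / sum(row) * len(fup))[1] > 0.01


def test_followup_margin_converges_to_stateprobs_times_matrix():
    cfg = GeneratorConfig(n_baseline=50000, attrition_rate=0.0, seed=8)
    base = generate_baseline(cfg)
    fup = generate_followup(base, cfg)
    sp = np.asarray(cfg.state_probs)
    tm = np.asarray(cfg.transition_matrix)
    tm = tm / tm.sum(axis=1, keepdims=True)
    expected = (sp / sp.sum()) @ tm
    obs = np.array([(fup["latent_state"] == s).sum() for s in STATES])
    assert stats.chisquare(obs, expected / expected.sum() * len(fup))[1] > 0.01


def test_null_exposure_effect_leaves_transitions_independent():
    cfg = GeneratorConfig(
        n_baseline=50000, attrition_rate=0.0, seed=13,
        exposure_effects={"low_activity": ExposureEffect(0.3, 0.0, "worsened")})
    base = generate_baseline(cfg)
    fup = generate_followup(base, cfg)
    merged = base.set_index("id").loc[fup["id"]]
    worsened = np.array([
        classify_transition(b, f) == "worsened"
        for b, f in zip(merged["latent_state"], fup["latent_state"])])
    exposed = merged["low_activity"].to_numpy() == 1
    count = np.array([worsened[exposed].sum(), worsened[~exposed].sum()])
    nobs = np.array([exposed.sum(), (~exposed).sum()])
    from statsmodels.stats.proportion import proportions_ztest
    _, p = proportions_ztest(count, nobs)
    assert p > 0.01


def test_exposure_tilt_moves_target_category():
    eff = ExposureEffect(prevalence=0.5, log_or=np.log(3.0), outcome="worsened")
    cfg = GeneratorConfig(n_baseline=30000, attrition_rate=0.0, seed=14,
                          exposure_effects={"x": eff})
    base = generate_baseline(cfg)
    fup = generate_followup(base, cfg)
    merged = base.set_index("id").loc[fup["id"]]
    robust = merged["latent_state"] == ROBUST
    worsened = np.array([
        classify_transition(b, f) != "unchanged" and classify_transition(b, f) == "worsened"
        for b, f in zip(merged["latent_state"], fup["latent_state"])])
    # conditional on baseline-robust, the exposed odds of worsening are ~3x
    exp_m = (merged["x"].to_numpy() == 1) & robust.to_numpy()
    une_m = (merged["x"].to_numpy() == 0) & robust.to_numpy()
    p1, p0 = worsened[exp_m].mean(), worsened[une_m].mean()
    odds_ratio = (p1 / (1 - p1)) / (p0 / (1 - p0))
    assert odds_ratio == pytest.approx(3.0, rel=0.15)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def test_zero_rates_are_a_noop():
    cfg = GeneratorConfig(n_baseline=200, seed=6)
    base = generate_baseline(cfg)
    out = inject_missingness(base, cfg)
    pd.testing.assert_frame_equal(out, base)


def test_marginal_missing_rate_calibrated():
    cfg = GeneratorConfig(n_baseline=10000, seed=6,
                          missing_rates={"pase_score": 0.1})
    out = inject_missingness(generate_baseline(cfg), cfg)
    frac = out["pase_score"].isna().mean()
    assert frac == pytest.approx(0.10, abs=3.5 * np.sqrt(0.1 * 0.9 / 10000))


def test_missingness_is_mar_in_age():
    """Positive age coefficient: records missing PASE are older on average."""
    cfg = GeneratorConfig(n_baseline=10000, seed=16,
                          missing_rates={"pase_score": 0.15},
                          missingness_depends_on=("age",))
    out = inject_missingness(generate_baseline(cfg), cfg)
    miss = out["pase_score"].isna()
    assert out.loc[miss, "age"].mean() > out.loc[~miss, "age"].mean()


def test_drivers_cannot_be_masked():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(missing_rates={"pase_score": 0.1},
                        missingness_depends_on=("pase_score",)).validate()
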