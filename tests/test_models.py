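"""Logistic fits, risk sets, univariate screening and backward elimination."""

import numpy as np
import pandas as pd
import pytest

from frailtrans.models import (
    build_multivariate, define_risk_sets, fit_logistic, univariate_screen,
)
from frailtrans.simulate import simulate_binary_exposure_outcome
from frailtrans.states import ROBUST, PREFRAIL, FRAIL
from frailtrans.transitions import IMPROVED, WORSENED, UNCHANGED


def _two_by_two(a, b, c, d):
    """exposure=1: a events / b non-events; exposure=0: c / d."""
    return pd.DataFrame({
        "x": [1] * (a + b) + [0] * (c + d),
        "y": [1] * a + [0] * b + [1] * c + [0] * d,
    })


def test_logistic_matches_crossproduct_oracle():
    df = _two_by_two(30, 70, 10, 90)
    res = fit_logistic(df, "y", ["x"])
    assert res.term("x").odds_ratio == pytest.approx(30 * 90 / (70 * 10), abs=1e-6)
    assert res.term("x").reference == "0"


def test_logistic_crossproduct_on_random_layouts(rng):
    for _ in range(50):
        a, b, c, d = rng.integers(3, 60, size=4)
        df = _two_by_two(a, b, c, d)
        res = fit_logistic(df, "y", ["x"])
        assert res.term("x").odds_ratio == pytest.approx(a * d / (b * c), abs=1e-6)


def test_intercept_only_recovers_marginal_logit():
    df = pd.DataFrame({"y": [1] * 25 + [0] * 75})
    res = fit_logistic(df, "y")
    assert res.intercept == pytest.approx(np.log(1 / 3), abs=1e-6)


def test_null_exposure_or_near_one(rng):
    df = simulate_binary_exposure_outcome(20000, 0.3, 0.25, 1.0, rng)
    res = fit_logistic(df, "outcome", ["exposure"])
    assert res.term("exposure").odds_ratio == pytest.approx(1.0, abs=0.15)


def test_cluster_robust_se_widens_under_cluster_effects(rng):
    n_cl, per = 40, 25
    u = np.repeat(rng.normal(0, 0.6, n_cl), per)
    # cluster-level exposure: clustering genuinely inflates its variance
    x = np.repeat((rng.random(n_cl) < 0.5).astype(int), per)
    from scipy.special import expit
    y = (rng.random(n_cl * per) < expit(-0.5 + 0.4 * x + u)).astype(int)
    df = pd.DataFrame({"y": y, "x": x, "cl": np.repeat(np.arange(n_cl), per)})
    plain = fit_logistic(df, "y", ["x"]).term("x")
    robust = fit_logistic(df, "y", ["x"], cluster="cl").term("x")
    assert robust.coef == pytest.approx(plain.coef)
    assert robust.se > plain.se


def test_single_class_outcome_is_an_error():
    with pytest.raises(ValueError):
        fit_logistic(pd.DataFrame({"y": [1, 1, 1], "x": [0, 1, 0]}), "y", ["x"])


def test_separation_flagged_not_raised():
    df = pd.DataFrame({"y": [0] * 20 + [1] * 20, "x": [0] * 20 + [1] * 20})
    res = fit_logistic(df, "y", ["x"])
    assert res.separation


def test_aliased_covariate_dropped_deterministically():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 2, 200)
    y = (rng.random(200) < 0.4).astype(int)
    df = pd.DataFrame({"y": y, "gender": np.where(g == 1, "woman", "man"),
                       "copy": np.where(g == 1, "late", "early")})
    res = fit_logistic(df, "y", ["gender", "copy"])
    assert res.dropped_collinear == ["copy=late"]
    assert {t.variable for t in res.terms} == {"gender"}


def test_parameter_recovery_and_ci_coverage(rng):
    """Configured log-OR is recovered unbiasedly with ~95% CI coverage."""
    beta = np.log(2.0)
    hits, coefs = 0, []
    reps = 200
    for _ in range(reps):
        df = simulate_binary_exposure_outcome(10000, 0.3, 0.25, 2.0, rng)
        t = fit_logistic(df, "outcome", ["exposure"]).term("exposure")
        coefs.append(t.coef)
        hits += t.ci_low <= 2.0 <= t.ci_high
    assert np.mean(coefs) == pytest.approx(beta, rel=0.05)
    assert 0.93 <= hits / reps <= 0.97


# ---------------------------------------------------------------------------
# risk sets and model building
# ---------------------------------------------------------------------------

def _transition_frame():
    return pd.DataFrame({
        "baseline_state": [ROBUST, PREFRAIL, FRAIL, ROBUST, PREFRAIL],
        "category": [WORSENED, IMPROVED, IMPROVED, UNCHANGED, WORSENED],
    })


def test_risk_set_membership():
    worsened, improved = define_risk_sets(_transition_frame())
    # frail participants cannot worsen further; robust cannot improve
    assert (worsened["baseline_state"] != FRAIL).all()
    assert (improved["baseline_state"] != ROBUST).all()
    # prefrail participants sit in both sets
    assert (worsened["baseline_state"] == PREFRAIL).sum() == 2
    assert (improved["baseline_state"] == PREFRAIL).sum() == 2
    assert worsened["outcome"].tolist() == [1, 0, 0, 1]
    assert improved["outcome"].tolist() == [1, 1, 0]


def test_risk_set_alternative_denominator():
    worsened, improved = define_risk_sets(_transition_frame(), include_all=True)
    assert len(worsened) == len(improved) == 5


def test_screen_thresholds_are_sharp(rng):
    n = 400
    df = pd.DataFrame({
        "y": (rng.random(n) < 0.3).astype(int),
        "a": rng.choice(["u", "v"], n), "b": rng.choice(["u", "v"], n),
    })
    everything, _ = univariate_screen(df, "y", ["a", "b"], threshold=1.0)
    nothing, _ = univariate_screen(df, "y", ["a", "b"], threshold=0.0)
    assert everything == ["a", "b"]
    assert nothing == []


def test_screen_retention_rule(rng):
    n = 3000
    x = (rng.random(n) < 0.4).astype(int)
    y = (rng.random(n) < 0.2 + 0.15 * x).astype(int)
    df = pd.DataFrame({"y": y, "strong": np.where(x == 1, "yes", "no"),
                       "noise": rng.choice(["p", "q"], n)})
    selected, log = univariate_screen(df, "y", ["strong", "noise"])
    assert "strong" in selected
    assert set(log["variable"]) == {"strong", "noise"}


def test_multivariate_keeps_forced_adjusters(rng):
    n = 2000
    x = (rng.random(n) < 0.3).astype(int)
    y = (rng.random(n) < 0.15 + 0.25 * x).astype(int)
    df = pd.DataFrame({
        "y": y,
        "exposure": np.where(x == 1, "low", "active"),
        "age_group": rng.choice(["60-69", "70-79", "80+"], n),
        "gender": rng.choice(["man", "woman"], n),
        "junk": rng.choice(["a", "b"], n),
    })
    selected, _ = univariate_screen(df, "y", ["exposure", "junk"])
    res = build_multivariate(df, "y", selected,
                             references={"exposure": "active"})
    vars_in = {t.variable for t in res.terms}
    assert {"age_group", "gender", "exposure"} <= vars_in
    assert "junk" not in vars_in or res.variable_p("junk") < 0.05
    assert res.term("exposure").odds_ratio > 1.5


def test_all_null_candidates_leave_adjustment_only_model(rng):
    n = 4000
    df = pd.DataFrame({
        "y": (rng.random(n) < 0.3).astype(int),
        "age_group": rng.choice(["60-69", "70-79"], n),
        "gender": rng.choice(["man", "woman"], n),
        "n1": rng.choice(["a", "b"], n),
        "n2": rng.choice(["a", "b"], n),
    })
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)  # adjustment-only fallback
        res = build_multivariate(df, "y", ["n1", "n2"])
    vars_in = {t.variable for t in res.terms}
    for v in vars_in - {"age_group", "gender"}:
        assert res.variable_p(v) < 0.05  # survivors must have earned their place
    assert {"age_group", "gender"} <= vars_in
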