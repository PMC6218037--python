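"""Synthetic two-wave cohort generator.

Emulates a rural ageing cohort drawn by two-stage cluster sampling
(enumeration blocks, then living quarters), with a baseline wave and a
12-month follow-up wave. Two modes:

* **state mode** — each participant carries a latent frailty state drawn from
  a configured distribution; component flags consistent with the state are
  drawn, and raw measurements are synthesised so that the phenotype
  classifier, applied with the generator's reference thresholds, recovers the
  latent state exactly. Follow-up states are drawn from a configured
  row-stochastic transition matrix, optionally tilted by binary exposure
  covariates with configured log-odds-ratios on a transition category.
* **raw mode** — measurements are drawn from gender-parameterised continuous
  distributions (normal for weight and height, lognormal for grip, walk time
  and PASE) with no latent state; states emerge from the cohort-relative
  classifier.

Attrition drops ``round(n * attrition_rate)`` participants uniformly at
random. Missingness is injected missing-at-random: per-field missingness
probability is a logistic function of standardised, always-observed driver
covariates, calibrated so the marginal rate matches the configured rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .states import STATES, ROBUST, PREFRAIL, FRAIL, state_index
from .scoring import ThresholdSet, FLAG_COLUMNS
from .transitions import classify_transition


class ConfigurationError(ValueError):
    """A generator configuration field violates its invariant."""


@dataclass(frozen=True)
class ExposureEffect:
    """A binary exposure tilting the transition draw.

    ``log_or`` is applied to the odds of the ``outcome`` category ("worsened"
    or "improved") within each participant's transition-matrix row, and the
    row is renormalised; a logistic regression of the category indicator on
    the exposure, conditional on baseline state, then recovers ``log_or`` in
    expectation.
    """

    prevalence: float
    log_or: float
    outcome: str = "worsened"


# Table-style defaults: baseline state distribution and weighted row-conditional
# transition proportions of the study population the generator emulates.
DEFAULT_STATE_PROBS = (0.327, 0.579, 0.094)
DEFAULT_TRANSITION_MATRIX = (
    (0.475, 0.496, 0.029),
    (0.281, 0.629, 0.089),
    (0.061, 0.449, 0.489),
)

#: Relative propensity of each component to be among those present
#: (weight loss, exhaustion, low activity, weakness, slowness), proportional
#: to the component prevalences of the emulated cohort.
DEFAULT_COMPONENT_WEIGHTS = (0.086, 0.317, 0.242, 0.227, 0.208)

CHRONIC_DISEASES = (
    "diabetes", "hypertension", "hyperlipidaemia", "cardiovascular",
    "respiratory", "arthritis", "stroke", "cancer", "depression",
)

#: Fields that inject_missingness may mask.
MASKABLE_FIELDS = (
    "weight_current", "weight_at25", "height",
    "grip_left_1", "grip_left_2", "grip_right_1", "grip_right_2",
    "walk_time_1", "walk_time_2", "pase_score", "gds_energy",
    "income_monthly", "dssi_score", "mmse_score",
)


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic cohort.

    Defaults reproduce the emulated study: n=2,324 participants over 156 of
    254 enumeration blocks with 16 living quarters sampled per block,
    baseline states (32.7%, 57.9%, 9.4%), the 12-month weighted transition
    matrix, and 20.2% attrition (469 lost, 1,855 followed).
    """

    n_baseline: int = 2324
    n_eb: int = 156
    total_eb: int = 254
    lq_per_eb: int = 16
    total_lq_per_eb: int = 100
    state_probs: tuple[float, float, float] = DEFAULT_STATE_PROBS
    transition_matrix: tuple = DEFAULT_TRANSITION_MATRIX
    attrition_rate: float = 0.202
    exposure_effects: dict[str, ExposureEffect] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)
    missingness_depends_on: tuple[str, ...] = ("age",)
    seed: int = 0
    mode: str = "state"
    component_weights: tuple[float, ...] = DEFAULT_COMPONENT_WEIGHTS
    #: If True, attrition probability rises with baseline frailty severity.
    state_dependent_attrition: bool = False
    #: Custom reference ThresholdSet for state-mode measurement synthesis.
    reference: ThresholdSet | None = None

    def validate(self) -> None:
        if self.n_baseline < 0:
            raise ConfigurationError("n_baseline must be nonnegative")
        if self.n_eb > self.total_eb:
            raise ConfigurationError("n_eb exceeds total_eb")
        if self.lq_per_eb > self.total_lq_per_eb:
            raise ConfigurationError("lq_per_eb exceeds total_lq_per_eb")
        # printed-table probabilities carry rounding; allow slack and renormalise on use
        sp = np.asarray(self.state_probs, dtype=float)
        if sp.shape != (3,) or (sp < 0).any() or abs(sp.sum() - 1) > 5e-3:
            raise ConfigurationError("state_probs must be a nonnegative triple summing to 1")
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (3, 3) or (tm < 0).any() or np.abs(tm.sum(axis=1) - 1).max() > 5e-3:
            raise ConfigurationError("transition_matrix rows must be nonnegative and sum to 1")
        if not (0 <= self.attrition_rate < 1):
            raise ConfigurationError("attrition_rate must be in [0, 1)")
        for name, rate in self.missing_rates.items():
            if not (0 <= rate < 1):
                raise ConfigurationError(f"missing_rates[{name!r}] must be in [0, 1)")
            if name in self.missingness_depends_on:
                raise ConfigurationError(
                    f"missingness driver {name!r} cannot itself be made missing")
            if name not in MASKABLE_FIELDS:
                raise ConfigurationError(f"missing_rates names unknown field {name!r}")
        for name, eff in self.exposure_effects.items():
            if not (0 < eff.prevalence < 1):
                raise ConfigurationError(f"exposure {name!r} prevalence must be in (0, 1)")
            if eff.outcome not in ("worsened", "improved"):
                raise ConfigurationError(f"exposure {name!r} outcome must be worsened/improved")
        if self.mode not in ("state", "raw"):
            raise ConfigurationError("mode must be 'state' or 'raw'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reference"] = self.reference.to_dict() if self.reference else None
        d["exposure_effects"] = {k: asdict(v) for k, v in self.exposure_effects.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if d.get("reference"):
            d["reference"] = ThresholdSet.from_dict(d["reference"])
        if "exposure_effects" in d:
            d["exposure_effects"] = {
                k: v if isinstance(v, ExposureEffect) else ExposureEffect(**v)
                for k, v in d["exposure_effects"].items()}
        for tup_field in ("state_probs", "component_weights", "missingness_depends_on"):
            if tup_field in d and d[tup_field] is not None:
                d[tup_field] = tuple(d[tup_field])
        if "transition_matrix" in d:
            d["transition_matrix"] = tuple(tuple(r) for r in d["transition_matrix"])
        return cls(**d)


def reference_thresholds(config: GeneratorConfig | None = None) -> ThresholdSet:
    """The fixed reference cut-offs that state-mode measurements are built around.

    Values are plausible for a rural South-East-Asian cohort aged 60+ (PASE
    around 60 at the 20th percentile; grip cut-offs rising with BMI quartile;
    4-m walk 80th percentiles near 6 s). State-mode cohorts must be classified
    against these frozen thresholds to recover their latent states.
    """
    if config is not None and config.reference is not None:
        return config.reference
    return ThresholdSet(
        pase_cutoff=60.0,
        bmi_quartile_bounds={"man": (20.5, 23.0, 25.5), "woman": (21.0, 24.0, 27.0)},
        grip_cutoff={
            ("man", 0): 24.0, ("man", 1): 26.0, ("man", 2): 28.0, ("man", 3): 30.0,
            ("woman", 0): 14.0, ("woman", 1): 16.0, ("woman", 2): 17.0, ("woman", 3): 18.0,
        },
        height_median={"man": 163.0, "woman": 151.0},
        walk_cutoff={
            ("man", "short"): 6.0, ("man", "tall"): 5.5,
            ("woman", "short"): 6.5, ("woman", "tall"): 6.0,
        },
        derived_from={"wave": "generator-reference"},
    )


# ---------------------------------------------------------------------------
# component flags from latent state
# ---------------------------------------------------------------------------

def make_components_for_state(state: str, rng: np.random.Generator,
                              weights: Sequence[float] = DEFAULT_COMPONENT_WEIGHTS):
    """Draw a 5-bit component vector consistent with a latent state.

    The number of present components is 0 (robust), uniform on {1, 2}
    (pre-frail) or uniform on {3, 4, 5} (frail); which components are present
    is weighted sampling without replacement proportional to ``weights``.
    """
    flags = draw_component_flags(np.array([state], dtype=object), rng, weights)
    return tuple(int(x) for x in flags[0])


def draw_component_flags(states, rng: np.random.Generator,
                         weights: Sequence[float] = DEFAULT_COMPONENT_WEIGHTS):
    """Vectorised component draw: (n, 5) 0/1 array consistent with each state."""
    states = np.asarray(states, dtype=object)
    n = states.size
    counts = np.zeros(n, dtype=int)
    pre = states == PREFRAIL
    fra = states == FRAIL
    counts[pre] = rng.integers(1, 3, size=int(pre.sum()))
    counts[fra] = rng.integers(3, 6, size=int(fra.sum()))
    w = np.asarray(weights, dtype=float)
    if w.shape != (5,) or (w <= 0).any():
        raise ConfigurationError("component_weights must be 5 positive values")
    # Weighted sampling without replacement via Gumbel-top-k keys.
    keys = np.log(w)[None, :] + rng.gumbel(size=(n, 5))
    order = np.argsort(-keys, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(5)[None, :].repeat(n, axis=0), axis=1)
    return (ranks < counts[:, None]).astype(int)


# ---------------------------------------------------------------------------
# measurement synthesis
# ---------------------------------------------------------------------------

def _demographics(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Demographic and covariate fields with margins matching the emulated cohort."""
    gender = np.where(rng.random(n) < 0.621, "woman", "man").astype(object)
    band = rng.choice(3, size=n, p=(0.482, 0.387, 0.131))
    age = np.select(
        [band == 0, band == 1, band == 2],
        [rng.uniform(60, 70, n), rng.uniform(70, 80, n), rng.uniform(80, 95, n)],
    ).round(1)
    ethnicity = rng.choice(
        ["malay", "chinese", "indian", "other"], size=n, p=(0.956, 0.018, 0.020, 0.006))
    marital = rng.choice(
        ["married", "divorced", "widowed", "single"], size=n, p=(0.624, 0.022, 0.334, 0.020))
    education = rng.choice(
        ["none", "primary", "secondary", "tertiary"], size=n, p=(0.145, 0.615, 0.217, 0.023))
    living = rng.choice(["with_others", "alone"], size=n, p=(0.875, 0.125))
    inc_band = rng.choice(3, size=n, p=(0.659, 0.308, 0.033))
    income = np.select(
        [inc_band == 0, inc_band == 1, inc_band == 2],
        [rng.uniform(100, 1000, n), rng.uniform(1000, 2500, n), rng.uniform(2500, 8000, n)],
    ).round(0)
    dssi = np.clip(np.round(rng.normal(23, 4, n)), 11, 33).astype(int)
    mmse = np.clip(np.round(rng.normal(23.5, 4.5, n)), 9, 30).astype(int)
    n_dis = rng.choice([0, 1, 2, 3, 4], size=n, p=(0.315, 0.226, 0.259, 0.140, 0.060))
    perm = np.argsort(rng.random((n, len(CHRONIC_DISEASES))), axis=1)
    diseases = [";".join(CHRONIC_DISEASES[j] for j in perm[i, :n_dis[i]]) for i in range(n)]
    return pd.DataFrame({
        "age": age, "gender": gender, "ethnicity": ethnicity,
        "marital_status": marital, "education_level": education,
        "living_arrangement": living, "income_monthly": income,
        "dssi_score": dssi.astype(float), "mmse_score": mmse.astype(float),
        "chronic_diseases": diseases,
    })


def _measurements_for_flags(demo: pd.DataFrame, flags: np.ndarray,
                            thr: ThresholdSet, rng: np.random.Generator) -> pd.DataFrame:
    """Raw measurements guaranteed to reproduce ``flags`` under ``thr``.

    Flagged quintile components land strictly on the flagged side of their
    stratum cut-off (inclusive side for the boundary-including rule);
    unflagged ones land strictly on the other side.
    """
    n = len(demo)
    gender = demo["gender"].to_numpy(dtype=object)
    man = gender == "man"

    height = np.where(man, rng.normal(163, 6, n), rng.normal(151, 6, n)).round(1)
    height = np.clip(height, 135, 190)
    weight = np.where(man, rng.normal(62, 9, n), rng.normal(55, 9, n)).round(1)
    weight = np.clip(weight, 32, 110)

    # weight loss: ratio (w25 - cur)/w25; margins absorb the 0.1-kg rounding
    wl = flags[:, 0] == 1
    ratio = np.where(wl, rng.uniform(0.153, 0.30, n), rng.uniform(-0.10, 0.147, n))
    weight_at25 = (weight / (1 - ratio)).round(1)

    gds = np.where(flags[:, 1] == 1, "no", "yes").astype(object)

    low = flags[:, 2] == 1
    pase = np.where(low,
                    rng.uniform(0.15, 1.0, n) * thr.pase_cutoff,
                    thr.pase_cutoff * (1.0 + rng.uniform(0.02, 2.0, n))).round(1)

    bmi = weight / (height / 100.0) ** 2
    grip_cut = np.empty(n)
    for g in ("man", "woman"):
        m = gender == g
        if m.any():
            quart = thr.bmi_quartile(g, bmi[m])
            grip_cut[m] = [thr.grip_cutoff[(g, int(q))] for q in np.atleast_1d(quart)]
    weak = flags[:, 3] == 1
    best_mean = np.where(weak,
                         grip_cut * rng.uniform(0.35, 0.99, n),
                         grip_cut * (1.0 + rng.uniform(0.02, 0.6, n)))
    other_mean = best_mean * rng.uniform(0.80, 1.0, n)
    # best side is strictly the larger mean; trials straddle their side mean
    jit_b = rng.uniform(0.0, 0.1, n) * best_mean
    jit_o = rng.uniform(0.0, 0.1, n) * other_mean
    best_is_right = rng.random(n) < 0.5
    right_mean = np.where(best_is_right, best_mean, other_mean)
    left_mean = np.where(best_is_right, other_mean, best_mean)
    jr = np.where(best_is_right, jit_b, jit_o)
    jl = np.where(best_is_right, jit_o, jit_b)
    grip_right_1 = (right_mean + jr).round(1)
    grip_right_2 = (2 * right_mean - grip_right_1).round(1)
    grip_left_1 = (left_mean + jl).round(1)
    grip_left_2 = (2 * left_mean - grip_left_1).round(1)

    walk_cut = np.empty(n)
    for g in ("man", "woman"):
        m = gender == g
        if m.any():
            strata = np.atleast_1d(thr.height_stratum(g, height[m]))
            walk_cut[m] = [thr.walk_cutoff[(g, s)] for s in strata]
    slow = flags[:, 4] == 1
    best_time = np.where(slow,
                         walk_cut * (1.0 + rng.uniform(0.002, 1.2, n)),
                         walk_cut * rng.uniform(0.35, 0.98, n))
    walk_time_1 = best_time
    walk_time_2 = best_time * (1.0 + rng.uniform(0.0, 0.25, n))

    return pd.DataFrame({
        "weight_current": weight, "weight_at25": weight_at25, "height": height,
        "grip_left_1": grip_left_1, "grip_left_2": grip_left_2,
        "grip_right_1": grip_right_1, "grip_right_2": grip_right_2,
        "walk_time_1": np.round(walk_time_1, 2), "walk_time_2": np.round(walk_time_2, 2),
        "pase_score": pase, "gds_energy": gds,
    })


def _measurements_raw(demo: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Raw-mode measurements: gender-parameterised continuous distributions."""
    n = len(demo)
    gender = demo["gender"].to_numpy(dtype=object)
    man = gender == "man"
    age = demo["age"].to_numpy(dtype=float)
    age_z = (age - 70.0) / 8.0

    height = np.where(man, rng.normal(163, 6, n), rng.normal(151, 6, n)).round(1)
    weight = np.where(man, rng.normal(62, 9, n), rng.normal(55, 9, n)).round(1)
    weight = np.clip(weight, 32, 110)
    ratio = np.clip(rng.normal(0.03, 0.10, n), -0.25, 0.45)
    weight_at25 = (weight / (1 - ratio)).round(1)

    strength = np.where(man,
                        np.exp(rng.normal(np.log(28), 0.25, n)),
                        np.exp(rng.normal(np.log(17), 0.25, n)))
    strength = strength * np.exp(-0.12 * age_z)
    side = strength[:, None] * np.exp(rng.normal(0, 0.05, (n, 2)))
    trial = np.repeat(side, 2, axis=1) * np.exp(rng.normal(0, 0.03, (n, 4)))
    walk = np.exp(rng.normal(np.log(4.6), 0.28, (n, 2))) * np.exp(0.15 * age_z)[:, None]
    pase = np.exp(rng.normal(np.log(95), 0.55, n)) * np.exp(-0.10 * age_z)
    gds = np.where(rng.random(n) < 0.317, "no", "yes").astype(object)

    return pd.DataFrame({
        "weight_current": weight, "weight_at25": weight_at25, "height": height,
        "grip_left_1": trial[:, 0].round(1), "grip_left_2": trial[:, 1].round(1),
        "grip_right_1": trial[:, 2].round(1), "grip_right_2": trial[:, 3].round(1),
        "walk_time_1": walk[:, 0].round(2), "walk_time_2": walk[:, 1].round(2),
        "pase_score": pase.round(1), "gds_energy": gds,
    })


# ---------------------------------------------------------------------------
# wave generation
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "id", "wave", "eb_id", "lq_id", "age", "gender", "ethnicity",
    "marital_status", "education_level", "living_arrangement", "income_monthly",
    "dssi_score", "mmse_score", "chronic_diseases",
    "weight_current", "weight_at25", "height",
    "grip_left_1", "grip_left_2", "grip_right_1", "grip_right_2",
    "walk_time_1", "walk_time_2", "pase_score", "gds_energy",
]


def generate_baseline(config: GeneratorConfig, rng: np.random.Generator | None = None
                      ) -> pd.DataFrame:
    """Generate the baseline wave.

    In state mode the returned frame carries a ``latent_state`` column and
    measurements consistent with it under ``reference_thresholds(config)``;
    in raw mode there is no latent state. Identical config and seed give
    byte-identical output.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_baseline

    eb_ids = np.sort(rng.choice(config.total_eb, size=config.n_eb, replace=False)) + 1
    lq_ids = np.arange(1, config.lq_per_eb + 1)
    cell_eb = rng.integers(0, config.n_eb, size=n)
    cell_lq = rng.integers(0, config.lq_per_eb, size=n)

    demo = _demographics(n, rng)
    base = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "wave": "baseline",
        "eb_id": eb_ids[cell_eb] if n else np.array([], dtype=int),
        "lq_id": lq_ids[cell_lq] if n else np.array([], dtype=int),
    })
    out = pd.concat([base, demo], axis=1)

    if config.mode == "state":
        sp = np.asarray(config.state_probs, dtype=float)
        states = rng.choice(np.array(STATES, dtype=object), size=n, p=sp / sp.sum())
        flags = draw_component_flags(states, rng, config.component_weights)
        meas = _measurements_for_flags(demo, flags, reference_thresholds(config), rng)
        out = pd.concat([out, meas], axis=1)
        out["latent_state"] = states
    else:
        meas = _measurements_raw(demo, rng)
        out = pd.concat([out, meas], axis=1)

    for name, eff in config.exposure_effects.items():
        out[name] = (rng.random(n) < eff.prevalence).astype(int)

    return out[COHORT_COLUMNS + [c for c in out.columns if c not in COHORT_COLUMNS]]


def _tilt_row(row: np.ndarray, baseline_state: str, outcome: str, log_or: float
              ) -> np.ndarray:
    """Apply a log-odds-ratio to the probability mass of one transition category."""
    cats = np.array([classify_transition(baseline_state, s) for s in STATES], dtype=object)
    mask = cats == outcome
    q = row[mask].sum()
    if q <= 0 or q >= 1 or log_or == 0:
        return row
    odds = np.exp(log_or) * q / (1 - q)
    q_new = odds / (1 + odds)
    out = row.copy()
    out[mask] *= q_new / q
    out[~mask] *= (1 - q_new) / (1 - q)
    return out


def generate_followup(baseline: pd.DataFrame, config: GeneratorConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the follow-up wave from a state-mode baseline.

    Drops ``round(n * attrition_rate)`` records uniformly at random (or
    severity-tilted when ``state_dependent_attrition``), draws each survivor's
    follow-up state from its baseline state's transition-matrix row (tilted by
    any configured exposure effects), and regenerates measurements consistent
    with the new state.
    """
    config.validate()
    if "latent_state" not in baseline.columns:
        raise ConfigurationError(
            "follow-up generation requires a state-mode baseline (latent_state column)")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))

    n = len(baseline)
    n_drop = int(round(n * config.attrition_rate))
    if config.state_dependent_attrition and n_drop > 0:
        sev = baseline["latent_state"].map(state_index).to_numpy(dtype=float)
        w = 1.0 + sev  # frail twice as likely to drop out as robust
        p = w / w.sum()
        drop = rng.choice(n, size=n_drop, replace=False, p=p)
    else:
        drop = rng.choice(n, size=n_drop, replace=False) if n_drop else np.array([], dtype=int)
    keep = np.setdiff1d(np.arange(n), drop)
    surv = baseline.iloc[keep].reset_index(drop=True)

    tm = np.asarray(config.transition_matrix, dtype=float)
    tm = tm / tm.sum(axis=1, keepdims=True)
    m = len(surv)
    u = rng.random(m)
    new_states = np.empty(m, dtype=object)
    base_states = surv["latent_state"].to_numpy(dtype=object)
    base_idx = np.array([state_index(s) for s in base_states], dtype=int)
    if not config.exposure_effects:
        cum = np.cumsum(tm, axis=1)
        picks = (u[:, None] * cum[base_idx, -1:] > cum[base_idx]).sum(axis=1)
        new_states[:] = np.array(STATES, dtype=object)[picks]
    else:
        exp_cols = {name: surv[name].to_numpy() for name in config.exposure_effects}
        # distinct (baseline state, exposure pattern) combinations share a row
        row_cache: dict[tuple, np.ndarray] = {}
        for i in range(m):
            key = (base_idx[i],) + tuple(int(exp_cols[nm][i]) for nm in config.exposure_effects)
            row = row_cache.get(key)
            if row is None:
                row = tm[base_idx[i]].copy()
                for nm, eff in config.exposure_effects.items():
                    if key[1 + list(config.exposure_effects).index(nm)] == 1:
                        row = _tilt_row(row, base_states[i], eff.outcome, eff.log_or)
                row_cache[key] = row
            new_states[i] = STATES[int(np.searchsorted(np.cumsum(row), u[i] * row.sum()))]

    flags = draw_component_flags(new_states, rng, config.component_weights)
    meas = _measurements_for_flags(
        pd.DataFrame({"gender": surv["gender"]}), flags, reference_thresholds(config), rng)

    out = surv.copy()
    out["wave"] = "followup"
    out["age"] = surv["age"] + 1.0
    for col in meas.columns:
        out[col] = meas[col]
    out["latent_state"] = new_states
    return out


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def _calibrate_intercept(eta: np.ndarray, rate: float) -> float:
    f = lambda a: expit(a + eta).mean() - rate
    return brentq(f, -40.0, 40.0)


def inject_missingness(records: pd.DataFrame, config: GeneratorConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Mask fields missing-at-random at the configured marginal rates.

    Per field, the missingness probability is ``expit(a + 0.5 * sum(z))``
    over standardised driver covariates, with ``a`` calibrated so the mean
    probability equals the field's configured rate. Drivers are never masked.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    if not config.missing_rates:
        return records.copy()
    out = records.copy()
    eta = np.zeros(len(out))
    for drv in config.missingness_depends_on:
        z = out[drv].to_numpy(dtype=float)
        sd = z.std()
        eta = eta + 0.5 * ((z - z.mean()) / sd if sd > 0 else 0.0)
    for name, rate in config.missing_rates.items():
        if rate == 0:
            continue
        a = _calibrate_intercept(eta, rate)
        mask = rng.random(len(out)) < expit(a + eta)
        if out[name].dtype == object:
            out.loc[mask, name] = None
        else:
            out.loc[mask, name] = np.nan
    return out


# ---------------------------------------------------------------------------
# direct exposure-outcome simulation (marginal OR recovery experiments)
# ---------------------------------------------------------------------------

def simulate_binary_exposure_outcome(n: int, prevalence: float, marginal: float,
                                     odds_ratio: float, rng: np.random.Generator
                                     ) -> pd.DataFrame:
    """Binary exposure and transition-outcome pair with an exact marginal OR.

    The exposure is Bernoulli(``prevalence``); the outcome is Bernoulli from a
    logistic model whose log-OR is ``log(odds_ratio)`` and whose intercept is
    solved so the marginal outcome proportion equals ``marginal``. Used for
    odds-ratio recovery experiments against printed univariate estimates.
    """
    beta = np.log(odds_ratio)
    f = lambda a: prevalence * expit(a + beta) + (1 - prevalence) * expit(a) - marginal
    a = brentq(f, -30.0, 30.0)
    x = (rng.random(n) < prevalence).astype(int)
    y = (rng.random(n) < expit(a + beta * x)).astype(int)
    return pd.DataFrame({"exposure": x, "outcome": y})
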