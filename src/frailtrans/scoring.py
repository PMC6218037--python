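"""Phenotype scoring: cohort-relative thresholds and the five-component classifier.

The physical-frailty phenotype comprises five binary components:

* weight loss — current weight at least 15% below self-reported weight at 25;
* exhaustion — answering "no" to the single energy item ("Do you feel full of
  energy?");
* low activity — PASE score in the lowest quintile of the cohort;
* weakness — best-side mean grip strength in the lowest quintile, stratified
  by gender and within-gender BMI quartile;
* slowness — best (fastest) 4-m walk time in the slowest quintile, stratified
  by gender and height (at/below vs above the gender median).

Quintile cut-offs are empirical 20th/80th percentiles with linear
interpolation; the flag rule is inclusive at the boundary (a value exactly at
the cut-off is flagged), so the degenerate all-tied cell is well defined.
Scores 0 / 1–2 / >=3 map to robust / pre-frail / frail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .states import ROBUST, PREFRAIL, FRAIL

GENDERS = ("man", "woman")

#: Strata used for the walk-time cut-off: at/below vs above the gender median height.
HEIGHT_STRATA = ("short", "tall")

#: Smallest stratification cell allowed when estimating a quintile threshold.
#: Grip cells below this are pooled with the adjacent BMI quartile; walk cells
#: collapse to a gender-wide cut-off.
MIN_STRATUM_SIZE = 20


class ThresholdDerivationError(ValueError):
    """A stratification cell is empty even after the pooling rule."""


@dataclass
class ThresholdSet:
    """Cohort-derived (or reference) cut-offs for the three quintile components.

    Attributes
    ----------
    pase_cutoff:
        Cohort-wide 20th percentile of the PASE score; values at or below it
        flag low activity.
    bmi_quartile_bounds:
        Per-gender (q25, q50, q75) BMI bounds in kg/m^2 used to place a
        participant in a BMI quartile (0-3); out-of-range values fall in the
        nearest boundary quartile.
    grip_cutoff:
        20th percentile of best-side grip (kgf) per (gender, BMI quartile).
    height_median:
        Per-gender median height (cm) splitting the walk strata.
    walk_cutoff:
        80th percentile of best walk time (s) per (gender, height stratum);
        times at or above it flag slowness.
    derived_from:
        Provenance: wave label and per-stratum sample sizes.
    """

    pase_cutoff: float
    bmi_quartile_bounds: dict[str, tuple[float, float, float]]
    grip_cutoff: dict[tuple[str, int], float]
    height_median: dict[str, float]
    walk_cutoff: dict[tuple[str, str], float]
    derived_from: dict = field(default_factory=dict)

    def bmi_quartile(self, gender, bmi):
        """Quartile index 0-3 for a BMI value; vectorised over arrays."""
        bounds = np.asarray(self.bmi_quartile_bounds[gender], dtype=float)
        return np.searchsorted(bounds, np.asarray(bmi, dtype=float), side="left")

    def height_stratum(self, gender, height):
        med = self.height_median[gender]
        return np.where(np.asarray(height, dtype=float) <= med, "short", "tall")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grip_cutoff"] = {f"{g}:{q}": v for (g, q), v in self.grip_cutoff.items()}
        d["walk_cutoff"] = {f"{g}:{s}": v for (g, s), v in self.walk_cutoff.items()}
        d["bmi_quartile_bounds"] = {g: list(b) for g, b in self.bmi_quartile_bounds.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThresholdSet":
        grip = {}
        for key, v in d["grip_cutoff"].items():
            g, q = key.split(":")
            grip[(g, int(q))] = float(v)
        walk = {}
        for key, v in d["walk_cutoff"].items():
            g, s = key.split(":")
            walk[(g, s)] = float(v)
        return cls(
            pase_cutoff=float(d["pase_cutoff"]),
            bmi_quartile_bounds={g: tuple(map(float, b)) for g, b in d["bmi_quartile_bounds"].items()},
            grip_cutoff=grip,
            height_median={g: float(v) for g, v in d["height_median"].items()},
            walk_cutoff=walk,
            derived_from=dict(d.get("derived_from", {})),
        )


# ---------------------------------------------------------------------------
# component flag rules
# ---------------------------------------------------------------------------

def _as_float(x):
    return np.asarray(x, dtype=float)


def flag_weight_loss(weight_current, weight_at25):
    """1 if current weight is at least 15% below weight at age 25, else 0.

    Missing (NaN) in either input propagates. Nonpositive weights are invalid.
    """
    cur, w25 = _as_float(weight_current), _as_float(weight_at25)
    if np.any(cur[~np.isnan(cur)] <= 0) or np.any(w25[~np.isnan(w25)] <= 0):
        raise ValueError("weights must be strictly positive")
    with np.errstate(invalid="ignore"):
        loss = (w25 - cur) / w25
        out = np.where(loss >= 0.15, 1.0, 0.0)
    out = np.where(np.isnan(cur) | np.isnan(w25), np.nan, out)
    return out if out.ndim else float(out)


def flag_exhaustion(gds_energy_answer):
    """1 for answering "no" to the energy item, 0 for "yes"; missing propagates."""
    arr = np.asarray(gds_energy_answer, dtype=object)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.full(arr.shape, np.nan)
    for i, v in enumerate(arr.ravel()):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        s = str(v).strip().lower()
        if s == "no":
            out.ravel()[i] = 1.0
        elif s == "yes":
            out.ravel()[i] = 0.0
        elif s in ("", "nan", "na"):
            continue
        else:
            raise ValueError(f"invalid energy answer {v!r}; expected yes/no/missing")
    return float(out[0]) if scalar else out


def summarize_grip(left1, left2=None, right1=None, right2=None,
                   method: str = "mean_best_side"):
    """Grip-strength summary across the four trials (kgf).

    The default reads "mean value of the best side" literally: per side, the
    mean of its available trials, then the larger side mean. The alternative
    ``method="max_trial"`` takes the single largest trial. Within a side,
    missing trials are dropped; a side with no trials is excluded; if neither
    side has a trial the result is missing.
    """
    trials = [_as_float(np.atleast_1d(t)) for t in (left1, left2, right1, right2)]
    for t in trials:
        if np.any(t[~np.isnan(t)] < 0):
            raise ValueError("grip force must be nonnegative")
    if method == "max_trial":
        best = np.fmax.reduce(np.vstack(trials), axis=0)
        return best if best.size > 1 else float(best[0])
    if method != "mean_best_side":
        raise ValueError(f"unknown grip summary method {method!r}")
    left = np.vstack([trials[0], trials[1]])
    right = np.vstack([trials[2], trials[3]])
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # a side with no observed trials is simply excluded; nanmean's
        # empty-slice warning is the expected path, not a problem
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_left = np.nanmean(left, axis=0)
        mean_right = np.nanmean(right, axis=0)
        best = np.fmax(mean_left, mean_right)
    return best if best.size > 1 else float(best[0])


def summarize_walk(time1, time2=None):
    """Best (fastest) 4-m walk time: minimum of available trials (s)."""
    t1, t2 = _as_float(np.atleast_1d(time1)), _as_float(np.atleast_1d(time2))
    for t in (t1, t2):
        if np.any(t[~np.isnan(t)] <= 0):
            raise ValueError("walk time must be strictly positive")
    best = np.fmin(t1, t2)
    return best if best.size > 1 else float(best[0])


def compute_bmi(weight_current, height_cm):
    """BMI in kg/m^2 from weight (kg) and height (cm)."""
    w, h = _as_float(weight_current), _as_float(height_cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        return w / (h / 100.0) ** 2


# ---------------------------------------------------------------------------
# threshold derivation
# ---------------------------------------------------------------------------

def _pool_groups(sizes: list[int], min_size: int) -> list[int]:
    """Deterministic adjacent pooling of ordered groups until all meet min_size.

    Returns a group id per original cell. An undersized cell merges with its
    smaller adjacent neighbour (lower index on ties), repeatedly.
    """
    groups = [[i] for i in range(len(sizes))]
    gsizes = list(sizes)
    while len(groups) > 1:
        under = [i for i, s in enumerate(gsizes) if s < min_size]
        if not under:
            break
        i = under[0]
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            j = i - 1 if gsizes[i - 1] <= gsizes[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        groups[lo] = groups[lo] + groups[hi]
        gsizes[lo] += gsizes[hi]
        del groups[hi], gsizes[hi]
    ids = [0] * len(sizes)
    for gid, members in enumerate(groups):
        for m in members:
            ids[m] = gid
    return ids


def derive_thresholds(cohort: pd.DataFrame, wave_label: str = "baseline",
                      min_stratum_size: int = MIN_STRATUM_SIZE) -> ThresholdSet:
    """Derive the quintile cut-offs from an (observed, unweighted) cohort wave.

    Records missing the relevant measurement are excluded from that
    threshold's estimation only. Grip cells (gender x BMI quartile) below
    ``min_stratum_size`` pool with the adjacent quartile; undersized walk
    strata collapse to a gender-wide cut-off.
    """
    if len(cohort) == 0:
        raise ThresholdDerivationError("cannot derive thresholds from an empty cohort")

    sizes: dict[str, int] = {"wave": wave_label}

    pase = cohort["pase_score"].to_numpy(dtype=float)
    pase = pase[~np.isnan(pase)]
    if pase.size == 0:
        raise ThresholdDerivationError("no observed PASE scores")
    pase_cutoff = float(np.quantile(pase, 0.20))
    sizes["pase_n"] = int(pase.size)

    grip_best = summarize_grip(
        cohort["grip_left_1"], cohort["grip_left_2"],
        cohort["grip_right_1"], cohort["grip_right_2"],
    )
    grip_best = np.atleast_1d(grip_best)
    bmi = compute_bmi(cohort["weight_current"], cohort["height"])
    walk_best = np.atleast_1d(summarize_walk(cohort["walk_time_1"], cohort["walk_time_2"]))
    gender = cohort["gender"].to_numpy(dtype=object)
    height = cohort["height"].to_numpy(dtype=float)

    bmi_bounds: dict[str, tuple[float, float, float]] = {}
    grip_cutoff: dict[tuple[str, int], float] = {}
    height_median: dict[str, float] = {}
    walk_cutoff: dict[tuple[str, str], float] = {}

    for g in GENDERS:
        gmask = gender == g
        if not gmask.any():
            raise ThresholdDerivationError(f"no records for gender {g!r}")

        b = bmi[gmask]
        b_obs = b[~np.isnan(b)]
        if b_obs.size == 0:
            raise ThresholdDerivationError(f"no observed BMI for gender {g!r}")
        bounds = tuple(float(q) for q in np.quantile(b_obs, [0.25, 0.50, 0.75]))
        bmi_bounds[g] = bounds

        ok = gmask & ~np.isnan(bmi) & ~np.isnan(grip_best)
        vals = grip_best[ok]
        qq = np.searchsorted(np.asarray(bounds), bmi[ok], side="left")
        cell_vals = [vals[qq == q] for q in range(4)]
        gids = _pool_groups([v.size for v in cell_vals], min_stratum_size)
        for gid in set(gids):
            pooled = np.concatenate([cell_vals[q] for q in range(4) if gids[q] == gid])
            if pooled.size == 0:
                raise ThresholdDerivationError(
                    f"empty grip stratum for gender {g!r}, pooled quartiles "
                    f"{[q for q in range(4) if gids[q] == gid]}")
            cut = float(np.quantile(pooled, 0.20))
            for q in range(4):
                if gids[q] == gid:
                    grip_cutoff[(g, q)] = cut
                    sizes[f"grip_n_{g}_q{q}"] = int(pooled.size)

        h = height[gmask]
        h_obs = h[~np.isnan(h)]
        if h_obs.size == 0:
            raise ThresholdDerivationError(f"no observed heights for gender {g!r}")
        med = float(np.median(h_obs))
        height_median[g] = med

        ok = gmask & ~np.isnan(height) & ~np.isnan(walk_best)
        short_vals = walk_best[ok & (height <= med)]
        tall_vals = walk_best[ok & (height > med)]
        if min(short_vals.size, tall_vals.size) < min_stratum_size:
            pooled = walk_best[ok]
            if pooled.size == 0:
                raise ThresholdDerivationError(f"empty walk stratum for gender {g!r}")
            cut = float(np.quantile(pooled, 0.80))
            walk_cutoff[(g, "short")] = cut
            walk_cutoff[(g, "tall")] = cut
            sizes[f"walk_n_{g}"] = int(pooled.size)
        else:
            walk_cutoff[(g, "short")] = float(np.quantile(short_vals, 0.80))
            walk_cutoff[(g, "tall")] = float(np.quantile(tall_vals, 0.80))
            sizes[f"walk_n_{g}_short"] = int(short_vals.size)
            sizes[f"walk_n_{g}_tall"] = int(tall_vals.size)

    return ThresholdSet(
        pase_cutoff=pase_cutoff,
        bmi_quartile_bounds=bmi_bounds,
        grip_cutoff=grip_cutoff,
        height_median=height_median,
        walk_cutoff=walk_cutoff,
        derived_from=sizes,
    )


# ---------------------------------------------------------------------------
# threshold-dependent flags and classification
# ---------------------------------------------------------------------------

def flag_low_activity(pase_score, thresholds: ThresholdSet):
    """1 if the PASE score falls at or below the cohort 20th percentile."""
    p = _as_float(pase_score)
    out = np.where(p <= thresholds.pase_cutoff, 1.0, 0.0)
    out = np.where(np.isnan(p), np.nan, out)
    return out if out.ndim else float(out)


def flag_weakness(grip, gender, bmi, thresholds: ThresholdSet):
    """1 if best-side grip is at or below its (gender x BMI-quartile) cut-off."""
    grip = np.atleast_1d(_as_float(grip))
    bmi = np.atleast_1d(_as_float(bmi))
    gender = np.atleast_1d(np.asarray(gender, dtype=object))
    out = np.full(grip.shape, np.nan)
    for g in GENDERS:
        gmask = gender == g
        if not gmask.any():
            continue
        quart = thresholds.bmi_quartile(g, bmi[gmask])
        cuts = np.array([thresholds.grip_cutoff[(g, int(q))] if not np.isnan(bmi[gmask][i]) else np.nan
                         for i, q in enumerate(np.atleast_1d(quart))])
        vals = grip[gmask]
        res = np.where(vals <= cuts, 1.0, 0.0)
        res = np.where(np.isnan(vals) | np.isnan(cuts), np.nan, res)
        out[gmask] = res
    return out if out.size > 1 else float(out[0])


def flag_slowness(best_time, gender, height, thresholds: ThresholdSet):
    """1 if best walk time is at or above its (gender x height-stratum) cut-off."""
    t = np.atleast_1d(_as_float(best_time))
    height = np.atleast_1d(_as_float(height))
    gender = np.atleast_1d(np.asarray(gender, dtype=object))
    out = np.full(t.shape, np.nan)
    for g in GENDERS:
        gmask = gender == g
        if not gmask.any():
            continue
        strata = thresholds.height_stratum(g, height[gmask])
        cuts = np.array([thresholds.walk_cutoff[(g, s)] for s in np.atleast_1d(strata)])
        vals = t[gmask]
        res = np.where(vals >= cuts, 1.0, 0.0)
        res = np.where(np.isnan(vals) | np.isnan(height[gmask]), np.nan, res)
        out[gmask] = res
    return out if out.size > 1 else float(out[0])


def classify_state(score):
    """Map a component score to robust (0), pre-frail (1-2) or frail (>=3).

    Missing scores raise: callers must impute or drop first.
    """
    s = np.atleast_1d(_as_float(score))
    if np.isnan(s).any():
        raise ValueError("cannot classify a missing frailty score; impute or drop first")
    if ((s < 0) | (s > 5)).any():
        raise ValueError("frailty score must be in 0..5")
    out = np.where(s >= 3, FRAIL, np.where(s >= 1, PREFRAIL, ROBUST)).astype(object)
    return out if out.size > 1 else str(out[0])


FLAG_COLUMNS = ["flag_weightloss", "flag_exhaustion", "flag_lowactivity",
                "flag_weakness", "flag_slowness"]


def score_cohort(cohort: pd.DataFrame, thresholds: ThresholdSet | None = None) -> pd.DataFrame:
    """Score a cohort wave: component flags, summed score, frailty state.

    If ``thresholds`` is None they are derived from this wave (the usual
    baseline path); follow-up waves should be classified against frozen
    baseline thresholds. Returns a copy with columns ``flag_*``,
    ``frailty_score`` (NaN when any flag is missing) and ``frailty_state``
    (missing when the score is undefined).
    """
    if thresholds is None:
        thresholds = derive_thresholds(cohort)
    out = cohort.copy()
    grip = np.atleast_1d(summarize_grip(
        out["grip_left_1"], out["grip_left_2"], out["grip_right_1"], out["grip_right_2"]))
    walk = np.atleast_1d(summarize_walk(out["walk_time_1"], out["walk_time_2"]))
    bmi = compute_bmi(out["weight_current"], out["height"])

    out["flag_weightloss"] = flag_weight_loss(out["weight_current"], out["weight_at25"])
    out["flag_exhaustion"] = flag_exhaustion(out["gds_energy"])
    out["flag_lowactivity"] = flag_low_activity(out["pase_score"], thresholds)
    out["flag_weakness"] = flag_weakness(grip, out["gender"], bmi, thresholds)
    out["flag_slowness"] = flag_slowness(walk, out["gender"], out["height"], thresholds)

    flags = out[FLAG_COLUMNS].to_numpy(dtype=float)
    score = flags.sum(axis=1)
    score[np.isnan(flags).any(axis=1)] = np.nan
    out["frailty_score"] = score
    state = np.full(len(out), None, dtype=object)
    okmask = ~np.isnan(score)
    if okmask.any():
        state[okmask] = np.atleast_1d(classify_state(score[okmask]))
    out["frailty_state"] = state
    return out
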