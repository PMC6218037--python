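"""Two-wave frailty-state transitions: taxonomy and weighted transition matrix.

A baseline/follow-up state pair falls in one of three categories: *improved*
(strictly less frail at follow-up), *worsened* (strictly more frail) or
*unchanged*. Two-level moves (frail->robust, robust->frail) stay within
improved/worsened and are only annotated. Participants missing either state
are excluded and summarised in an attrition report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import STATES, state_index

IMPROVED = "improved"
WORSENED = "worsened"
UNCHANGED = "unchanged"
CATEGORIES = (IMPROVED, WORSENED, UNCHANGED)


def classify_transition(baseline: str, followup: str) -> str:
    """Category of a state pair: improved / worsened / unchanged.

    Missing (None/NaN) states return None as an exclusion signal rather than
    raising: such records are dropped from transition analysis.
    """
    def _missing(s):
        return s is None or (isinstance(s, float) and np.isnan(s))
    if _missing(baseline) or _missing(followup):
        return None
    b, f = state_index(baseline), state_index(followup)
    if f < b:
        return IMPROVED
    if f > b:
        return WORSENED
    return UNCHANGED


def is_two_level(baseline: str, followup: str) -> bool:
    """True for frail->robust or robust->frail (a move across two levels)."""
    return abs(state_index(followup) - state_index(baseline)) == 2


@dataclass
class TransitionMatrix:
    """3x3 transition summary between two waves.

    ``counts`` are raw; ``conditional_props`` are weighted row-conditional
    proportions with 95% CIs; ``category_props`` are weighted proportions of
    the three categories (with ``category_props_unweighted`` alongside, since
    the two can legitimately differ under a complex design).
    """

    counts: pd.DataFrame
    conditional_props: pd.DataFrame
    margins: dict
    category_props: dict
    category_props_unweighted: dict
    n: int
    attrition: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: one row per (baseline, followup) cell."""
        rows = []
        for b in STATES:
            for f in STATES:
                est = self.conditional_props.loc[b, f]
                rows.append({
                    "baseline": b, "followup": f,
                    "n": int(self.counts.loc[b, f]),
                    "proportion": est["estimate"],
                    "ci_low": est["ci_low"], "ci_high": est["ci_high"],
                    "category": classify_transition(b, f),
                })
        return pd.DataFrame(rows)


def build_transition_matrix(records: pd.DataFrame,
                            baseline_col: str = "baseline_state",
                            followup_col: str = "followup_state",
                            weight_col: str | None = "weight",
                            cluster_col: str | None = None) -> TransitionMatrix:
    """Tabulate the weighted 3x3 transition matrix from joined two-wave records.

    ``records`` must hold one row per participant with both states; rows with
    a missing state are excluded (and returned as the attrition frame).
    Confidence intervals come from the design-based proportion estimator
    (cluster-robust when ``cluster_col`` is given).
    """
    from .survey import weighted_proportion

    if len(records) == 0:
        raise ValueError("no transition records")
    df = records.copy()
    ok = df[baseline_col].isin(STATES) & df[followup_col].isin(STATES)
    excluded = df.loc[~ok]
    df = df.loc[ok]
    if len(df) == 0:
        raise ValueError("all transition records are missing a state")

    w = (df[weight_col].to_numpy(dtype=float)
         if weight_col and weight_col in df.columns else np.ones(len(df)))
    clusters = df[cluster_col].to_numpy() if cluster_col else None

    counts = pd.DataFrame(0, index=list(STATES), columns=list(STATES), dtype=int)
    cond_cells: dict[str, dict[str, dict]] = {b: {} for b in STATES}
    b_arr = df[baseline_col].to_numpy(dtype=object)
    f_arr = df[followup_col].to_numpy(dtype=object)
    for b in STATES:
        row_mask = b_arr == b
        for f in STATES:
            cell = row_mask & (f_arr == f)
            counts.loc[b, f] = int(cell.sum())
            if row_mask.sum() == 0:
                cond_cells[b][f] = {"estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan}
            else:
                est = weighted_proportion(
                    cell[row_mask].astype(float), w[row_mask],
                    clusters[row_mask] if clusters is not None else None)
                cond_cells[b][f] = {"estimate": est.estimate,
                                    "ci_low": est.ci_low, "ci_high": est.ci_high}
    cond = pd.DataFrame.from_dict(cond_cells, orient="index")[list(STATES)]

    cats = np.array([classify_transition(b, f) for b, f in zip(b_arr, f_arr)], dtype=object)
    wsum = w.sum()
    category_props = {}
    category_props_unweighted = {}
    for c in CATEGORIES:
        ind = (cats == c).astype(float)
        est = weighted_proportion(ind, w, clusters)
        category_props[c] = {"estimate": est.estimate,
                             "ci_low": est.ci_low, "ci_high": est.ci_high}
        category_props_unweighted[c] = float(ind.mean())

    margins = {
        "baseline": {s: float(w[b_arr == s].sum() / wsum) for s in STATES},
        "followup": {s: float(w[f_arr == s].sum() / wsum) for s in STATES},
        "baseline_counts": {s: int((b_arr == s).sum()) for s in STATES},
        "followup_counts": {s: int((f_arr == s).sum()) for s in STATES},
    }
    return TransitionMatrix(
        counts=counts, conditional_props=cond, margins=margins,
        category_props=category_props,
        category_props_unweighted=category_props_unweighted,
        n=len(df), attrition=excluded,
    )


def join_waves(baseline_scored: pd.DataFrame, followup_scored: pd.DataFrame,
               id_col: str = "id") -> pd.DataFrame:
    """Join two scored waves on participant id into transition records.

    Baseline participants without a follow-up row keep a missing follow-up
    state (they surface in the attrition report).
    """
    b = baseline_scored[[id_col, "frailty_state"]].rename(
        columns={"frailty_state": "baseline_state"})
    f = followup_scored[[id_col, "frailty_state"]].rename(
        columns={"frailty_state": "followup_state"})
    merged = b.merge(f, on=id_col, how="left")
    extra = [c for c in baseline_scored.columns if c not in (id_col, "frailty_state")]
    return merged.merge(baseline_scored[[id_col] + extra], on=id_col, how="left")
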