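"""Design-based estimation for a two-stage cluster sample.

The sampling design selects enumeration blocks (EBs, first stage) and living
quarters (LQs, second stage) by simple random sampling without replacement at
each stage. The inverse-inclusion-probability weight of every participant in
a selected LQ is

    w = (EB_total / EB_selected) * (LQ_total_in_EB / LQ_selected_in_EB)

Proportion variance uses first-stage (between-EB) cluster-robust Taylor
linearisation under the usual with-replacement approximation, ignoring
second-stage finite-population corrections; confidence intervals are built on
the logit scale and back-transformed. Contingency tests follow the
conventional rule: Pearson chi-square, switching to an exact test when any
expected cell count is below 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit


@dataclass
class SurveyDesign:
    """Two-stage cluster design parameters.

    ``lq_total_per_eb`` may be a single count (all EBs alike) or a mapping
    from EB id to its LQ frame size; likewise ``lq_selected_per_eb``.
    """

    eb_selected: int
    eb_total: int
    lq_selected_per_eb: int | Mapping = 16
    lq_total_per_eb: int | Mapping = 100

    def weight_for(self, eb_id) -> float:
        sel = (self.lq_selected_per_eb[eb_id]
               if isinstance(self.lq_selected_per_eb, Mapping) else self.lq_selected_per_eb)
        tot = (self.lq_total_per_eb[eb_id]
               if isinstance(self.lq_total_per_eb, Mapping) else self.lq_total_per_eb)
        return (self.eb_total / self.eb_selected) * (tot / sel)


def compute_weights(design: SurveyDesign, records: pd.DataFrame,
                    eb_col: str = "eb_id", normalize: bool = False) -> pd.DataFrame:
    """Attach the design weight to every record.

    With ``normalize`` the weights are rescaled to mean 1 (estimates are
    invariant to the rescaling; it only eases reporting).
    """
    out = records.copy()
    ebs = out[eb_col].to_numpy()
    unknown = []
    w = np.empty(len(out))
    for i, eb in enumerate(ebs):
        try:
            w[i] = design.weight_for(eb)
        except KeyError:
            unknown.append(eb)
    if unknown:
        raise ValueError(f"records reference cluster ids absent from the design: "
                         f"{sorted(set(unknown))}")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("design weights must be positive and finite")
    if normalize:
        w = w / w.mean()
    out["weight"] = w
    return out


@dataclass
class ProportionEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    se: float
    method: str


def weighted_proportion(indicator, weights=None, clusters=None,
                        alpha: float = 0.05) -> ProportionEstimate:
    """Design-based proportion with a 95% CI.

    estimate = sum(w*x)/sum(w). Variance is the between-cluster linearised
    estimator (each observation is its own cluster when ``clusters`` is
    None); the CI is computed on the logit scale and back-transformed.
    Degenerate all-0/all-1 indicators get a one-sided Clopper-Pearson-style
    exact bound on the unweighted count.
    """
    x = np.asarray(indicator, dtype=float)
    if x.size == 0:
        raise ValueError("empty indicator")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("indicator must be 0/1")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    n = x.size
    p = float(np.sum(w * x) / np.sum(w))
    z = stats.norm.ppf(1 - alpha / 2)

    if p <= 0.0 or p >= 1.0:
        # exact-style one-sided bound, on the unweighted count
        if p <= 0.0:
            lo, hi = 0.0, float(1 - (alpha / 2) ** (1 / n))
        else:
            lo, hi = float((alpha / 2) ** (1 / n)), 1.0
        return ProportionEstimate(p, lo, hi, n, 0.0, "exact-bound")

    if clusters is None:
        resid = w * (x - p)
        var = n / (n - 1) * np.sum(resid ** 2) / np.sum(w) ** 2 if n > 1 else np.nan
        method = "linearized"
    else:
        clusters = np.asarray(clusters)
        uniq = pd.unique(clusters)
        m = len(uniq)
        if m < 2:
            resid = w * (x - p)
            var = n / (n - 1) * np.sum(resid ** 2) / np.sum(w) ** 2 if n > 1 else np.nan
            method = "linearized"
        else:
            totals = np.zeros(m)
            for j, c in enumerate(uniq):
                sel = clusters == c
                totals[j] = np.sum(w[sel] * (x[sel] - p))
            var = m / (m - 1) * np.sum(totals ** 2) / np.sum(w) ** 2
            method = "cluster-linearized"

    se = float(np.sqrt(var))
    if se == 0:
        return ProportionEstimate(p, p, p, n, 0.0, method)
    se_logit = se / (p * (1 - p))
    lo = float(expit(logit(p) - z * se_logit))
    hi = float(expit(logit(p) + z * se_logit))
    return ProportionEstimate(p, lo, hi, n, se, method)


@dataclass
class ContingencyResult:
    statistic: float
    p_value: float
    method: str
    dof: int | None = None


def contingency_test(table, design_adjusted: bool = False,
                     weights_ratio: float | None = None,
                     seed: int = 0, n_resamples: int = 20000) -> ContingencyResult:
    """Pearson chi-square or exact test on an r x c count table.

    Uses Pearson's statistic without continuity correction; switches to
    Fisher's exact test (2x2) or a Monte-Carlo exact test with fixed-margin
    resampling (larger tables) when any expected count is below 5.
    ``design_adjusted`` applies a first-order Rao-Scott-style correction,
    dividing the statistic by the supplied mean design effect.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2-D array of nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")

    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    stat = float(((t - expected) ** 2 / expected).sum())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)

    if (expected < 5).any():
        if t.shape == (2, 2):
            _, p = stats.fisher_exact(t.astype(int))
            return ContingencyResult(stat, float(p), "fisher-exact", None)
        rng = np.random.default_rng(seed)
        rt = stats.random_table(t.sum(axis=1).astype(int), t.sum(axis=0).astype(int))
        samples = rt.rvs(n_resamples, random_state=rng)
        stats_mc = ((samples - expected) ** 2 / expected).sum(axis=(1, 2))
        p = float((np.sum(stats_mc >= stat - 1e-9) + 1) / (n_resamples + 1))
        return ContingencyResult(stat, p, "fisher-montecarlo", None)

    if design_adjusted:
        deff = weights_ratio if weights_ratio and weights_ratio > 0 else 1.0
        stat_adj = stat / deff
        p = float(stats.chi2.sf(stat_adj, dof))
        return ContingencyResult(stat_adj, p, "rao-scott-first-order", dof)

    p = float(stats.chi2.sf(stat, dof))
    return ContingencyResult(stat, p, "pearson-chi2", dof)
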