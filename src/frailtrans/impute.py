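"""Chained-equations multiple imputation and Rubin's-rules pooling.

Missing frailty-component flags (binary, logistic conditional draws) and
high-missingness covariates (continuous, predictive-mean matching over a
linear predictor) are imputed in m independent chains. Each chain starts from
a random fill drawn from the observed values, then sweeps the target fields a
fixed number of times, re-fitting each field's conditional model on the
currently-completed data. Frailty state and transition category are re-derived
within each completed dataset, never imputed directly.

Per-dataset analysis results are combined by Rubin's rules: pooled
coefficient = mean; total variance = mean within-variance + (1 + 1/m) x
between-variance; interval quantiles use the Barnard-Rubin degrees of
freedom (normal quantiles when the between-variance is zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .models import RegressionResult, Term

#: Covariates become imputation-eligible above this missing fraction;
#: frailty-component inputs are eligible at any nonzero missingness.
COVARIATE_MISSING_THRESHOLD = 0.05


@dataclass
class ImputationSpec:
    """Targets and tuning of the chained-equations sampler.

    ``target_fields`` maps each field to its conditional model: "logistic"
    for binary fields, "pmm" for continuous ones. ``predictors`` lists the
    always-observed covariates entering every conditional model (the other
    targets, in their current completed form, are always included).
    """

    target_fields: dict[str, str]
    m: int = 20
    iterations: int = 10
    donor_count: int = 5
    predictors: tuple[str, ...] = ()
    seed: int = 0

    def validate(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.donor_count < 1:
            raise ValueError("donor_count must be >= 1")
        for f, kind in self.target_fields.items():
            if kind not in ("logistic", "pmm"):
                raise ValueError(f"unknown conditional model {kind!r} for field {f!r}")


def missingness_report(records: pd.DataFrame,
                       component_fields=(), covariate_fields=()) -> pd.DataFrame:
    """Per-field missing fractions and imputation eligibility.

    A frailty-component input is eligible as soon as one record misses it; a
    covariate is eligible only above the 5% missingness threshold (below it,
    complete-case analysis is used for that field).
    """
    rows = []
    component_fields = set(component_fields)
    covariate_fields = set(covariate_fields)
    for col in records.columns:
        frac = float(records[col].isna().mean())
        if col in component_fields:
            eligible = frac > 0
            role = "component"
        elif col in covariate_fields:
            eligible = frac > COVARIATE_MISSING_THRESHOLD
            role = "covariate"
        else:
            eligible = False
            role = "other"
        rows.append({"field": col, "missing_fraction": frac,
                     "role": role, "imputation_eligible": eligible})
    return pd.DataFrame(rows)


def _predictor_matrix(df: pd.DataFrame, cols) -> np.ndarray:
    parts = [np.ones(len(df))]
    for c in cols:
        s = df[c]
        if s.dtype == object:
            for lev in sorted(map(str, pd.unique(s.dropna())))[1:]:
                parts.append((s.astype(str) == lev).to_numpy(dtype=float))
        else:
            parts.append(s.to_numpy(dtype=float))
    return np.column_stack(parts)


def _impute_field(work: pd.DataFrame, f: str, kind: str, miss: np.ndarray,
                  other_cols: list[str], donor_count: int,
                  rng: np.random.Generator) -> None:
    obs = ~miss
    X = _predictor_matrix(work, other_cols)
    y = work[f].to_numpy(dtype=float)
    try:
        if kind == "logistic":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y[obs], X[obs]).fit(disp=0, maxiter=100)
            p = expit(X[miss] @ fit.params)
            draws = (rng.random(miss.sum()) < p).astype(float)
        else:  # pmm
            fit = sm.OLS(y[obs], X[obs]).fit()
            pred_obs = X[obs] @ fit.params
            pred_mis = X[miss] @ fit.params
            obs_vals = y[obs]
            k = min(donor_count, obs_vals.size)
            draws = np.empty(miss.sum())
            for j, pm in enumerate(pred_mis):
                idx = np.argsort(np.abs(pred_obs - pm), kind="stable")[:k]
                draws[j] = obs_vals[idx[rng.integers(k)]]
    except Exception:
        # singular design / separation: fall back to a marginal draw
        draws = rng.choice(y[obs], size=int(miss.sum()), replace=True)
    vals = work[f].copy()
    vals[miss] = draws
    work[f] = vals


def mice_impute(records: pd.DataFrame, spec: ImputationSpec,
                rng: np.random.Generator | None = None) -> list[pd.DataFrame]:
    """Produce m completed datasets by chained-equations sampling.

    Observed values are never altered; output is deterministic under a fixed
    seed. Fields with no missing values pass through untouched.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    targets = {f: k for f, k in spec.target_fields.items() if f in records.columns}
    miss_masks = {f: records[f].isna().to_numpy() for f in targets}
    for f in targets:
        n_obs = int((~miss_masks[f]).sum())
        if n_obs == 0:
            raise ValueError(f"field {f!r} has no observed values to impute from")

    active = [f for f in targets if miss_masks[f].any()]
    completed = []
    for _ in range(spec.m):
        work = records.copy()
        for f in active:
            obs_vals = records.loc[~miss_masks[f], f].to_numpy()
            work.loc[miss_masks[f], f] = rng.choice(obs_vals, size=int(miss_masks[f].sum()))
        for _ in range(spec.iterations if active else 0):
            for f in active:
                other_cols = [c for c in targets if c != f] + [
                    c for c in spec.predictors if c in work.columns and c not in targets]
                _impute_field(work, f, targets[f], miss_masks[f],
                              other_cols, spec.donor_count, rng)
        completed.append(work)
    return completed


def pool_estimates(results: list[RegressionResult], alpha: float = 0.05
                   ) -> RegressionResult:
    """Combine m per-dataset regression results by Rubin's rules."""
    if not results:
        raise ValueError("no results to pool")
    m = len(results)
    keys = [(t.variable, t.level) for t in results[0].terms]
    for r in results[1:]:
        if [(t.variable, t.level) for t in r.terms] != keys:
            raise ValueError("per-dataset results have mismatched model structures")

    pooled_terms = []
    for i, (var, lev) in enumerate(keys):
        coefs = np.array([r.terms[i].coef for r in results])
        ses = np.array([r.terms[i].se for r in results])
        qbar = float(coefs.mean())
        W = float((ses ** 2).mean())
        B = float(coefs.var(ddof=1)) if m > 1 else 0.0
        T = W + (1 + 1 / m) * B
        se = float(np.sqrt(T))
        if B > 0 and m > 1:
            nu = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
            q = float(stats.t.ppf(1 - alpha / 2, nu))
            p = float(2 * stats.t.sf(abs(qbar) / se, nu)) if se > 0 else np.nan
        else:
            q = float(stats.norm.ppf(1 - alpha / 2))
            p = float(2 * stats.norm.sf(abs(qbar) / se)) if se > 0 else np.nan
        pooled_terms.append(Term(
            variable=var, level=lev, reference=results[0].terms[i].reference,
            coef=qbar, se=se, odds_ratio=float(np.exp(qbar)),
            ci_low=float(np.exp(qbar - q * se)), ci_high=float(np.exp(qbar + q * se)),
            p_value=p,
        ))
    return RegressionResult(
        outcome=results[0].outcome, terms=pooled_terms,
        n=results[0].n, converged=all(r.converged for r in results),
        separation=any(r.separation for r in results),
        adjustment=results[0].adjustment,
    )
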