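"""Logistic predictor models for frailty-transition outcomes.

Two binary outcomes are modelled separately: *worsened* (among participants
not frail at baseline, who can still worsen) and *improved* (among
participants not robust at baseline, who can still improve). Candidate
categorical covariates are screened univariately at p < 0.25; retained ones
enter a multivariable model that always adjusts for age group and gender,
with backward elimination at p >= 0.05 (largest p first, adjusters never
removed). Estimates are maximum-likelihood with Wald CIs on the log-odds
scale, exponentiated to odds ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .states import ROBUST, FRAIL
from .transitions import IMPROVED, WORSENED


@dataclass
class Term:
    variable: str
    level: str
    reference: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class RegressionResult:
    outcome: str
    terms: list[Term]
    n: int
    converged: bool
    separation: bool = False
    adjustment: tuple[str, ...] = ()
    intercept: float = np.nan
    dropped_collinear: list[str] = field(default_factory=list)

    def term(self, variable: str, level: str | None = None) -> Term:
        matches = [t for t in self.terms if t.variable == variable
                   and (level is None or t.level == level)]
        if not matches:
            raise KeyError(f"no term for {variable!r} (level {level!r})")
        return matches[0]

    def variable_p(self, variable: str) -> float:
        """Smallest Wald p over the variable's non-reference levels."""
        return min(t.p_value for t in self.terms if t.variable == variable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.terms])


def _design(df: pd.DataFrame, predictors, references) -> tuple[np.ndarray, list[tuple[str, str, str]]]:
    """Dummy-coded design matrix and (variable, level, reference) per column."""
    cols, names = [], []
    for var in predictors:
        series = df[var]
        levels = [str(v) for v in pd.unique(series.dropna())]
        levels.sort()
        ref = str(references.get(var, levels[0])) if references else levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not observed for {var!r}")
        for lev in levels:
            if lev == ref:
                continue
            cols.append((series.astype(str) == lev).to_numpy(dtype=float))
            names.append((var, lev, ref))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def fit_logistic(df: pd.DataFrame, outcome: str, predictors=(),
                 references: dict | None = None, alpha: float = 0.05,
                 cluster: str | None = None) -> RegressionResult:
    """Maximum-likelihood logistic fit of a binary outcome on categorical covariates.

    Rows with a missing outcome or predictor are dropped (complete case; the
    imputation module supplies completed datasets when needed). Collinear
    (aliased) columns are dropped deterministically, later-listed first, and
    recorded. Complete or quasi-complete separation is flagged on the result
    rather than raised. ``cluster`` names a column for optional
    cluster-robust standard errors (off by default).
    """
    use = df.dropna(subset=[outcome, *predictors])
    y = use[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; cannot fit")

    X, names = _design(use, predictors, references or {})
    dropped = []
    # deterministic aliasing rule: drop later columns until full column rank
    while X.shape[1] > 0:
        full = np.column_stack([np.ones(len(use)), X])
        if np.linalg.matrix_rank(full) == full.shape[1]:
            break
        X = X[:, :-1]
        dropped.append(f"{names[-1][0]}={names[-1][1]}")
        names = names[:-1]

    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, Xc)
            if cluster is not None:
                fit = model.fit(disp=0, maxiter=200, cov_type="cluster",
                                cov_kwds={"groups": use[cluster].to_numpy()})
            else:
                fit = model.fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
    except Exception:
        # perfect separation or singular information matrix
        separation = True
        converged = False
        k = Xc.shape[1]
        params = np.full(k, np.nan)
        bse = np.full(k, np.nan)
        pvals = np.full(k, np.nan)
    if converged and np.nanmax(np.abs(params)) > 15:
        separation = True

    z = float(stats.norm.ppf(1 - alpha / 2))
    terms = []
    for j, (var, lev, ref) in enumerate(names, start=1):
        b, s = float(params[j]), float(bse[j])
        terms.append(Term(
            variable=var, level=lev, reference=ref, coef=b, se=s,
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - z * s)), ci_high=float(np.exp(b + z * s)),
            p_value=float(pvals[j]),
        ))
    return RegressionResult(
        outcome=outcome, terms=terms, n=len(use), converged=converged,
        separation=separation, intercept=float(params[0]),
        dropped_collinear=dropped,
    )


def define_risk_sets(transitions: pd.DataFrame,
                     baseline_col: str = "baseline_state",
                     category_col: str = "category",
                     include_all: bool = False
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analysis sets for the two outcomes.

    Worsened set: participants who can worsen (not frail at baseline) with a
    0/1 ``outcome`` column marking a worsened transition; improved set:
    participants who can improve (not robust at baseline), outcome marking an
    improved transition. ``include_all`` keeps every participant in both sets
    (the alternative denominator reading).
    """
    df = transitions.dropna(subset=[baseline_col, category_col])
    if include_all:
        worsened = df.copy()
        improved = df.copy()
    else:
        worsened = df[df[baseline_col] != FRAIL].copy()
        improved = df[df[baseline_col] != ROBUST].copy()
    worsened["outcome"] = (worsened[category_col] == WORSENED).astype(int)
    improved["outcome"] = (improved[category_col] == IMPROVED).astype(int)
    return worsened, improved


def univariate_screen(df: pd.DataFrame, outcome: str, candidates,
                      references: dict | None = None, threshold: float = 0.25
                      ) -> tuple[list[str], pd.DataFrame]:
    """Fit each candidate alone; retain those with any level's Wald p < threshold.

    Returns the retained variable names and a per-candidate decision log
    (variable, smallest p, retained flag).
    """
    if not list(candidates):
        raise ValueError("candidate list is empty")
    selected, log = [], []
    for var in candidates:
        res = fit_logistic(df, outcome, [var], references)
        p = res.variable_p(var) if res.terms else np.nan
        keep = bool(np.isfinite(p) and p < threshold)
        if keep:
            selected.append(var)
        log.append({"variable": var, "min_p": p, "retained": keep})
    return selected, pd.DataFrame(log)


def build_multivariate(df: pd.DataFrame, outcome: str, selected,
                       references: dict | None = None,
                       forced: tuple[str, ...] = ("age_group", "gender"),
                       alpha: float = 0.05) -> RegressionResult:
    """Joint model of the screened variables, always adjusted for ``forced``.

    Backward elimination removes the non-forced variable with the largest
    variable-level p (smallest level p >= alpha), one at a time, refitting
    until all remaining pass or none are left; the forced adjusters are never
    removed. Collinear variables dropped during fitting leave the candidate
    list first.
    """
    forced = tuple(f for f in forced if f in df.columns)
    current = [v for v in selected if v not in forced]
    while True:
        predictors = list(forced) + current
        res = fit_logistic(df, outcome, predictors, references, alpha=alpha)
        fitted_vars = {t.variable for t in res.terms}
        aliased = [v for v in current if v not in fitted_vars]
        if aliased:
            current = [v for v in current if v != aliased[-1]]
            continue
        removable = [(v, res.variable_p(v)) for v in current]
        failing = [(v, p) for v, p in removable if not (np.isfinite(p) and p < alpha)]
        if not failing:
            break
        worst = max(failing, key=lambda vp: (np.inf if not np.isfinite(vp[1]) else vp[1]))
        current = [v for v in current if v != worst[0]]
        if not current:
            predictors = list(forced)
            res = fit_logistic(df, outcome, predictors, references, alpha=alpha)
            warnings.warn("backward elimination removed every screened variable; "
                          "returning the adjustment-only model")
            break
    res.adjustment = forced
    return res
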