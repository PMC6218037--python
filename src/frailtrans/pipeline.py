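"""End-to-end orchestration: simulate/load, score, weight, tabulate, model.

``run_pipeline`` executes the full analysis on a synthetic or user cohort and
writes a report bundle: scored waves, thresholds, characteristic/prevalence/
transition/model tables, and a run manifest (config hash, seed, versions).
Every proportion cell is tagged weighted or unweighted; unweighted cells are
recomputable from the emitted scored files by plain tabulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .states import STATES
from .scoring import derive_thresholds, score_cohort, FLAG_COLUMNS
from .simulate import (GeneratorConfig, generate_baseline, generate_followup,
                       inject_missingness, reference_thresholds)
from .covariates import derive_covariates
from .survey import SurveyDesign, compute_weights, weighted_proportion, contingency_test
from .transitions import build_transition_matrix, join_waves, classify_transition
from .models import define_risk_sets, univariate_screen, build_multivariate, fit_logistic
from .impute import ImputationSpec, mice_impute, pool_estimates, missingness_report
from . import io


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


DEFAULT_CANDIDATES = ("age_group", "gender", "cognitive_binary", "activity_level")
DEFAULT_REFERENCES = {
    "age_group": "60-69", "gender": "man",
    "cognitive_binary": "normal", "activity_level": "active",
}

CHARACTERISTIC_VARS = (
    "age_group", "gender", "ethnicity", "education_level", "marital_status",
    "living_arrangement", "social_support", "income_category",
    "cognitive_category", "chronic_band",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "frailtrans_report"
    simulate: dict | None = None          # GeneratorConfig fields
    inputs: dict | None = None            # {"baseline": path, "followup": path}
    design: dict = field(default_factory=lambda: {
        "eb_selected": 156, "eb_total": 254,
        "lq_selected_per_eb": 16, "lq_total_per_eb": 100})
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    references: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    imputation: dict | None = None        # {"m": 5, "iterations": 5, ...}
    risk_set_all: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if cfg.candidates:
            cfg.candidates = tuple(cfg.candidates)
        return cfg


def _prevalence_table(scored: pd.DataFrame, cluster_col: str = "eb_id") -> pd.DataFrame:
    """Weighted state and component prevalences, overall and by gender."""
    rows = []
    scored = scored[scored["frailty_state"].notna()]
    groups = [("all", scored)] + [(g, scored[scored["gender"] == g])
                                  for g in ("man", "woman")]
    items = [("state", s) for s in STATES] + [("component", c) for c in FLAG_COLUMNS]
    for gname, sub in groups:
        if len(sub) == 0:
            continue
        w = sub["weight"].to_numpy(dtype=float) if "weight" in sub else None
        cl = sub[cluster_col].to_numpy() if cluster_col in sub else None
        for kind, item in items:
            if kind == "state":
                ind = (sub["frailty_state"] == item).to_numpy(dtype=float)
                label = item
            else:
                vals = sub[item].to_numpy(dtype=float)
                keep = ~np.isnan(vals)
                ind, w_, cl_ = vals[keep], (w[keep] if w is not None else None), \
                    (cl[keep] if cl is not None else None)
                label = item
            if kind == "state":
                w_, cl_ = w, cl
            if ind.size == 0:
                continue
            est = weighted_proportion(ind, w_, cl_)
            rows.append({"group": gname, "item": label,
                         "estimate": est.estimate, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "n": est.n, "weighted": w_ is not None})
    return pd.DataFrame(rows)


def _characteristics_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Unweighted characteristic counts by frailty state, with association tests."""
    rows = []
    state = scored["frailty_state"]
    for var in CHARACTERISTIC_VARS:
        if var not in scored.columns:
            continue
        sub = scored.dropna(subset=[var])
        levels = sorted(map(str, pd.unique(sub[var].dropna())))
        table = np.array([[int(((sub[var].astype(str) == lev) &
                                (sub["frailty_state"] == s)).sum())
                           for s in STATES] for lev in levels])
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p, method = np.nan, "untestable"
        else:
            res = contingency_test(table)
            p, method = res.p_value, res.method
        for i, lev in enumerate(levels):
            row = {"variable": var, "level": lev, "n_all": int(table[i].sum()),
                   "p_value": p, "method": method, "weighted": False}
            for j, s in enumerate(STATES):
                row[f"n_{s}"] = int(table[i, j])
            rows.append(row)
    return pd.DataFrame(rows)


def _age_prevalence_table(scored: pd.DataFrame, cluster_col: str = "eb_id") -> pd.DataFrame:
    """Weighted frail prevalence per 5-year age band, overall and by gender."""
    rows = []
    for band in sorted(pd.unique(scored["age_band5"].dropna())):
        sub = scored[scored["age_band5"] == band]
        for gname, s2 in [("all", sub)] + [(g, sub[sub["gender"] == g])
                                           for g in ("man", "woman")]:
            if len(s2) == 0:
                continue
            ind = (s2["frailty_state"] == "frail").to_numpy(dtype=float)
            w = s2["weight"].to_numpy(dtype=float) if "weight" in s2 else None
            cl = s2[cluster_col].to_numpy() if cluster_col in s2 else None
            est = weighted_proportion(ind, w, cl)
            rows.append({"age_band": band, "group": gname, "n_frail": int(ind.sum()),
                         "estimate": est.estimate, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "n": est.n, "weighted": w is not None})
    return pd.DataFrame(rows)


def _model_tables(trans: pd.DataFrame, candidates, references, risk_set_all: bool
                  ) -> pd.DataFrame:
    worsened, improved = define_risk_sets(trans, include_all=risk_set_all)
    frames = []
    for label, riskset in (("worsened", worsened), ("improved", improved)):
        if riskset["outcome"].nunique() < 2 or len(riskset) < 20:
            continue
        usable = [c for c in candidates if c in riskset.columns
                  and riskset[c].dropna().nunique() > 1]
        uni_rows = []
        for var in usable:
            res = fit_logistic(riskset, "outcome", [var], references)
            for t in res.terms:
                uni_rows.append({"outcome": label, "model": "univariate",
                                 "variable": t.variable, "level": t.level,
                                 "reference": t.reference, "odds_ratio": t.odds_ratio,
                                 "ci_low": t.ci_low, "ci_high": t.ci_high,
                                 "p_value": t.p_value, "n": res.n})
        selected, _ = univariate_screen(riskset, "outcome", usable, references)
        multi = build_multivariate(riskset, "outcome", selected, references)
        multi_rows = [{"outcome": label, "model": "multivariate",
                       "variable": t.variable, "level": t.level,
                       "reference": t.reference, "odds_ratio": t.odds_ratio,
                       "ci_low": t.ci_low, "ci_high": t.ci_high,
                       "p_value": t.p_value, "n": multi.n}
                      for t in multi.terms]
        frames.append(pd.DataFrame(uni_rows + multi_rows))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute the full pipeline; returns the report bundle as a dict of frames.

    Stages: simulate (optional) -> load/validate -> eligibility filter ->
    derive covariates -> thresholds -> score both waves -> weights ->
    characteristics -> prevalence -> transitions -> predictor models ->
    outputs + manifest. Any stage failure aborts with the stage name.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- obtain waves ------------------------------------------------------
    gen_thresholds = None
    if config.simulate is not None:
        gen = GeneratorConfig.from_dict({**config.simulate, "seed": config.seed})
        baseline = generate_baseline(gen)
        followup = generate_followup(baseline, gen) if gen.mode == "state" else None
        if gen.missing_rates:
            baseline = inject_missingness(baseline, gen)
        if gen.mode == "state":
            gen_thresholds = reference_thresholds(gen)
    elif config.inputs is not None:
        bpath = config.inputs.get("baseline")
        try:
            baseline = io.read_cohort(bpath)
        except FileNotFoundError as e:
            raise PipelineError("load", str(e))
        followup = None
        if config.inputs.get("followup"):
            try:
                followup = io.read_cohort(config.inputs["followup"])
            except FileNotFoundError as e:
                raise PipelineError("load", str(e))
    else:
        raise PipelineError("config", "config must name input files or a simulation block")

    try:
        io.validate_cohort(baseline)
        if followup is not None:
            io.validate_cohort(followup)
    except io.CohortValidationError as e:
        raise PipelineError("validate", str(e))

    baseline, excluded = io.filter_eligible(baseline)
    if len(baseline) == 0:
        raise PipelineError("eligibility", "no eligible baseline records")

    baseline = derive_covariates(baseline)
    dssi_cut = baseline.attrs.get("dssi_low_cutoff")

    # --- thresholds and scoring -------------------------------------------
    try:
        thresholds = gen_thresholds or derive_thresholds(baseline)
    except Exception as e:
        raise PipelineError("thresholds", str(e))
    baseline_scored = score_cohort(baseline, thresholds)
    followup_scored = None
    if followup is not None:
        followup = derive_covariates(followup, dssi_low_cutoff=dssi_cut)
        followup_scored = score_cohort(followup, thresholds)

    # --- weights -----------------------------------------------------------
    design = SurveyDesign(**config.design)
    baseline_scored = compute_weights(design, baseline_scored)
    if followup_scored is not None:
        followup_scored = compute_weights(design, followup_scored)

    bundle: dict = {"thresholds": thresholds}
    bundle["missingness"] = missingness_report(
        baseline_scored, component_fields=FLAG_COLUMNS,
        covariate_fields=("income_monthly", "dssi_score", "mmse_score"))
    bundle["characteristics"] = _characteristics_table(baseline_scored)
    bundle["prevalence"] = _prevalence_table(baseline_scored)
    bundle["age_prevalence"] = _age_prevalence_table(baseline_scored)

    # --- transitions and models -------------------------------------------
    if followup_scored is not None and len(baseline_scored) > 1:
        trans = join_waves(baseline_scored, followup_scored)
        matrix = build_transition_matrix(trans, cluster_col="eb_id")
        bundle["transition_matrix"] = matrix
        trans_ok = trans[trans["followup_state"].notna() & trans["baseline_state"].notna()].copy()
        trans_ok["category"] = [
            classify_transition(b, f)
            for b, f in zip(trans_ok["baseline_state"], trans_ok["followup_state"])]
        trans_ok["activity_level"] = np.where(
            trans_ok["flag_lowactivity"].astype(float) == 1, "low", "active")
        bundle["models"] = _model_tables(
            trans_ok, config.candidates, config.references, config.risk_set_all)
    elif len(baseline_scored) <= 1:
        bundle["model_skip_reason"] = "cohort too small for transition models"

    # --- write outputs ------------------------------------------------------
    io.write_cohort(baseline_scored, out_dir / "baseline_scored.csv")
    if followup_scored is not None:
        io.write_cohort(followup_scored, out_dir / "followup_scored.csv")
    io.write_thresholds(thresholds, out_dir / "thresholds.yaml")
    for name in ("characteristics", "prevalence", "age_prevalence", "missingness", "models"):
        if name in bundle and isinstance(bundle[name], pd.DataFrame) and len(bundle[name]):
            bundle[name].to_csv(out_dir / f"{name}.csv", index=False)
    if "transition_matrix" in bundle:
        bundle["transition_matrix"].to_frame().to_csv(
            out_dir / "transitions.csv", index=False)
        with open(out_dir / "transition_categories.json", "w") as fh:
            json.dump({
                "weighted": bundle["transition_matrix"].category_props,
                "unweighted": bundle["transition_matrix"].category_props_unweighted,
            }, fh, indent=2)

    cfg_text = yaml.safe_dump(
        {k: v for k, v in vars(config).items()}, sort_keys=True, default_flow_style=None)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_baseline": int(len(baseline_scored)),
        "n_excluded_mmse": int(len(excluded)),
        "n_followup": int(len(followup_scored)) if followup_scored is not None else 0,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
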