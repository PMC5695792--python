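"""End-to-end orchestration: cohort -> features -> factors -> outcomes ->
disease risk -> adherence -> linkage, with a single JSON-able summary."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import features as feat
from . import factorize
from . import outcomes as out_mod
from . import disease_risk
from . import adherence as adh_mod
from . import linkage as link_mod
from .config import PipelineConfig

__all__ = ["run_all", "PipelineError", "build_design"]

log = logging.getLogger("statinadh")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def build_design(cohort: pd.DataFrame, scores: pd.DataFrame | None = None,
                 extra: dict | None = None) -> pd.DataFrame:
    """Shared model design: demographics, statin characteristics,
    interaction counts, and (optionally) factor scores."""
    X = pd.DataFrame(index=pd.Index(cohort["patient_id"], name="patient_id"))
    c = cohort.set_index("patient_id")
    X["age"] = c["age"].astype(float)
    X["sex_male"] = (c["sex"] == "M").astype(float)
    X["tobacco"] = c["tobacco"].astype(float)
    for cat in sorted(c["pharmacy_program"].dropna().unique())[1:]:
        X[f"pharmacy_{cat}"] = (c["pharmacy_program"] == cat).astype(float)
    for cat in sorted(c["race"].dropna().unique())[1:]:
        X[f"race_{cat}"] = (c["race"] == cat).astype(float)
    X["first_supply_days"] = c["first_statin_days_supply"].astype(float)
    X["first_strength"] = c["first_statin_strength"].astype(float)
    X["followup_days"] = c["followup_days"].astype(float)
    X["n_labs"] = c["n_labs"].astype(float)
    X["n_drugs"] = c["n_drugs"].astype(float)
    X["n_codes"] = c["n_codes"].astype(float)
    if scores is not None:
        for col in scores.columns:
            X[col] = scores[col].reindex(X.index).to_numpy(float)
    if extra:
        for k, v in extra.items():
            X[k] = pd.Series(v).reindex(X.index).to_numpy(float)
    return X


def run_all(claims: pd.DataFrame, demographics: pd.DataFrame,
            config: PipelineConfig | None = None,
            precomputed_scores: pd.DataFrame | None = None) -> dict:
    """Run the whole analysis and return a results bundle.

    The returned dict has a JSON-able ``summary`` plus per-stage artifacts
    (cohort table, count matrix, factor model, outcome tables, fits).
    Deterministic given (claims, demographics, config).
    """
    cfg = config or PipelineConfig()
    rng_seed = int(cfg.seed)
    summary: dict = {"seed": rng_seed}
    artifacts: dict = {"summary": summary}

    def stage(name):
        log.info("stage: %s", name)
        return name

    # ---- cohort -----------------------------------------------------------
    name = stage("cohort")
    try:
        window = cfg.prescribing_window
        if window is None:
            first = cohort_mod.identify_first_statin(claims, cfg.statin_codes)
            if first.empty:
                raise ValueError("no statin first fills in claims")
            window = (int(first.min()), int(first.max()))
        cohort, tally = cohort_mod.apply_filters(
            claims, demographics, cfg.statin_codes, window=window)
        if cohort.empty:
            raise ValueError(f"cohort empty after filters (tally: {tally})")
    except Exception as e:
        raise PipelineError(name, str(e)) from e
    summary["cohort_size"] = len(cohort)
    summary["exclusion_tally"] = tally
    artifacts["cohort"] = cohort

    # ---- features ---------------------------------------------------------
    name = stage("features")
    try:
        counts = feat.build_count_matrix(
            claims, cohort, window_months=cfg.count_window_months,
            min_patients=cfg.min_patients_per_variable,
            exclude_codes=cfg.statin_codes)
        labs = feat.extract_baseline_labs(claims, cohort,
                                          lookback_months=cfg.lab_lookback_months)
        prior_pdc = feat.compute_prior_pdc(claims, cohort,
                                           statin_codes=cfg.statin_codes)
    except Exception as e:
        raise PipelineError(name, str(e)) from e
    summary["n_count_variables"] = int(counts.shape[1])
    summary["count_variables_by_kind"] = \
        counts.variables["kind"].value_counts().to_dict()
    summary["n_lab_value_variables"] = int(labs.shape[1])
    summary["n_prior_pdc_variables"] = int(prior_pdc.shape[1])
    artifacts.update(counts=counts, labs=labs, prior_pdc=prior_pdc)

    # ---- factorize --------------------------------------------------------
    name = stage("factorize")
    try:
        if cfg.use_precomputed_scores and precomputed_scores is not None:
            scores = precomputed_scores.reindex(cohort["patient_id"])
            model = None
        else:
            k = min(cfg.n_factors, min(counts.shape) - 1)
            model = factorize.fit_nmf(counts, k=k, max_iter=cfg.nmf_max_iter,
                                      tol=cfg.nmf_tol, seed=rng_seed,
                                      log1p=cfg.log1p_counts)
            scores = model.scores_frame()
            scores.index = pd.Index(cohort["patient_id"], name="patient_id")
    except Exception as e:
        raise PipelineError(name, str(e)) from e
    summary["n_factors"] = int(scores.shape[1])
    artifacts["factor_model"] = model
    artifacts["scores"] = scores

    # ---- outcomes ---------------------------------------------------------
    name = stage("outcomes")
    try:
        adh = out_mod.adherence_outcomes(claims, cohort, cfg.statin_codes)
        lipids = out_mod.lipid_change(claims, cohort)
        events = out_mod.event_outcomes(claims, cohort, cfg.group_code_map)
    except Exception as e:
        raise PipelineError(name, str(e)) from e
    summary["n_adherent"] = int(adh["adherent"].sum())
    summary["adherent_fraction"] = float(adh["adherent"].mean())
    summary["first_refill_fraction"] = float(adh["first_refill"].mean())
    summary["n_composite_events"] = int(events["composite_event"].sum())
    artifacts.update(adherence_outcomes=adh, lipids=lipids, events=events)

    # ---- disease risk -----------------------------------------------------
    name = stage("disease_risk")
    try:
        X_risk = build_design(cohort, scores)
        horizon = 365 * cfg.risk_horizon_years
        Y = pd.DataFrame({
            g: (events[f"{g}_event"] & (events[f"{g}_time_days"] <= horizon))
            .astype(float).to_numpy()
            for g in out_mod.EVENT_GROUPS}, index=events.index)
        risk = disease_risk.fit_risk(
            X_risk, Y, n_folds=cfg.n_folds, seed=rng_seed,
            fixed_lambda=cfg.risk_fixed_lambda,
            patient_ids=X_risk.index.to_numpy())
    except Exception as e:
        raise PipelineError(name, str(e)) from e
    risk_auc = {}
    for g in Y.columns:
        if 0 < Y[g].sum() < len(Y):
            risk_auc[g] = adh_mod.c_statistic(Y[g].to_numpy(bool),
                                              risk.oof_probs[g])
    summary["risk_cv_auc"] = risk_auc
    artifacts["risk"] = risk

    # ---- adherence --------------------------------------------------------
    name = stage("adherence")
    try:
        X_adh = build_design(cohort, scores,
                             extra={"disease_risk": risk.composite_risk})
        for col in labs.columns:
            X_adh[f"lab_{col}"] = labs[col].reindex(X_adh.index).to_numpy(float)
        y = adh["adherent"].reindex(X_adh.index).to_numpy(bool)
        spec = adh_mod.AdherenceModelSpec(n_trees=cfg.n_trees,
                                          n_folds=cfg.n_folds, seed=rng_seed)
        fit = adh_mod.fit_adherence(X_adh, y, spec)
        summary["adherence_cv_auc"] = fit.auc
        fit_fr = None
        if cfg.include_first_refill_model:
            X_fr = X_adh.copy()
            X_fr["first_refill"] = adh["first_refill"].reindex(
                X_adh.index).astype(float).to_numpy()
            y_fr = (adh["followup_pdc"].reindex(X_adh.index) > 0.8).to_numpy(bool)
            if 0 < y_fr.sum() < len(y_fr):
                fit_fr = adh_mod.fit_adherence(X_fr, y_fr, spec)
                summary["adherence_cv_auc_first_refill"] = fit_fr.auc
        assoc = adh_mod.factor_association(
            y, scores, build_design(cohort, None,
                                    extra={"disease_risk": risk.composite_risk}))
    except Exception as e:
        raise PipelineError(name, str(e)) from e
    artifacts.update(adherence_fit=fit, adherence_fit_first_refill=fit_fr,
                     factor_association=assoc)

    # ---- linkage ----------------------------------------------------------
    name = stage("linkage")
    try:
        corr = link_mod.lipid_correlation(fit.oof_prob, lipids)
        cov = build_design(cohort)[["age", "sex_male", "tobacco",
                                    "first_supply_days", "followup_days"]]
        hr = link_mod.cox_linkage(fit.oof_prob, events, covariates=cov,
                                  disease_risk=risk.composite_risk)
        km = link_mod.adherence_tertile_km(fit.oof_prob, events,
                                           groups=("composite",))
    except Exception as e:
        raise PipelineError(name, str(e)) from e
    summary["lipid_correlation"] = {
        row["analyte"]: {"r": row["r"], "p": row["p_value"], "n": row["n"]}
        for _, row in corr.iterrows()}
    summary["cox_hazard_ratios"] = hr.set_index("group").to_dict("index")
    summary["composite_km_logrank_p"] = km["composite"].logrank_p
    artifacts.update(lipid_corr=corr, cox_table=hr, adherence_km=km)
    return artifacts
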