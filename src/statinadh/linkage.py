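"""Linking predicted adherence to cholesterol change and hospitalizations.

Three analyses: (i) Pearson correlation between predicted adherence and the
magnitude of cholesterol lowering; (ii) Cox proportional-hazards regression
of each hospitalization group (and the composite) on predicted adherence,
adjusting for patient/statin covariates and predicted disease risk; (iii)
Kaplan-Meier curves by tertile of predicted adherence with log-rank tests.
Predicted adherence enters the Cox model as the out-of-fold probability on
its natural 0-1 scale, so hazard ratios are per full unit of predicted
adherence probability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from lifelines import CoxPHFitter

from .disease_risk import TertileKM, risk_tertile_km

__all__ = ["lipid_correlation", "cox_linkage", "adherence_tertile_km"]


def lipid_correlation(predicted_adherence: pd.Series, lipids: pd.DataFrame,
                      analytes=("LDL", "TC")) -> pd.DataFrame:
    """Pearson correlation of predicted adherence with cholesterol lowering.

    For each analyte, r is computed against minus the baseline-to-follow-up
    delta, so positive r means higher predicted adherence goes with more
    lowering; the raw-delta correlation is also reported. Analytes with
    fewer than 3 complete pairs are flagged not computable.
    """
    pred = pd.Series(predicted_adherence)
    rows = []
    for analyte in analytes:
        delta = lipids[f"{analyte}_delta"].reindex(pred.index)
        ok = delta.notna() & pred.notna()
        row = {"analyte": analyte, "n": int(ok.sum()),
               "r": np.nan, "p_value": np.nan, "r_raw_delta": np.nan}
        if ok.sum() >= 3:
            r, p = pearsonr(pred[ok], -delta[ok])
            row.update(r=float(r), p_value=float(p), r_raw_delta=float(-r))
        rows.append(row)
    return pd.DataFrame(rows)


def cox_linkage(predicted_adherence: pd.Series, events: pd.DataFrame,
                covariates: pd.DataFrame | None = None,
                disease_risk: pd.Series | None = None,
                groups=("MI", "stroke", "CAD", "composite")) -> pd.DataFrame:
    """Adjusted Cox hazard ratios for predicted adherence, per outcome group.

    Fits one proportional-hazards model per group on (time, event) with
    predicted adherence, predicted disease risk, and the supplied covariates.
    Groups with no events are skipped with a notice row. Returns hazard
    ratio and Wald p for adherence and disease risk in each group.
    """
    idx = events.index
    base = pd.DataFrame(index=idx)
    base["adherence"] = pd.Series(predicted_adherence).reindex(idx)
    if disease_risk is not None:
        base["disease_risk"] = pd.Series(disease_risk).reindex(idx)
    if covariates is not None:
        for c in covariates.columns:
            base[c] = covariates[c].reindex(idx) if isinstance(covariates.index, pd.Index) \
                else covariates[c].to_numpy()
    rows = []
    for grp in groups:
        T = events[f"{grp}_time_days"]
        E = events[f"{grp}_event"].astype(bool)
        row = {"group": grp, "n_events": int(E.sum())}
        if E.sum() == 0:
            row.update(skipped=True, note="no events in group")
            rows.append(row)
            continue
        df = base.copy()
        df["T"] = T
        df["E"] = E.astype(int)
        df = df.dropna()
        cph = CoxPHFitter(penalizer=1e-6)
        cph.fit(df, duration_col="T", event_col="E")
        row.update(skipped=False,
                   adherence_hr=float(np.exp(cph.params_["adherence"])),
                   adherence_p=float(cph.summary.loc["adherence", "p"]),
                   adherence_hr_lo=float(np.exp(cph.confidence_intervals_.loc[
                       "adherence"].iloc[0])),
                   adherence_hr_hi=float(np.exp(cph.confidence_intervals_.loc[
                       "adherence"].iloc[1])))
        if disease_risk is not None:
            row.update(risk_hr=float(np.exp(cph.params_["disease_risk"])),
                       risk_p=float(cph.summary.loc["disease_risk", "p"]))
        rows.append(row)
    return pd.DataFrame(rows)


def adherence_tertile_km(predicted_adherence: pd.Series, events: pd.DataFrame,
                         groups=("MI", "stroke", "CAD", "composite")) -> dict:
    """Per-group KM curves and log-rank tests over adherence tertiles."""
    pred = pd.Series(predicted_adherence).reindex(events.index)
    out: dict[str, TertileKM] = {}
    for grp in groups:
        out[grp] = risk_tertile_km(pred.to_numpy(float),
                                   events[f"{grp}_time_days"],
                                   events[f"{grp}_event"])
    return out
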