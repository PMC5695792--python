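"""Cohort construction: inclusion/exclusion filters over raw claims.

The eligible cohort consists of statin-naive adults (18-65 at the threshold
month) whose first flagged statin fill falls inside the prescribing window,
whose first fill has a standard duration (30/60/90/180 days), and who have
at least one year of follow-up, where follow-up runs from the threshold to
the last recorded data element of any kind. Dates are month indices and day
arithmetic uses 30 days per month throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .features import interaction_counts

__all__ = ["identify_first_statin", "apply_filters", "cohort_summary",
           "ALLOWED_SUPPLY", "DAYS_PER_MONTH"]

ALLOWED_SUPPLY = (30, 60, 90, 180)
DAYS_PER_MONTH = 30
MIN_FOLLOWUP_DAYS = 365


def _statin_fills(claims: pd.DataFrame, statin_codes) -> pd.DataFrame:
    mask = (claims["kind"] == "drug") & claims["code"].isin(set(statin_codes))
    return claims.loc[mask]


def identify_first_statin(claims: pd.DataFrame, statin_codes,
                          window: tuple | None = None) -> pd.Series:
    """Threshold month per patient: earliest statin fill flagged as a first fill.

    Parameters
    ----------
    claims : claim events for one or many patients.
    statin_codes : iterable of drug tokens that count as statins.
    window : optional (start, end) month range; first fills outside it are
        ignored (the patient then has no threshold).

    Returns a Series indexed by patient_id; patients with no qualifying fill
    are absent.
    """
    fills = _statin_fills(claims, statin_codes)
    fills = fills[fills["new_refill_flag"] == True]  # noqa: E712  (object col)
    if window is not None:
        fills = fills[(fills["month"] >= window[0]) & (fills["month"] <= window[1])]
    if fills.empty:
        return pd.Series(dtype=int, name="threshold_month")
    out = fills.groupby("patient_id")["month"].min()
    out.name = "threshold_month"
    return out


def apply_filters(claims: pd.DataFrame, demographics: pd.DataFrame,
                  statin_codes, window: tuple,
                  naive_months: int = 12,
                  recent_statin_months: int = 6,
                  min_followup_days: int = MIN_FOLLOWUP_DAYS,
                  count_windows: dict | None = None):
    """Apply the inclusion/exclusion cascade and emit one row per kept patient.

    Filters are applied in order: treatment-naive -> prescribing window ->
    age 18-65 -> first-fill duration in {30,60,90,180} -> >= 365 days of
    follow-up. The exclusion tally is order-dependent: a patient failing
    several rules is counted under the first.

    Returns ``(cohort, tally)`` where ``tally`` maps rule name -> count
    removed (plus ``retained``). An empty cohort is a valid result.
    """
    demo = demographics.set_index("patient_id")
    missing = set(claims["patient_id"].unique()) - set(demo.index)
    if missing:
        raise ValueError(f"demographics missing for patients: {sorted(missing)[:5]}")

    all_patients = pd.Index(claims["patient_id"].unique())
    tally = {"no_first_statin_fill": 0, "not_treatment_naive": 0,
             "outside_prescribing_window": 0, "age": 0,
             "nonstandard_days_supply": 0, "insufficient_followup": 0}

    thresholds = identify_first_statin(claims, statin_codes)
    tally["no_first_statin_fill"] = int(len(all_patients) - len(thresholds))

    statins = _statin_fills(claims, statin_codes)
    first = statins[statins["new_refill_flag"] == True].sort_values(  # noqa: E712
        "month", kind="stable").drop_duplicates("patient_id", keep="first")
    first = first.set_index("patient_id").loc[thresholds.index]

    # treatment-naive: no statin fill of any kind in the 12 months before the
    # threshold (the stated 6-month exclusion is subsumed but applied too)
    lookback = max(naive_months, recent_statin_months)
    t = thresholds.reindex(statins["patient_id"]).to_numpy()
    prior = statins[(statins["month"].to_numpy() < t)
                    & (statins["month"].to_numpy() >= t - lookback)]
    not_naive = pd.Index(prior["patient_id"].unique())
    tally["not_treatment_naive"] = len(not_naive)
    keep = thresholds.drop(not_naive)

    in_window = keep[(keep >= window[0]) & (keep <= window[1])]
    tally["outside_prescribing_window"] = int(len(keep) - len(in_window))
    keep = in_window

    age = demo["age"].reindex(keep.index)
    ok = (age >= 18) & (age <= 65)
    tally["age"] = int((~ok).sum())
    keep = keep[ok]

    supply = first["days_supply"].reindex(keep.index)
    ok = supply.isin(ALLOWED_SUPPLY)
    tally["nonstandard_days_supply"] = int((~ok).sum())
    keep = keep[ok]

    last_month = claims.groupby("patient_id")["month"].max().reindex(keep.index)
    followup_days = (last_month - keep) * DAYS_PER_MONTH
    ok = followup_days >= min_followup_days
    tally["insufficient_followup"] = int((~ok).sum())
    keep = keep[ok]
    followup_days = followup_days[ok]

    cohort = pd.DataFrame({
        "patient_id": keep.index,
        "threshold_month": keep.to_numpy(int),
        "followup_days": followup_days.to_numpy(int),
    })
    for col in ("age", "sex", "race", "tobacco", "pharmacy_program"):
        if col in demo.columns:
            cohort[col] = demo[col].reindex(keep.index).to_numpy()
    fs = first.reindex(keep.index)
    cohort["first_statin_code"] = fs["code"].to_numpy()
    cohort["first_statin_days_supply"] = fs["days_supply"].to_numpy(float).astype(int)
    cohort["first_statin_strength"] = fs["strength"].to_numpy(float)

    counts = interaction_counts(claims, cohort, windows=count_windows)
    cohort = cohort.merge(counts, on="patient_id", how="left")
    cohort[["n_labs", "n_drugs", "n_codes"]] = \
        cohort[["n_labs", "n_drugs", "n_codes"]].fillna(0).astype(int)

    tally["retained"] = len(cohort)
    assert sum(tally.values()) == len(all_patients)
    return cohort.reset_index(drop=True), tally


def cohort_summary(cohort: pd.DataFrame, labels: pd.Series,
                   variables: list | None = None) -> pd.DataFrame:
    """Stratified descriptive table with two-sample tests.

    Continuous variables get mean-by-stratum and a Welch t-test; binary/boolean
    variables get proportion-by-stratum and a chi-square test. ``labels`` is a
    boolean Series aligned to ``cohort`` rows (e.g. adherent yes/no). Strata
    with fewer than two patients, or all-missing variables, report no p-value.
    """
    labels = np.asarray(labels, bool)
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in ("patient_id",) and
                     pd.api.types.is_numeric_dtype(cohort[c]) or
                     pd.api.types.is_bool_dtype(cohort[c])]
    rows = []
    for var in variables:
        x = pd.to_numeric(cohort[var], errors="coerce") \
            if not pd.api.types.is_bool_dtype(cohort[var]) else cohort[var].astype(float)
        x = x.to_numpy(float)
        present = ~np.isnan(x)
        a, b = x[present & labels], x[present & ~labels]
        row = {"variable": var, "n_missing": int((~present).sum()),
               "mean_group1": float(np.mean(a)) if a.size else np.nan,
               "mean_group0": float(np.mean(b)) if b.size else np.nan,
               "p_value": np.nan}
        if a.size >= 2 and b.size >= 2:
            uniq = np.unique(x[present])
            if len(uniq) <= 2 and set(uniq) <= {0.0, 1.0}:
                table = np.array([[np.sum(a == 1), np.sum(a == 0)],
                                  [np.sum(b == 1), np.sum(b == 0)]])
                if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
                    row["p_value"] = float(stats.chi2_contingency(table)[1])
            elif len(uniq) > 1:
                row["p_value"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
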