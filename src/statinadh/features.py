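"""Baseline (pre-threshold) predictor construction.

Four predictor families are built from the claims history before each
patient's first statin fill: per-variable occurrence counts in a short
window (the input to the factorization), the most recent value of each
laboratory analyte, a prior percent-days-covered for every non-statin
medication with enough history, and per-kind interaction totals used to
control for how much a patient touches the health system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "build_count_matrix", "extract_baseline_labs",
           "compute_prior_pdc", "interaction_counts",
           "DEFAULT_COUNT_WINDOW", "DEFAULT_INTERACTION_WINDOWS"]

DAYS_PER_MONTH = 30

#: Months counted into the count matrix (window ends at the threshold month).
DEFAULT_COUNT_WINDOW = 6

#: Per-kind raw collection windows (months) for interaction totals:
#: one year of coding and prescription history, two years of laboratory data.
DEFAULT_INTERACTION_WINDOWS = {"code": 12, "drug": 12, "lab": 24}

#: A variable must be observed in at least this many patients to be kept.
DEFAULT_MIN_PATIENTS = 100


@dataclass
class CountMatrix:
    """Patients x variables nonnegative integer occurrence matrix."""

    patient_ids: np.ndarray        # ordered, aligned to rows
    variables: pd.DataFrame        # columns: name, kind; aligned to columns
    X: np.ndarray                  # (n_patients, n_variables) int
    window_months: int

    def __post_init__(self):
        if (self.X < 0).any():
            raise ValueError("count matrix entries must be nonnegative")

    @property
    def shape(self):
        return self.X.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.patient_ids,
                            columns=self.variables["name"].to_numpy())


def _thresholds(cohort: pd.DataFrame) -> pd.Series:
    return cohort.set_index("patient_id")["threshold_month"]


def build_count_matrix(claims: pd.DataFrame, cohort: pd.DataFrame,
                       window_months: int = DEFAULT_COUNT_WINDOW,
                       min_patients: int = DEFAULT_MIN_PATIENTS,
                       exclude_codes=None) -> CountMatrix:
    """Count occurrences of every variable in the months leading to threshold.

    Entry (p, v) is the number of claim events with code v for patient p in
    months ``[threshold - window_months + 1, threshold]`` (the window includes
    the threshold month). Variables observed in fewer than ``min_patients``
    patients are dropped; column order is lexicographic by variable name.
    ``exclude_codes`` (e.g. the statin list) removes variables outright.
    """
    if window_months <= 0:
        raise ValueError("window_months must be positive")
    thr = _thresholds(cohort)
    ev = claims[claims["patient_id"].isin(thr.index)].copy()
    t = thr.reindex(ev["patient_id"]).to_numpy()
    m = ev["month"].to_numpy()
    ev = ev[(m <= t) & (m > t - window_months)]
    if exclude_codes is not None:
        ev = ev[~ev["code"].isin(set(exclude_codes))]

    tab = ev.groupby(["patient_id", "code"], sort=False).agg(
        n=("code", "size"), kind=("kind", "first")).reset_index()
    # drop variables seen in too few patients
    per_var = tab.groupby("code")["patient_id"].nunique()
    kept = sorted(per_var.index[per_var >= min_patients])
    tab = tab[tab["code"].isin(kept)]

    pids = cohort["patient_id"].to_numpy()
    pid_pos = {p: i for i, p in enumerate(pids)}
    var_pos = {v: j for j, v in enumerate(kept)}
    X = np.zeros((len(pids), len(kept)), dtype=int)
    if len(tab):
        rows = tab["patient_id"].map(pid_pos).to_numpy()
        cols = tab["code"].map(var_pos).to_numpy()
        X[rows, cols] = tab["n"].to_numpy()
    kind_of = dict(zip(tab["code"], tab["kind"]))
    variables = pd.DataFrame({"name": kept,
                              "kind": [kind_of.get(v, "code") for v in kept]})
    return CountMatrix(patient_ids=pids, variables=variables, X=X,
                       window_months=window_months)


def extract_baseline_labs(claims: pd.DataFrame, cohort: pd.DataFrame,
                          lookback_months: int = 24) -> pd.DataFrame:
    """Most recent value per analyte at or before the threshold month.

    Values older than the lookback (months in ``[threshold - lookback + 1,
    threshold]``) are ignored. Ties within the chosen month are broken by
    taking the last record in file order. Returns a wide frame indexed by
    patient_id with one column per analyte; absent values are NaN.
    """
    thr = _thresholds(cohort)
    labs = claims[(claims["kind"] == "lab")
                  & claims["patient_id"].isin(thr.index)].copy()
    t = thr.reindex(labs["patient_id"]).to_numpy()
    m = labs["month"].to_numpy()
    labs = labs[(m <= t) & (m > t - lookback_months)]
    labs = labs.sort_values("month", kind="stable")
    last = labs.groupby(["patient_id", "code"], sort=False).last()
    wide = last["value"].unstack("code")
    return wide.reindex(cohort["patient_id"]).sort_index(axis=1)


def compute_prior_pdc(claims: pd.DataFrame, cohort: pd.DataFrame,
                      statin_codes=(), min_history_months: int = 2,
                      cap: bool = True) -> pd.DataFrame:
    """Pre-threshold percent-days-covered per non-statin medication.

    For each patient/drug pair whose first fill is at least
    ``min_history_months`` months before threshold:
    ``PDC = total days supplied before threshold / (30 * months from first
    fill to threshold)``, capped at 1. Statins never appear as columns; pairs
    with insufficient history are missing.
    """
    thr = _thresholds(cohort)
    drugs = claims[(claims["kind"] == "drug")
                   & claims["patient_id"].isin(thr.index)
                   & ~claims["code"].isin(set(statin_codes))].copy()
    t = thr.reindex(drugs["patient_id"]).to_numpy()
    pre = drugs[drugs["month"].to_numpy() < t]
    if pre.empty:
        return pd.DataFrame(index=pd.Index(cohort["patient_id"], name="patient_id"))
    g = pre.groupby(["patient_id", "code"])
    agg = g.agg(first_month=("month", "min"), supplied=("days_supply", "sum"))
    t2 = thr.reindex(agg.index.get_level_values("patient_id")).to_numpy()
    months_hist = t2 - agg["first_month"].to_numpy()
    pdc = agg["supplied"].to_numpy(float) / (DAYS_PER_MONTH * months_hist)
    if cap:
        pdc = np.minimum(pdc, 1.0)
    agg["pdc"] = np.where(months_hist >= min_history_months, pdc, np.nan)
    wide = agg["pdc"].unstack("code")
    return wide.reindex(cohort["patient_id"]).sort_index(axis=1)


def interaction_counts(claims: pd.DataFrame, cohort: pd.DataFrame,
                       windows: dict | None = None) -> pd.DataFrame:
    """Per-patient totals of pre-threshold events by kind.

    Each kind uses its own collection window (months before and including
    threshold); defaults follow the raw-collection periods: 12 months for
    codes and drugs, 24 for labs. Returns columns n_labs, n_drugs, n_codes.
    """
    if windows is None:
        windows = DEFAULT_INTERACTION_WINDOWS
    thr = _thresholds(cohort)
    ev = claims[claims["patient_id"].isin(thr.index)]
    t = thr.reindex(ev["patient_id"]).to_numpy()
    m = ev["month"].to_numpy()
    out = pd.DataFrame({"patient_id": cohort["patient_id"]})
    for kind, col in (("lab", "n_labs"), ("drug", "n_drugs"), ("code", "n_codes")):
        w = windows.get(kind, 12)
        sel = ev[(ev["kind"].to_numpy() == kind) & (m <= t) & (m > t - w)]
        cnt = sel.groupby("patient_id").size()
        out[col] = cnt.reindex(cohort["patient_id"]).fillna(0).to_numpy(int)
    return out
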