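"""Post-threshold outcome definitions.

Adherence is percent days covered (PDC): total days of statin supplied (any
statin) divided by days of follow-up, capped at 1; a patient is adherent
when PDC > 0.8. A follow-up PDC variant drops the first prescription's
pills and starts the clock when that first supply runs out. Lipid response
compares the last pre-threshold value to the first value at least two
months after threshold. Cardiovascular hospitalization outcomes are the
first in-group coded event after threshold, censored at end of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AdherenceOutcome", "compute_pdc", "pdc_day_oracle",
           "coverage_pdc_oracle", "adherence_outcomes", "lipid_change",
           "event_outcomes", "EVENT_GROUPS"]

DAYS_PER_MONTH = 30
ADHERENT_THRESHOLD = 0.8
EVENT_GROUPS = ("MI", "stroke", "CAD", "kidney")


@dataclass
class AdherenceOutcome:
    pdc: float
    adherent: bool
    first_refill: bool
    followup_pdc: float | None    # None iff the post-first-supply window is empty
    followup_days: int


def compute_pdc(fills, followup_days: int) -> AdherenceOutcome:
    """Adherence outcome from a statin fill schedule.

    Parameters
    ----------
    fills : sequence of (day, days_supply) with the threshold fill first
        (day 0). Month-indexed callers convert via 30 days/month.
    followup_days : observation span from threshold, >= 365.

    ``pdc = min(1, sum(days_supply) / followup_days)`` — the literal supplied
    -days ratio, not a union of covered days (see ``coverage_pdc_oracle`` for
    the difference on overlapping schedules). ``followup_pdc`` applies the
    same ratio to fills after the first, over the window that starts when the
    first supply ends.
    """
    fills = list(fills)
    if not fills:
        raise ValueError("at least the threshold fill is required")
    if any(d < 0 for _, d in fills):
        raise ValueError("negative days_supply")
    if fills[0][0] != 0:
        raise ValueError("first fill must be at day 0 (the threshold)")
    total = sum(d for _, d in fills)
    pdc = min(1.0, total / followup_days)
    first_supply = fills[0][1]
    later = fills[1:]
    first_refill = len(later) > 0
    window = followup_days - first_supply
    if window <= 0:
        followup_pdc = None
    else:
        followup_pdc = min(1.0, sum(d for _, d in later) / window)
    return AdherenceOutcome(pdc=pdc, adherent=pdc > ADHERENT_THRESHOLD,
                            first_refill=first_refill,
                            followup_pdc=followup_pdc,
                            followup_days=int(followup_days))


def pdc_day_oracle(fills, followup_days: int) -> float:
    """Brute-force day-by-day enumeration of the supplied-days PDC ratio.

    Walks every individual supplied day of every fill and counts it, then
    divides by the follow-up span and caps at 1. Independent of
    :func:`compute_pdc`'s arithmetic; used as its test oracle.
    """
    covered = 0
    for _day, supply in fills:
        for _ in range(int(supply)):
            covered += 1
    return min(1.0, covered / followup_days)


def coverage_pdc_oracle(fills, followup_days: int) -> float:
    """Day-coverage PDC with pill carry-over, for documentation/contrast.

    Simulates a pill stock consumed one per day from each fill's date (fills
    arriving while stock remains are banked) and counts days with stock
    inside [0, followup_days). On schedules with no overlap and no supply
    running past the follow-up end this equals the supplied-days ratio;
    otherwise it is smaller.
    """
    stock = 0.0
    covered = 0
    schedule = sorted(fills)
    idx = 0
    for day in range(int(followup_days)):
        while idx < len(schedule) and schedule[idx][0] <= day:
            stock += schedule[idx][1]
            idx += 1
        if stock > 0:
            covered += 1
            stock -= 1
    return covered / followup_days


def adherence_outcomes(claims: pd.DataFrame, cohort: pd.DataFrame,
                       statin_codes) -> pd.DataFrame:
    """Vectorized per-patient adherence outcomes for a whole cohort.

    Fill days are ``30 * (month - threshold)``; follow-up span is the
    cohort's ``followup_days``. Fills after the end of follow-up are ignored.
    Returns a frame indexed by patient_id with columns pdc, adherent,
    first_refill, followup_pdc, followup_days.
    """
    info = cohort.set_index("patient_id")[["threshold_month", "followup_days"]]
    fills = claims[(claims["kind"] == "drug")
                   & claims["code"].isin(set(statin_codes))
                   & claims["patient_id"].isin(info.index)].copy()
    t = info["threshold_month"].reindex(fills["patient_id"]).to_numpy()
    fu = info["followup_days"].reindex(fills["patient_id"]).to_numpy()
    day = (fills["month"].to_numpy() - t) * DAYS_PER_MONTH
    fills = fills[(day >= 0) & (day <= fu)]
    day = day[(day >= 0) & (day <= fu)]
    fills = fills.assign(day=day)

    g = fills.groupby("patient_id")
    total = g["days_supply"].sum()
    n_fills = g.size()
    first_supply = fills.sort_values("day", kind="stable") \
        .drop_duplicates("patient_id", keep="first").set_index("patient_id")["days_supply"]

    out = pd.DataFrame(index=info.index)
    fu_days = info["followup_days"].astype(float)
    out["pdc"] = np.minimum(1.0, total.reindex(info.index).fillna(0) / fu_days)
    out["adherent"] = out["pdc"] > ADHERENT_THRESHOLD
    out["first_refill"] = (n_fills.reindex(info.index).fillna(0) > 1)
    window = fu_days - first_supply.reindex(info.index).fillna(0)
    later = (total - first_supply).reindex(info.index).fillna(0)
    out["followup_pdc"] = np.where(window > 0,
                                   np.minimum(1.0, later / window.replace(0, np.nan)),
                                   np.nan)
    out["followup_days"] = info["followup_days"]
    return out


def lipid_change(claims: pd.DataFrame, cohort: pd.DataFrame,
                 analytes=("LDL", "TC"), min_gap_months: int = 2) -> pd.DataFrame:
    """Baseline-to-follow-up change per analyte.

    Baseline = last value at month <= threshold; follow-up = first value at
    month >= threshold + ``min_gap_months``. ``delta`` is follow-up minus
    baseline and ``decreased`` uses the strict inequality delta < 0. Missing
    whenever either side is absent.
    """
    thr = cohort.set_index("patient_id")["threshold_month"]
    labs = claims[(claims["kind"] == "lab") & claims["code"].isin(analytes)
                  & claims["patient_id"].isin(thr.index)].copy()
    t = thr.reindex(labs["patient_id"]).to_numpy()
    rel = labs["month"].to_numpy() - t
    labs = labs.assign(rel=rel).sort_values("rel", kind="stable")

    out = pd.DataFrame(index=thr.index)
    for analyte in analytes:
        sub = labs[labs["code"] == analyte]
        base = sub[sub["rel"] <= 0].groupby("patient_id")["value"].last()
        post = sub[sub["rel"] >= min_gap_months].groupby("patient_id")["value"].first()
        out[f"{analyte}_baseline"] = base.reindex(thr.index)
        out[f"{analyte}_followup"] = post.reindex(thr.index)
        delta = out[f"{analyte}_followup"] - out[f"{analyte}_baseline"]
        out[f"{analyte}_delta"] = delta
        out[f"{analyte}_decreased"] = np.where(delta.isna(), np.nan,
                                               (delta < 0).astype(float))
    return out


def event_outcomes(claims: pd.DataFrame, cohort: pd.DataFrame,
                   group_map: dict, groups=EVENT_GROUPS,
                   composite_groups=("MI", "stroke", "CAD")) -> pd.DataFrame:
    """Time-to-first-hospitalization per diagnosis group, plus composite.

    ``group_map`` assigns each diagnosis code to exactly one group (a code in
    two groups is a configuration error). For each group the first in-group
    coded event strictly after threshold defines the event time in days
    (30 * months); patients without one are censored at ``followup_days``.
    The composite is the earliest event over ``composite_groups`` (the
    statin-responsive diagnoses). ``*_within_1yr`` flags events by day 365.
    """
    pairs = group_map.items() if isinstance(group_map, dict) else list(group_map)
    seen: dict = {}
    for code, grp in pairs:
        if code in seen and seen[code] != grp:
            raise ValueError(f"code {code} mapped to two groups")
        seen[code] = grp
    group_map = seen
    info = cohort.set_index("patient_id")[["threshold_month", "followup_days"]]
    ev = claims[(claims["kind"] == "code")
                & claims["code"].isin(group_map)
                & claims["patient_id"].isin(info.index)].copy()
    ev["group"] = ev["code"].map(group_map)
    t = info["threshold_month"].reindex(ev["patient_id"]).to_numpy()
    ev = ev[ev["month"].to_numpy() > t]
    t = info["threshold_month"].reindex(ev["patient_id"]).to_numpy()
    ev["day"] = (ev["month"].to_numpy() - t) * DAYS_PER_MONTH

    out = pd.DataFrame(index=info.index)
    fu = info["followup_days"].to_numpy(float)
    for grp in groups:
        first = ev[ev["group"] == grp].groupby("patient_id")["day"].min()
        day = first.reindex(info.index).to_numpy(float)
        event = ~np.isnan(day) & (day <= fu)
        time = np.where(event, day, fu)
        out[f"{grp}_event"] = event
        out[f"{grp}_time_days"] = time
        out[f"{grp}_within_1yr"] = event & (time <= 365)
    comp_time = np.min([out[f"{g}_time_days"].to_numpy() for g in composite_groups], axis=0)
    comp_event = np.any([(out[f"{g}_event"] & (out[f"{g}_time_days"] == comp_time)).to_numpy()
                         for g in composite_groups], axis=0)
    out["composite_event"] = comp_event
    out["composite_time_days"] = comp_time
    out["composite_within_1yr"] = comp_event & (comp_time <= 365)
    # the risk-model label additionally folds in kidney disease
    all_time = np.min([out[f"{g}_time_days"].to_numpy() for g in groups], axis=0)
    all_event = np.any([(out[f"{g}_event"] & (out[f"{g}_time_days"] == all_time)).to_numpy()
                        for g in groups], axis=0)
    out["any_event"] = all_event
    out["any_time_days"] = all_time
    out["any_within_1yr"] = all_event & (all_time <= 365)
    return out
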