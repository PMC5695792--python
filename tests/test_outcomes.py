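"""PDC and its day-enumeration oracle; lipid change; event outcomes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from statinadh.outcomes import (adherence_outcomes, compute_pdc,
                                coverage_pdc_oracle, event_outcomes,
                                lipid_change, pdc_day_oracle)

from conftest import toy_claims


def test_single_fill_no_refill():
    out = compute_pdc([(0, 30)], 365)
    assert out.pdc == pytest.approx(30 / 365)
    assert not out.first_refill and not out.adherent
    assert out.followup_pdc == 0.0


def test_full_monthly_coverage_is_adherent():
    fills = [(30 * m, 30) for m in range(13)]
    out = compute_pdc(fills, 390)
    assert out.pdc == 1.0 and out.adherent and out.first_refill


def test_quarterly_90_day_fills_cover_exactly():
    out = compute_pdc([(0, 90), (90, 90), (180, 90), (270, 90)], 360)
    assert out.pdc == 1.0
    # and the oracle agrees: the ratio needs no double counting here
    assert pdc_day_oracle([(0, 90), (90, 90), (180, 90), (270, 90)], 360) == 1.0


def test_adherent_iff_pdc_above_080_boundary():
    # exactly 0.8 is NOT adherent (strict inequality)
    out = compute_pdc([(0, 292)], 365)
    assert out.pdc == pytest.approx(0.8)
    assert not out.adherent


def test_errors_on_bad_schedules():
    with pytest.raises(ValueError):
        compute_pdc([(0, -30)], 365)
    with pytest.raises(ValueError):
        compute_pdc([], 365)
    with pytest.raises(ValueError):
        compute_pdc([(10, 30)], 365)


@st.composite
def fill_schedules(draw):
    followup = draw(st.integers(365, 1500))
    n_later = draw(st.integers(0, 12))
    fills = [(0, draw(st.sampled_from([30, 60, 90, 180])))]
    for _ in range(n_later):
        fills.append((draw(st.integers(1, followup)),
                      draw(st.sampled_from([30, 60, 90]))))
    return sorted(fills), followup


@settings(max_examples=300, deadline=None, derandomize=True)
@given(fill_schedules())
def test_pdc_matches_day_enumeration_oracle(sched):
    fills, followup = sched
    assert compute_pdc(fills, followup).pdc == pytest.approx(
        pdc_day_oracle(fills, followup), abs=1e-12)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(fill_schedules())
def test_adding_a_fill_never_decreases_pdc(sched):
    fills, followup = sched
    more = fills + [(min(followup - 1, 100), 30)]
    assert compute_pdc(sorted(more), followup).pdc >= compute_pdc(fills, followup).pdc


def test_coverage_oracle_documents_overlap_difference():
    # two 30-day fills on the same day: the supplied-days ratio counts 60,
    # the carry-over coverage oracle agrees (pills are banked) ...
    assert coverage_pdc_oracle([(0, 30), (0, 30)], 365) == pytest.approx(60 / 365)
    # ... but supply that runs past the end of follow-up differs
    fills = [(0, 30), (340, 180)]
    assert compute_pdc(fills, 365).pdc == pytest.approx(210 / 365)
    assert coverage_pdc_oracle(fills, 365) == pytest.approx(55 / 365)


def test_followup_pdc_equals_shifted_pdc_without_first_fill():
    rng = np.random.default_rng(0)
    for _ in range(200):
        followup = int(rng.integers(365, 1200))
        first = int(rng.choice([30, 60, 90, 180]))
        fills = [(0, first)]
        for _ in range(int(rng.integers(0, 8))):
            fills.append((int(rng.integers(first, followup)), 30))
        fills = sorted(fills)
        out = compute_pdc(fills, followup)
        shifted = [(d - first, s) for d, s in fills[1:]]
        window = followup - first
        expect = min(1.0, sum(s for _, s in shifted) / window) if window > 0 else None
        assert out.followup_pdc == pytest.approx(expect)


def test_vectorized_outcomes_match_scalar_path(small_sim):
    codes = ("STATIN_A", "STATIN_B", "STATIN_C")
    cohort = small_sim.truth[["patient_id", "threshold_month", "followup_days"]]
    out = adherence_outcomes(small_sim.claims, cohort, codes)
    fills = small_sim.claims[(small_sim.claims["kind"] == "drug")
                             & small_sim.claims["code"].isin(codes)]
    info = cohort.set_index("patient_id")
    rng = np.random.default_rng(1)
    for pid in rng.choice(cohort["patient_id"].to_numpy(), 25, replace=False):
        t = info.loc[pid, "threshold_month"]
        fu = info.loc[pid, "followup_days"]
        mine = fills[fills["patient_id"] == pid].sort_values("month")
        sched = [((m - t) * 30, int(d)) for m, d in
                 zip(mine["month"], mine["days_supply"])
                 if 0 <= (m - t) * 30 <= fu]
        ref = compute_pdc(sched, fu)
        assert out.loc[pid, "pdc"] == pytest.approx(ref.pdc)
        assert bool(out.loc[pid, "first_refill"]) == ref.first_refill
        assert out.loc[pid, "adherent"] == ref.adherent


def _lipid_cohort():
    return pd.DataFrame({"patient_id": ["p", "q", "r"], "threshold_month": 12})


def test_lipid_change_examples():
    claims = toy_claims([
        ("p", 11, "lab", "LDL", 160.0), ("p", 15, "lab", "LDL", 120.0),
        ("q", 13, "lab", "LDL", 120.0),                   # only +1 month: missing
        ("r", 11, "lab", "LDL", 130.0), ("r", 14, "lab", "LDL", 130.0),
    ])
    out = lipid_change(claims, _lipid_cohort(), analytes=("LDL",))
    assert out.loc["p", "LDL_delta"] == -40.0
    assert out.loc["p", "LDL_decreased"] == 1.0
    assert np.isnan(out.loc["q", "LDL_delta"])
    assert out.loc["r", "LDL_decreased"] == 0.0          # strict inequality


GROUP_MAP = {"DX_MI": "MI", "DX_STROKE": "stroke", "DX_CAD": "CAD",
             "DX_KIDNEY": "kidney"}


def _event_cohort(pids):
    return pd.DataFrame({"patient_id": pids, "threshold_month": 12,
                         "followup_days": 1500})


def test_event_outcomes_examples():
    claims = toy_claims([
        ("p", 18, "code", "DX_MI", None),                # +6 months
        ("q", 32, "code", "DX_STROKE", None),            # +20 months
        ("q", 16, "code", "DX_MI", None),                # +4 months
    ])
    out = event_outcomes(claims, _event_cohort(["p", "q", "r"]), GROUP_MAP)
    assert out.loc["p", "MI_event"] and out.loc["p", "MI_time_days"] == 180
    assert out.loc["p", "MI_within_1yr"]
    assert out.loc["q", "composite_time_days"] == 120    # min over groups
    assert not out.loc["r", "MI_event"]
    assert out.loc["r", "composite_time_days"] == 1500   # censored at follow-up
    assert out.loc["r", "composite_time_days"] <= out.loc["r", "MI_time_days"] + 1e-9


def test_event_code_in_two_groups_is_config_error():
    with pytest.raises(ValueError):
        event_outcomes(toy_claims([]), _event_cohort(["p"]),
                       [("DX_MI", "MI"), ("DX_MI", "stroke")])
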