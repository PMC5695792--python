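"""Synthetic pharmacy-claims cohort generator with recorded ground truth.

Emulates the statistical structure a claims-based statin-adherence analysis
assumes: month-truncated event dates, a per-patient threshold month (first
statin fill), baseline code/drug/lab events whose co-occurrence arises from
nonnegative latent patient phenotypes (so the baseline count matrix has a
known low nonnegative rank), post-threshold statin refills driven by a
logistic adherence propensity, LDL trajectories that respond to realized
adherence, and censored cardiovascular hospitalization times whose hazard
depends on disease burden and adherence.

Ground truth (latent intensities, adherence propensity, realized adherence,
hazard multiplier) is returned alongside the claims so every downstream
stage has a parameter-recovery oracle; pipeline stages never see it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimResult",
    "generate_cohort",
    "STATIN_CODES",
    "EVENT_GROUP_CODES",
    "NAMED_ANALYTES",
]

#: Synthetic statin drug tokens (stand-ins for an NDC-based statin list).
STATIN_CODES = ("STATIN_A", "STATIN_B", "STATIN_C")

#: Hospitalization diagnosis tokens mapped to outcome groups (stand-in for an
#: ICD-based hospitalization code list).
EVENT_GROUP_CODES = {
    "DX_MI": "MI",
    "DX_STROKE": "stroke",
    "DX_CAD": "CAD",
    "DX_KIDNEY": "kidney",
}

#: Named analytes; the first carries the statin-responsive lipid signal.
NAMED_ANALYTES = ("LDL", "TC", "HDL", "TRIG", "CREAT", "CK")

_ANALYTE_MEAN = {"LDL": 140.0, "TC": 210.0, "HDL": 50.0, "TRIG": 150.0,
                 "CREAT": 1.0, "CK": 120.0}
_ANALYTE_SD = {"LDL": 25.0, "TC": 30.0, "HDL": 12.0, "TRIG": 60.0,
               "CREAT": 0.2, "CK": 40.0}

#: Allowed first-fill durations (days) and their default sampling weights.
FIRST_SUPPLY_CHOICES = (30, 60, 90, 180)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model.

    Adherence propensity is ``logistic(adherence_intercept + sum_c w_c x_c)``
    where covariate names in ``adherence_coefficients`` refer to
    ``age_std`` ((age - 45)/12), ``sex_male``, ``tobacco`` (0/1) or
    ``factor_<j>`` (latent intensity j, standardized across patients).
    Event hazards are exponential with per-group baseline rate (per day)
    multiplied by ``exp(sum_j event_coefficients[j] * factor_j_std +
    adherence_event_coefficient * realized_adherence)``.
    """

    n_patients: int = 2000
    n_latent_factors: int = 10
    n_code_vars: int = 120
    n_drug_vars: int = 60
    n_lab_vars: int = 12
    months_baseline: int = 24
    months_followup: int = 60
    min_followup_months: int = 13
    adherence_intercept: float = -1.0
    adherence_coefficients: dict = field(default_factory=dict)
    event_coefficients: dict = field(default_factory=dict)
    adherence_event_coefficient: float = 0.0
    base_event_rate: float = 2e-4           # per day, per diagnosis group
    lipid_effect: float = 40.0              # mean LDL drop (mg/dL) per unit adherence
    lipid_noise_sd: float = 12.0            # sd of each LDL measurement error
    events_per_patient: float = 40.0        # mean baseline events per patient
    count_rate_scale: float = 1.0
    cross_loading_prob: float = 0.10        # chance a variable loads on a 2nd factor
    first_supply_probs: tuple = (0.5, 0.1, 0.3, 0.1)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients", "n_latent_factors", "n_code_vars",
                     "n_drug_vars", "n_lab_vars", "months_baseline",
                     "months_followup", "min_followup_months"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.months_followup < 12:
            raise ValueError("months_followup must be >= 12")
        if self.min_followup_months > self.months_followup:
            raise ValueError("min_followup_months exceeds months_followup")
        for name in ("base_event_rate", "lipid_noise_sd", "events_per_patient",
                     "count_rate_scale", "cross_loading_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative (rate/scale)")
        if self.n_lab_vars < len(NAMED_ANALYTES):
            raise ValueError(
                f"n_lab_vars must be >= {len(NAMED_ANALYTES)} (named analytes)")
        if len(self.first_supply_probs) != len(FIRST_SUPPLY_CHOICES):
            raise ValueError("first_supply_probs must have 4 entries")
        if abs(sum(self.first_supply_probs) - 1.0) > 1e-9 or min(self.first_supply_probs) < 0:
            raise ValueError("first_supply_probs must be a probability vector")


@dataclass
class SimResult:
    """Claims, demographics and hidden ground truth for one simulated cohort."""

    claims: pd.DataFrame
    demographics: pd.DataFrame
    truth: pd.DataFrame
    loadings: pd.DataFrame      # true variable x latent-factor rate loadings
    config: SimConfig

    @property
    def prescribing_window(self) -> tuple:
        t = self.truth["threshold_month"]
        return int(t.min()), int(t.max())


def _variable_names(config: SimConfig) -> pd.DataFrame:
    codes = [f"CODE_{i:04d}" for i in range(config.n_code_vars)]
    drugs = [f"RX_{i:04d}" for i in range(config.n_drug_vars)]
    labs = list(NAMED_ANALYTES) + [
        f"LAB_{i:04d}" for i in range(config.n_lab_vars - len(NAMED_ANALYTES))]
    names = codes + drugs + labs
    kinds = ["code"] * len(codes) + ["drug"] * len(drugs) + ["lab"] * len(labs)
    return pd.DataFrame({"name": names, "kind": kinds})


def _true_loadings(config: SimConfig, rng: np.random.Generator,
                   n_vars: int) -> np.ndarray:
    """Sparse nonnegative loading matrix (variables x latent factors)."""
    L = config.n_latent_factors
    W = np.zeros((n_vars, L))
    primary = rng.integers(0, L, size=n_vars)
    W[np.arange(n_vars), primary] = rng.gamma(3.0, 1.0, size=n_vars)
    cross = rng.random(n_vars) < config.cross_loading_prob
    if cross.any():
        other = (primary[cross] + rng.integers(1, L, size=int(cross.sum()))) % L
        W[np.where(cross)[0], other] = rng.gamma(1.0, 0.5, size=int(cross.sum()))
    return W


def _adherence_covariates(config: SimConfig, demographics: pd.DataFrame,
                          theta_std: np.ndarray) -> dict:
    cov = {
        "age_std": (demographics["age"].to_numpy(float) - 45.0) / 12.0,
        "sex_male": (demographics["sex"] == "M").to_numpy(float),
        "tobacco": demographics["tobacco"].to_numpy(float),
    }
    for j in range(config.n_latent_factors):
        cov[f"factor_{j}"] = theta_std[:, j]
    return cov


def generate_cohort(config: SimConfig) -> SimResult:
    """Simulate a claims cohort under ``config``; deterministic in the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pid = np.array([f"P{i:06d}" for i in range(n)])

    # demographics
    age = np.clip(np.round(rng.normal(50, 9, size=n)), 18, 65).astype(int)
    demographics = pd.DataFrame({
        "patient_id": pid,
        "age": age,
        "sex": rng.choice(["M", "F"], size=n),
        "race": rng.choice(["white", "black", "asian", "other"], size=n,
                           p=[0.6, 0.2, 0.1, 0.1]),
        "tobacco": rng.random(n) < 0.25,
        "pharmacy_program": rng.choice(["retail", "mail", "mtf"], size=n,
                                       p=[0.5, 0.2, 0.3]),
    })

    # threshold months: data collection starts at absolute month 0; every
    # patient has a full baseline history before threshold
    m0 = config.months_baseline
    threshold = rng.integers(m0, m0 + 24, size=n)

    # latent phenotype intensities and baseline event rates
    theta = rng.gamma(1.5, 1.0, size=(n, config.n_latent_factors))
    variables = _variable_names(config)
    W = _true_loadings(config, rng, len(variables))
    rates = theta @ W.T
    mean_total = rates.sum(axis=1).mean()
    scale = config.events_per_patient / max(mean_total, 1e-12)
    W = W * scale                       # fold the calibration into the truth
    rates = rates * scale * config.count_rate_scale
    counts = rng.poisson(rates)

    theta_sd = theta.std(axis=0)
    theta_sd[theta_sd == 0] = 1.0
    theta_std = (theta - theta.mean(axis=0)) / theta_sd

    # adherence propensity and realized refills
    cov = _adherence_covariates(config, demographics, theta_std)
    eta = np.full(n, config.adherence_intercept, float)
    for name, w in config.adherence_coefficients.items():
        if name not in cov:
            raise ValueError(f"unknown adherence covariate: {name}")
        eta += w * cov[name]
    propensity = 1.0 / (1.0 + np.exp(-eta))

    followup_months = rng.integers(config.min_followup_months,
                                   config.months_followup + 1, size=n)
    max_fm = int(followup_months.max())
    refill_u = rng.random((n, max_fm))  # decision for months 1..max_fm
    refill = refill_u < propensity[:, None]
    month_grid = np.arange(1, max_fm + 1)
    opportunity = month_grid[None, :] < followup_months[:, None]  # months 1..fm-1
    refill &= opportunity
    n_opp = opportunity.sum(axis=1)
    realized = np.where(n_opp > 0, refill.sum(axis=1) / np.maximum(n_opp, 1), 0.0)

    first_supply = rng.choice(FIRST_SUPPLY_CHOICES, size=n,
                              p=np.asarray(config.first_supply_probs, float))
    statin_code = rng.choice(STATIN_CODES, size=n, p=[0.5, 0.3, 0.2])

    # cardiovascular event times: exponential clocks per diagnosis group
    log_mult = np.zeros(n)
    for j, w in config.event_coefficients.items():
        j = int(j)
        if not 0 <= j < config.n_latent_factors:
            raise ValueError(f"event coefficient for unknown factor {j}")
        log_mult += w * theta_std[:, j]
    log_mult += config.adherence_event_coefficient * realized
    hazard_mult = np.exp(log_mult)
    followup_days = followup_months * 30

    frames = []

    # --- baseline events from the Poisson-factor model ---------------------
    p_idx, v_idx = np.nonzero(counts)
    reps = counts[p_idx, v_idx]
    p_e = np.repeat(p_idx, reps)
    v_e = np.repeat(v_idx, reps)
    offs = rng.integers(-(m0 - 1), 1, size=p_e.size)
    base = pd.DataFrame({
        "patient_id": pid[p_e],
        "month": threshold[p_e] + offs,
        "kind": variables["kind"].to_numpy()[v_e],
        "code": variables["name"].to_numpy()[v_e],
    })
    kind_e = base["kind"].to_numpy()
    value = np.full(p_e.size, np.nan)
    lab_mask = kind_e == "lab"
    if lab_mask.any():
        lab_codes = base.loc[lab_mask, "code"]
        mu = lab_codes.map(lambda c: _ANALYTE_MEAN.get(c, 1.0)).to_numpy(float)
        sd = lab_codes.map(lambda c: _ANALYTE_SD.get(c, 0.2)).to_numpy(float)
        value[lab_mask] = mu + sd * rng.standard_normal(int(lab_mask.sum()))
    base["value"] = value
    days_supply = np.full(p_e.size, np.nan)
    drug_mask = kind_e == "drug"
    days_supply[drug_mask] = 30.0
    base["days_supply"] = days_supply
    base["strength"] = np.where(drug_mask, 10.0, np.nan)
    frames.append(base)

    # --- forced baseline LDL at the threshold month (appended after the
    # random labs so it is the most recent pre-threshold value) -------------
    ldl_base = rng.normal(_ANALYTE_MEAN["LDL"], 20.0, size=n) \
        + config.lipid_noise_sd * rng.standard_normal(n)
    frames.append(pd.DataFrame({
        "patient_id": pid, "month": threshold, "kind": "lab", "code": "LDL",
        "value": ldl_base, "days_supply": np.nan, "strength": np.nan,
    }))

    # --- follow-up LDL responding to realized adherence --------------------
    post_off = np.array([3, 9])
    for off in post_off:
        keep = followup_months > off
        val = (ldl_base[keep] - config.lipid_effect * realized[keep]
               + config.lipid_noise_sd * rng.standard_normal(int(keep.sum())))
        frames.append(pd.DataFrame({
            "patient_id": pid[keep], "month": threshold[keep] + off,
            "kind": "lab", "code": "LDL", "value": val,
            "days_supply": np.nan, "strength": np.nan,
        }))

    # --- statin fills: threshold fill + monthly refills --------------------
    frames.append(pd.DataFrame({
        "patient_id": pid, "month": threshold, "kind": "drug",
        "code": statin_code, "value": np.nan,
        "days_supply": first_supply.astype(float), "strength": 20.0,
        "new_refill_flag": True,
    }))
    rp, rm = np.nonzero(refill)
    frames.append(pd.DataFrame({
        "patient_id": pid[rp], "month": threshold[rp] + rm + 1, "kind": "drug",
        "code": statin_code[rp], "value": np.nan,
        "days_supply": 30.0, "strength": 20.0, "new_refill_flag": False,
    }))

    # --- cardiovascular hospitalization codes ------------------------------
    event_time = {}
    for code, group in EVENT_GROUP_CODES.items():
        lam = config.base_event_rate * hazard_mult
        with np.errstate(divide="ignore"):
            t = rng.exponential(1.0 / np.maximum(lam, 1e-300))
        t = np.where(lam > 0, t, np.inf)
        event_time[group] = t
        hit = t < followup_days
        if hit.any():
            ev_month = threshold[hit] + np.maximum(
                1, np.ceil(t[hit] / 30.0).astype(int))
            frames.append(pd.DataFrame({
                "patient_id": pid[hit], "month": ev_month, "kind": "code",
                "code": code, "value": np.nan, "days_supply": np.nan,
                "strength": np.nan,
            }))

    # --- terminal encounter pinning each patient's last observed month -----
    frames.append(pd.DataFrame({
        "patient_id": pid, "month": threshold + followup_months,
        "kind": "code", "code": "ENC_VISIT", "value": np.nan,
        "days_supply": np.nan, "strength": np.nan,
    }))

    claims = pd.concat(frames, ignore_index=True)
    if "new_refill_flag" not in claims.columns:
        claims["new_refill_flag"] = np.nan
    claims["new_refill_flag"] = claims["new_refill_flag"].astype(object)
    # flag the first fill of each non-statin drug (first-ever fill per
    # patient/drug pair); statin flags were set explicitly above
    drug_rows = claims["kind"] == "drug"
    nonstatin = drug_rows & ~claims["code"].isin(STATIN_CODES)
    sub = claims.loc[nonstatin].sort_values("month", kind="stable")
    first_rows = sub.drop_duplicates(subset=["patient_id", "code"], keep="first").index
    claims.loc[nonstatin, "new_refill_flag"] = False
    claims.loc[first_rows, "new_refill_flag"] = True
    claims["month"] = claims["month"].astype(int)

    truth = pd.DataFrame({
        "patient_id": pid,
        "threshold_month": threshold,
        "followup_months": followup_months,
        "followup_days": followup_days,
        "first_supply_days": first_supply,
        "propensity": propensity,
        "realized_adherence": realized,
        "hazard_multiplier": hazard_mult,
    })
    for j in range(config.n_latent_factors):
        truth[f"factor_{j}"] = theta[:, j]

    loadings = pd.DataFrame(W, index=variables["name"],
                            columns=[f"factor_{j}" for j in range(config.n_latent_factors)])
    return SimResult(claims=claims, demographics=demographics, truth=truth,
                     loadings=loadings, config=config)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed (convenience for replicates)."""
    return replace(config, seed=int(seed))
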