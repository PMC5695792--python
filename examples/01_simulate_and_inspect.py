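"""Generate a synthetic claims cohort and look at its structure.

The simulator emits month-truncated claim events (drug fills, lab results,
diagnostic codes) for a cohort of statin initiators, together with the
hidden ground truth (latent phenotype intensities, adherence propensity,
realized adherence, event-hazard multiplier) that downstream stages try to
recover.
"""

from statinadh.simulate import SimConfig, generate_cohort

cfg = SimConfig(
    n_patients=1000,
    adherence_intercept=-0.5,                      # baseline refill log-odds
    adherence_coefficients={"age_std": 0.8},       # older patients adhere more
    adherence_event_coefficient=-0.4,              # adherence protects
    seed=7,
)
sim = generate_cohort(cfg)

print(f"claims rows: {len(sim.claims)}")
print(sim.claims["kind"].value_counts().to_string())
print("\nfirst few claim events:")
print(sim.claims.head(5).to_string(index=False))
print("\nground truth (hidden from the pipeline):")
print(sim.truth[["propensity", "realized_adherence"]].describe()
      .loc[["mean", "std"]].round(3).to_string())
# realized adherence tracks the logistic propensity: each follow-up month is
# an independent refill decision at that probability
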