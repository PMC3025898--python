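"""Recovering a planted risk factor for non-persistence.

Plants a log hazard ratio of 0.5 on the daily discontinuation hazard for
patients initiating with human (rather than analog) insulin, simulates
5,000 patients, classifies 12-month persistence with the gap rule, and fits
a logistic regression.  The fitted odds ratio should be well below 1: human
initiation predicts non-persistence, matching the planted effect's sign.
"""

from rxpersist import SimulationConfig, fit_persistence_model, \
    simulate_persistence_sample

config = SimulationConfig(
    discontinuation_hazard=1 / 600,
    covariate_effects={"index_human": 0.5},  # hazard ratio exp(0.5) ~ 1.65
)
sample = simulate_persistence_sample(config, n=5000, seed=42)

rates = sample.groupby("index_human")["persistent_m1_12m"].mean()
print(f"12-month gap-rule persistence: analog {rates[0]:.1%}, "
      f"human {rates[1]:.1%}")

result = fit_persistence_model(sample, sample["persistent_m1_12m"],
                               covariate_names=["index_human"])
row = result.row("index_human")
print(f"fitted OR for human initiation: {row['odds_ratio']:.3f} "
      f"(95% CI {row['ci_low']:.3f}, {row['ci_high']:.3f}; "
      f"p = {row['p_value']:.2g})")
print("OR < 1: initiating with human insulin lowers the odds of remaining"
      "\npersistent at 12 months, recovering the planted hazard effect.")
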