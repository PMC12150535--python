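"""Generate a seeded synthetic cohort and inspect its structure.

The generator emulates a three-exam prospective cohort (exams ~10 years
apart, baseline ages 35-56) with four incident-diabetes subtype groups and
a diabetes-free control group, piecewise-linear latent biomarker
trajectories broken at the classification exam, per-participant random
intercepts, and monotone dropout.
"""

from diatraj import SimulationConfig, simulate_cohort

config = SimulationConfig(seed=1).scaled(0.1)  # one tenth of the full design
participants, exams = simulate_cohort(config)

print(f"participants: {len(participants)}  exam records: {len(exams)}")
print("\ngroup sizes (generator truth):")
print(participants["group"].value_counts().to_string())
print("\nfirst exam records:")
print(exams.head(5).round(2).to_string(index=False))

cases = participants[participants["group"] != "control"]
print(
    f"\n{len(cases)} cases; diagnosis lag to classification exam is within "
    f"[0, 5] years by design (max drawn lag: "
    f"{(10 - (cases['diagnosis_time'] % 10)).max():.2f} y)."
)
print(
    "Each biomarker follows intercept + slope * time with the slope switching "
    "at the classification exam; controls follow a single calendar-time line."
)
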