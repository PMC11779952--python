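"""Score a dose adjustment in the TCP/NTCP outcome space.

Outcomes are read off a patient's dose-response curves by interpolation and
scored with the toxicity-free local control schema TCP * (1 - NTCP).
"""

from collabrt import (
    CohortConfig,
    Disease,
    SimulationConfig,
    generate_curves,
    interpolate_outcome,
    reward,
    score,
    total_eqd2,
)

cohort = CohortConfig.default(Disease.HCC)
curve = generate_curves(SimulationConfig.default(Disease.HCC, seed=5))[0]

un, aia = 10.0, 7.0  # an evaluator de-escalating from the 10 Gy/fx SOC
for label, dose in (("unassisted", un), ("AI-assisted", aia)):
    p = interpolate_outcome(curve, dose)
    print(f"{label:12s} {dose:4.1f} Gy/fx -> TCP {p.tcp:.4f}, NTCP {p.ntcp:.4f}, "
          f"score {score(p):.4f}, reward {reward(p, cohort):.4f}, "
          f"EQD2 {total_eqd2(dose, cohort.adaptation_fractions):.1f} Gy")
print("\nA higher score means better odds of tumor control without toxicity;")
print("the reward adds +1/+2 bonuses when the computational/clinical goals are met.")
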