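"""Generate a synthetic evaluation study and look at evaluator behavior.

The generator emulates a two-phase study: each evaluator first prescribes a
dose unassisted, then re-decides after seeing the AI recommendation and the
TCP/NTCP outcome display.
"""

from collabrt import Disease, SimulationConfig, adjustment_frequency, generate_study

config = SimulationConfig.default(Disease.NSCLC, seed=7)
study = generate_study(config)

freq = adjustment_frequency(study.records)
print(f"records: {len(study.records)} "
      f"({config.cohort.n_patients} patients x {config.cohort.n_evaluators} evaluators)")
print(f"decisions adjusted after AI assistance: {freq.count}/{freq.total} "
      f"({freq.percent:.0f}%)")
print(study.truth_frame().to_string(index=False))
print("\nbeliever=False rows are sceptics who never move from their unassisted")
print("decision; influence_weight is how far a believer shifts toward the AI.")
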