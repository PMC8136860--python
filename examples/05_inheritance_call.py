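"""Classify the inheritance mode of a mutation, end to end.

A wt/het/hom cohort is simulated with an overdominant walking-speed
pattern (het fastest, hom slowest), a dominant fixation pattern (het and
hom fixate equally strongly) and a declining sugar-response pattern, then
analysed: metrics -> statistics -> one inheritance-mode call per metric.
The same locus earns different calls for different phenotypes —
differential dominance.
"""

import buridan as b

config = b.SimulationConfig(duration=300.0, seed=11, n_flies_per_group=60)
effects = b.differential_dominance_effects()
cohort = b.simulate_cohort(config, effects)
per = b.simulate_per_cohort(effects, 60, seed=11)

result = b.analyze_experiment(cohort, config.arena, per_table=per)
for metric, call in result.calls.items():
    print(f"{metric}: {call.mode}")
    print(f"  {call.sentence}")
print()
print(b.render_report(result))
# Expected calls: overdominant walking speed, dominant stripe deviation,
# and (at these effect sizes) an intermediate sugar-response pattern.
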