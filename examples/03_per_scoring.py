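"""Score sugar responsiveness from proboscis-extension series.

Each fly sees water (0 %), six sucrose concentrations (0.1-30 %) on the
tarsi, and a final 30 % stimulation of the proboscis itself. Flies that
respond to water or ignore the proboscis stimulation are excluded; the
rest score 0-6 responses.
"""

import buridan as b

record = b.PERRecord("fly1", "wt", (False, False, False, True, True, True, True, True))
score = b.score_fly(record)
print(f"single fly: score {score.score} of 6, excluded={score.excluded}")

effects = [
    b.GenotypeEffect(label="wt", per_half_conc=0.6),
    b.GenotypeEffect(label="mutant", per_half_conc=20.0),
]
table = b.simulate_per_cohort(effects, n=40, seed=7)
scores, vectors, exclusion_counts, warnings = b.score_cohort(table)
print(f"exclusions: {exclusion_counts}")
for genotype, values in vectors.items():
    print(f"{genotype}: n={len(values)}, median score {sorted(values)[len(values)//2]:.0f}")
# The mutant's dose curve is shifted to higher concentrations, so its
# retained flies respond to fewer of the six stimulations.
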