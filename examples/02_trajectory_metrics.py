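"""Compute the two Buridan measures for a simulated cohort.

Median walking speed (after excluding > 50 mm/s jump frames) is the
temporal measure; stripe deviation — the median angle between the velocity
vector and the vector to the frontal stripe — is the spatial fixation
measure: the smaller it is, the more tightly the fly fixates the stripes.
"""

import buridan as b

config = b.SimulationConfig(duration=120.0, seed=3, n_flies_per_group=12)
effects = [
    b.GenotypeEffect(label="weak_fixation", fixation_kappa=0.5),
    b.GenotypeEffect(label="strong_fixation", fixation_kappa=8.0),
]
cohort = b.simulate_cohort(config, effects)
per_fly, groups, exclusions = b.cohort_metrics(cohort, config.arena)

print(per_fly.head(4).to_string(index=False))
print()
for _, row in groups.iterrows():
    print(
        f"{row['genotype']}: speed {row['speed_mean']:.1f} ± {row['speed_sem']:.2f} "
        f"mm/s (mean ± SEM), stripe deviation median {row['deviation_median']:.1f}°"
    )
# The strongly fixating group shows a much smaller stripe deviation at the
# same walking speed: the two measures separate spatial and temporal control.
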