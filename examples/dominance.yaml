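# Dominance-series demo: wild type vs heterozygous vs homozygous mutant.
# Short sessions and small groups keep the demo quick; raise duration to 300
# and n_flies_per_group to 60 for a full-scale experiment.
seed: 42
design: dominance_triplet
alpha: 0.005
repeat_k: 2
arena:
  platform_radius: 58.5
  stripe_distance: 146.5
  stripe_width: 30
  stripe_height: 320
simulation:
  dt: 0.05
  duration: 60
  n_flies_per_group: 12
per_n: 30
genotypes:
  - label: wt
    role: wt
    speed_mean: 12.0
    fixation_kappa: 1.5
    per_half_conc: 0.6
  - label: het
    role: het
    speed_mean: 14.4
    fixation_kappa: 4.0
    per_half_conc: 3.0
  - label: hom
    role: hom
    speed_mean: 7.0
    fixation_kappa: 4.0
    per_half_conc: 20.0
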