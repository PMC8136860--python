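# buridan

Behavioral-genetics analysis for *Drosophila* walking and taste assays:
Buridan's-paradigm trajectory metrics, proboscis-extension-response (PER)
scoring, the accompanying group-comparison statistics, and the categorical
genetic calls built on them — inheritance mode (including overdominance)
and transgenic-rescue outcome. A synthetic cohort generator with the same
statistical structure makes the whole pipeline runnable and testable
without any recorded data.

## Who this is for

Labs quantifying fly locomotion in Buridan's paradigm (a wing-clipped fly
walking on a water-surrounded platform between two opposing black stripes)
and sugar sensitivity via PER, who want a reproducible path from tracked
centroid positions and stimulus-response tables to letter-annotated group
comparisons and defensible categorical calls.

## What it computes

**Walking speed.** For consecutive tracked positions within a segment,
instantaneous speed is `v_i = ‖x_{i+1} − x_i‖ / (t_{i+1} − t_i)` (mm/s).
Speeds above 50 mm/s are ballistic jumps and are excluded; the per-fly
statistic is the median of retained speeds, and groups are summarised as
mean ± SEM of per-fly medians.

**Stripe deviation.** Per moving frame (speed ≥ 1 mm/s and ≤ 50 mm/s), the
absolute angle between the velocity vector **v** and the vector **s** from
the fly to the frontal stripe's centre, `θ = |atan2(v×s, v·s)|`, where the
frontal stripe is the angle-minimising one of the two. The per-fly summary
is the median frame angle in degrees; small values mean tight fixation.

**PER score.** Each fly receives water (0 %), six sucrose tarsal
stimulations (0.1, 0.3, 0.6, 1, 3, 30 %), and a final 30 % proboscis
stimulation. Flies responding to water, or not responding to the proboscis
stimulation, are excluded; retained flies score the number of sucrose
responses (0–6, ordinal).

**Statistics.** Per-group Shapiro–Wilk tests (p < 0.05) gate the branch:
parametric (two-way ANOVA + Tukey HSD when a second design factor exists,
one-way otherwise; Welch's *t* for two groups) or nonparametric (all-pairs
Wilcoxon rank-sum with Bonferroni correction over the pairs). Speed and
stripe deviation are two measurements of one session, so their p-values are
additionally multiplied by 2. Significance is p < α with α = 0.005, and
groups get a compact letter display (shared letter ⇔ not significantly
different).

**Genetic calls.** From a wt/het/hom panel the inheritance mode is read off
the significance pattern and the heterozygote's position: recessive
(het ≈ wt), dominant (het ≈ hom, both ≠ wt), intermediate (het between,
different from both), overdominant/underdominant (het beyond wt or hom).
From a four-group rescue panel: FR (experimental ≠ both mutant controls,
≈ wt control), PR (≈ wt and ≈ at least one mutant control), NR otherwise;
mutually inconsistent mutant controls make the panel uninterpretable.

## Worked example

`examples/05_inheritance_call.py` simulates a 60-flies-per-genotype
dominance cohort (5-minute sessions at 20 Hz) and runs the full analysis:

```
median_speed_mm_s: overdominant
  het differs from both wt and hom and exceeds wt on the side opposite hom,
  indicating overdominant inheritance
stripe_deviation_deg: dominant
  het differs from wt but not from hom, indicating dominant inheritance
per_score: intermediate
  het differs from both wt and hom and lies between them, indicating
  intermediate inheritance
```

with, for walking speed,

```
| group | n | central tendency | letters |
|---|---|---|---|
| het | 60 | 14.1 | b |
| wt  | 60 | 11.7 | a |
| hom | 60 | 6.53 | c |
```

The heterozygote walks ~20 % faster than wild type while the homozygote is
slowest — all three pairs significant (distinct letters), so walking speed
is overdominant; stripe deviation drops identically in het and hom
(dominant); and the PER medians fall 3/2/1 across wt/het/hom. One locus,
three phenotypes, three different dominance relations: differential
dominance.

The other examples cover the generator (01), the trajectory metrics (02),
PER scoring (03), the statistics layer (04) and rescue classification (06).
A thin CLI wraps the same library:

```sh
buridan simulate --config examples/dominance.yaml --out run/
buridan analyze --config examples/dominance.yaml \
    --trajectories run/trajectories.csv --manifest run/cohort.csv \
    --per run/per.csv --out run/
buridan report --stats run/stats.json --calls run/calls.json
```

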