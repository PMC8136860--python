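# Methods

## The measurement model

A Buridan experiment tracks the centroid of a wing-clipped fly walking on
a circular platform (radius 58.5 mm) surrounded by water, with two black
stripes (30 mm wide, 320 mm tall) diametrically opposed 146.5 mm from the
platform centre. The tracker emits time-stamped x/y positions in mm in a
platform-centred frame; when a fly leaves the platform the tracker is
restarted, so a fly's record is an ordered list of non-overlapping
segments and no inter-sample speed is ever computed across a segment
boundary.

Two per-fly statistics summarise a session:

* **Median walking speed.** Inter-sample speeds within segments; speeds
  strictly above 50 mm/s are ballistic jumps and are excluded ("exceeding"
  is read as strict: exactly 50 mm/s is retained). A fly whose every frame
  is a jump raises an explicit no-valid-frames error and is excluded with
  a logged reason, never silently zeroed. Groups are summarised as
  mean ± SEM of the per-fly medians.
* **Stripe deviation.** Per frame, the absolute angle between the velocity
  vector and the vector from the fly's position (taken at the start of the
  step) to the centre of the frontal stripe; the frontal stripe is
  recomputed every frame as the one minimising that angle, which allows
  mid-walk target switches. Frames slower than 1 mm/s carry no meaningful
  direction and are excluded (configurable movement threshold); jump
  frames are excluded likewise. The per-fly summary is the **median** of
  frame angles — chosen for robustness and consistency with the
  nonparametric treatment of this measure downstream; the mean is
  available behind a switch since either convention appears in trackers'
  analysis suites. Angles are radians internally, degrees in all outputs.

Positions are used exactly as read; no smoothing is applied by default, so
results match what the raw tracker output implies.

## The statistics scheme

Per metric, per-group Shapiro–Wilk tests at p < 0.05 decide the branch; a
group too small (< 3) or constant makes the test undefined and forces the
nonparametric branch with a warning. The branch decision and per-group
p-values are always logged.

* Parametric: Welch's *t* for two groups; otherwise Tukey HSD on the
  fitted linear model. When a second design factor (batch/treatment) is
  present the model is `y ~ group * batch` and its residual mean square
  studentises the pairwise group contrasts (Tukey–Kramer form for unequal
  n); without one, a one-way fit is used and a deviation note is logged.
  The one-way path reproduces statsmodels' `pairwise_tukeyhsd` to 1e-6
  (cross-checked in tests).
* Nonparametric: all-pairs two-sample Wilcoxon rank-sum (Mann–Whitney U,
  tie-corrected asymptotic) with Bonferroni correction over the pairs of
  the metric's family. "Paired" in the field's usual phrasing is read as
  *pairwise*: flies are independent, there is no pairing unit. A pair with
  zero combined variance reports p = 1 with a warning.
* Repeated-measurement correction: walking speed and stripe deviation are
  measured in the same session, so each pairwise p is multiplied by k = 2
  (capped at 1) — equivalent to halving α. PER scores come from a separate
  experiment and are never corrected this way. PER scores are ordinal, so
  only the nonparametric branch is offered for them.
* Significance is strict, p < α, with α = 0.005 by default.
* Compact letter display: insert-and-absorb. Start with one set holding
  all groups; for each significant pair split every set containing both;
  drop absorbed (subset or duplicate) sets; letter the survivors. The
  invariant — two groups share a letter iff not significantly different —
  is property-tested over random p-matrices; minimality of the letter
  count is not guaranteed.

Under null simulation (3 × 50 i.i.d. normal values, 1,000 replicates) the
family-wise significant-pair rate of both branches stays within
α + 3 Monte-Carlo SEs; this is recomputed by `scripts/acceptance.py`.

## The decision tables

**Inheritance** (wt/het/hom; sig = corrected p < α): a hom–wt difference
is required for any informative call, else *indeterminate*. Then:
*recessive* if het is not sig vs wt (an intermediate central tendency is
noted in the evidence but does not change the call — significance alone
decides); *dominant* if het is sig vs wt but not vs hom; if het is sig vs
both, the central tendency places the call: *intermediate* strictly
between wt and hom, *overdominant* beyond wt on the side opposite hom,
*underdominant* beyond hom, ties *indeterminate*. The tendency used is the
one the comparison itself reports: group mean on the parametric branch,
median on the nonparametric (matching bar-plot vs boxplot conventions).
No effect-size threshold is imposed beyond significance. Exhaustive
enumeration over all significance patterns × orderings shows the table is
total and disjoint (property test).

**Rescue** (wt control, two mutant controls, experimental): the
control-consistency check runs first — if the two mutant controls differ
significantly from each other (threshold configurable, default α) the
panel is *uninterpretable* regardless of the experimental group. Then
*FR* = sig vs both mutant controls and not sig vs wt; *PR* = not sig vs wt
and not sig vs at least one mutant control (the conjunction reading; the
disjunction reading — failing either of those — is available behind
`strict_pr=False` since the phrasing is genuinely ambiguous); *NR*
otherwise.

## The synthetic generator

Each fly is a discrete-time biased walk at dt = 0.05 s (20 Hz; typical for
centroid trackers, fine enough that displacement/dt approximates speed —
the frame rate is a free choice here, exposed in the config) for 300 s,
the conventional 5 minutes of uninterrupted walk.

* **Heading:** drawn fresh each step from a von Mises distribution centred
  on the direction to the currently targeted stripe, concentration
  `fixation_kappa` (kappa 0 → uniform). This is the minimal circular model
  with tunable fixation; it makes no claim about saccade structure or
  body-orientation/heading dissociation.
* **Step length:** speed × dt. Per-fly mean speed is normal across flies
  (CV `speed_cv_between_flies`, default 0.15, truncated positive);
  within-fly instantaneous speed is gamma (CV `speed_cv_within`, default
  0.3). With probability `pause_prob` (default 0.05) a step is a near-zero
  displacement; with probability `jump_rate·dt` (default rate 0.02 /s) it
  is a ballistic jump at `jump_speed` (default 80 mm/s > the 50 mm/s
  filter), so the jump filter is genuinely exercised.
* **Target switching:** when the fly comes within 5 mm of the platform
  edge on the targeted side, the target flips to the opposite stripe,
  producing the characteristic back-and-forth walk.
* **Boundary:** proposed positions outside the disc are clipped radially
  to the edge (the water-surrounded platform makes flies turn); the next
  step's heading is re-drawn as always. Clipping slightly shortens edge
  steps, which is why recovered group speeds sit a few percent below the
  configured `speed_mean` (within 10 % at 40 flies/condition; measured by
  the acceptance script).
* **Seeds:** per-fly streams derive from (master seed, group index, fly
  index) via `SeedSequence`, so enlarging a cohort never reshuffles
  earlier flies, and identical configs give byte-identical CSVs.
* **Tracker restarts:** optional `restart_rate` splits tracks into
  segments at random times so multi-segment handling is exercised; default
  0 (the analysis convention is 5 uninterrupted minutes).
* **PER:** response to water with probability 0.05 (false positives), to
  sucrose concentration c with probability
  `logistic(per_slope · (log10 c − log10 per_half_conc))`, to the final
  proboscis stimulation with probability 0.95 — the two exclusion rules
  both fire at realistic rates.

The default dominance cohort sets speeds 12/14.4/7 mm/s (het 20 % above
wt, hom slowest), fixation kappa 1.5/4/4 (mutants fixate more; dominant),
and PER half-concentrations 0.6/3/20 % (expected scores ≈ 3.3/2.3/1.3,
medians 3/2/1). The stepping loop is numba-compiled, with a pure-Python
reference stepper kept as its oracle in the tests.

**What the generator does not emulate:** tracker pixel noise and dropout,
body-orientation vs heading dissociation, saccadic turn structure,
thigmotaxis, activity bouts, genetic-background heterogeneity, or
between-batch variation (the two-factor ANOVA path is therefore exercised
on constructed batch labels, not on generator output). Passing tests show
the pipeline's operations and decision rules are correct on data with the
assumed statistical structure; they do not validate the walk model against
real fly kinematics.

## Problem sizes and numerics

Unit tests run seconds-long sessions; the acceptance suite and script use
full 5-minute sessions with 60 flies/group for classifier recovery
(100 replicates), 1,000 replicates for null calibration, and 40
flies/condition for the fixation dose-response — sizes at which every
Monte-Carlo criterion has comfortable margin. Angles are computed with
`atan2` (no arccos cancellation); p-values are clipped to [0, 1]; the
jump-filter boundary keeps exactly-50 mm/s frames; Shapiro–Wilk is taken
from scipy, Tukey's distribution from `scipy.stats.studentized_range`.

## Known limitations

* The walk model is phenomenological; kappa is not identifiable from real
  data without a model fit, and the generator's parameters are stated
  conditions, not inferred ones.
* The two-way ANOVA's second factor must be supplied by the caller; the
  pipeline's own simulated designs are single-factor, so the default path
  is the logged one-way deviation.
* Letter displays are not minimised; with many groups the assignment may
  use more letters than strictly necessary (the sharing invariant still
  holds).
* Exact-method Mann–Whitney p-values are not used (asymptotic with tie
  correction), which matters only for very small groups where the gate
  has already warned.
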