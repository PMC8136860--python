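"""Synthetic fly cohorts for Buridan's paradigm and the sugar-sensitivity test.

The generator produces data with the statistical structure the downstream
analysis assumes, so the whole pipeline is testable without any recorded
data. A fly is modelled as a biased correlated walk: at every time step it
draws a heading from a von Mises distribution centred on the direction to
the currently targeted stripe (concentration ``fixation_kappa``; kappa 0
means uniform headings, i.e. no fixation) and a step length from a gamma
speed distribution. Rare ballistic jumps and near-zero-displacement pauses
are superimposed. The target switches to the opposite stripe when the fly
closes in on the platform edge nearest its current target, producing the
back-and-forth walks characteristic of the paradigm. Positions are clipped
to the platform disc: the platform is surrounded by water, so flies turn at
the edge.

Sugar-response series are drawn per fly: one water (0 %) stimulation with a
small false-positive probability, six sucrose tarsal stimulations whose
response probability follows a logistic curve in log10 concentration, and a
final 30 % proboscis stimulation with a high response probability — so both
of the analysis's exclusion rules are exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

from .arena import ArenaGeometry
from .errors import ConfigError
from .trajectory import CohortTrajectorySet, Trajectory, TrajectorySegment

#: Sucrose tarsal stimulation concentrations (% w/v), in presentation order.
SUCROSE_CONCENTRATIONS: tuple[float, ...] = (0.1, 0.3, 0.6, 1.0, 3.0, 30.0)

#: Stimulus labels in the PER CSV dialect, in presentation order.
STIM_LABELS: tuple[str, ...] = (
    "water",
    "s0.1",
    "s0.3",
    "s0.6",
    "s1",
    "s3",
    "s30",
    "proboscis30",
)

#: Probability that a fly responds to the water-only (0 %) stimulation.
WATER_FALSE_POSITIVE_P = 0.05
#: Probability that a fly responds to the final 30 % proboscis stimulation.
PROBOSCIS_RESPONSE_P = 0.95

#: Distance from the platform edge (mm) at which the targeted stripe switches.
TARGET_SWITCH_MARGIN = 5.0


@dataclass(frozen=True)
class GenotypeEffect:
    """Behavioural parameters of one genotype.

    Parameters
    ----------
    label : str
        Genotype label, unique within a cohort.
    speed_mean : float
        Population-mean walking speed, mm/s.
    speed_cv_between_flies : float
        Coefficient of variation of per-fly mean speed across flies.
    fixation_kappa : float
        von Mises concentration of the heading bias toward the targeted
        stripe; 0 disables fixation entirely.
    jump_rate : float
        Ballistic-jump events per second.
    jump_speed : float
        Speed during a jump frame, mm/s; must exceed the 50 mm/s jump
        threshold so jumps are visible to the filter.
    pause_prob : float
        Per-step probability of a near-zero displacement.
    per_half_conc : float
        Sucrose concentration (% w/v) at which the response probability
        is 0.5.
    per_slope : float
        Logistic slope on log10 concentration.
    speed_cv_within : float
        Within-fly coefficient of variation of instantaneous speed.
    """

    label: str
    speed_mean: float = 12.0
    speed_cv_between_flies: float = 0.15
    fixation_kappa: float = 2.0
    jump_rate: float = 0.02
    jump_speed: float = 80.0
    pause_prob: float = 0.05
    per_half_conc: float = 0.6
    per_slope: float = 1.2
    speed_cv_within: float = 0.3

    def __post_init__(self) -> None:
        if not self.speed_mean > 0:
            raise ConfigError(f"{self.label}: speed_mean must be > 0")
        if self.fixation_kappa < 0:
            raise ConfigError(f"{self.label}: fixation_kappa must be >= 0")
        if not self.jump_speed > 50:
            raise ConfigError(f"{self.label}: jump_speed must exceed 50 mm/s")
        if not 0 <= self.pause_prob < 1:
            raise ConfigError(f"{self.label}: pause_prob must be in [0, 1)")
        if not self.per_half_conc > 0:
            raise ConfigError(f"{self.label}: per_half_conc must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings.

    ``duration`` defaults to 300 s: the analysis convention is 5 minutes of
    uninterrupted walk per fly. ``restart_rate`` emulates tracker restarts
    (events/s); each restart splits the track into a new segment.
    """

    dt: float = 0.05
    duration: float = 300.0
    seed: int = 0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    n_flies_per_group: int = 20
    restart_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ConfigError("dt must be > 0")
        if not self.duration > 0:
            raise ConfigError("duration must be > 0")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("duration must be a whole number of dt steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@njit(cache=False)
def _step_kernel(x0, y0, target0, head_dev, step_len, radius, sx, sy, margin):
    """Advance the biased walk; returns positions of n_steps+1 samples.

    ``target0`` is +1/-1 selecting the stripe at +-(sx, sy). Headings are
    the direction from the current position to the targeted stripe centre
    plus the pre-drawn deviation. Proposed positions outside the platform
    disc are clipped radially; reaching within ``margin`` of the edge on the
    targeted side flips the target.
    """
    n = head_dev.size
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    xs[0] = x0
    ys[0] = y0
    tgt = target0
    for i in range(n):
        px = xs[i]
        py = ys[i]
        ang = math.atan2(tgt * sy - py, tgt * sx - px) + head_dev[i]
        nx = px + step_len[i] * math.cos(ang)
        ny = py + step_len[i] * math.sin(ang)
        r = math.sqrt(nx * nx + ny * ny)
        if r > radius:
            nx *= radius / r
            ny *= radius / r
            r = radius
        xs[i + 1] = nx
        ys[i + 1] = ny
        if r >= radius - margin and (nx * tgt * sx + ny * tgt * sy) > 0.0:
            tgt = -tgt
    return xs, ys


def _step_reference(x0, y0, target0, head_dev, step_len, radius, sx, sy, margin):
    """Pure-Python twin of :func:`_step_kernel`; oracle for tests."""
    n = len(head_dev)
    xs = [0.0] * (n + 1)
    ys = [0.0] * (n + 1)
    xs[0], ys[0] = x0, y0
    tgt = target0
    for i in range(n):
        px, py = xs[i], ys[i]
        ang = math.atan2(tgt * sy - py, tgt * sx - px) + head_dev[i]
        nx = px + step_len[i] * math.cos(ang)
        ny = py + step_len[i] * math.sin(ang)
        r = math.sqrt(nx * nx + ny * ny)
        if r > radius:
            nx *= radius / r
            ny *= radius / r
            r = radius
        xs[i + 1], ys[i + 1] = nx, ny
        if r >= radius - margin and (nx * tgt * sx + ny * tgt * sy) > 0.0:
            tgt = -tgt
    return np.array(xs), np.array(ys)


def _draw_speeds(rng: np.random.Generator, effect: GenotypeEffect, dt: float, n: int):
    """Per-step speeds (mm/s): gamma base, pause and jump overrides."""
    z = rng.standard_normal()
    mu_fly = effect.speed_mean * max(1.0 + effect.speed_cv_between_flies * z, 0.05)
    cv = effect.speed_cv_within
    if cv > 0:
        shape = 1.0 / cv**2
        speeds = rng.gamma(shape, mu_fly / shape, n)
    else:
        speeds = np.full(n, mu_fly)
    pause = rng.random(n) < effect.pause_prob
    speeds[pause] = rng.uniform(0.0, 0.5, int(pause.sum()))
    jump = rng.random(n) < effect.jump_rate * dt
    speeds[jump] = effect.jump_speed
    return speeds


def simulate_trajectory(
    config: SimulationConfig,
    effect: GenotypeEffect,
    fly_seed: int | np.random.SeedSequence,
    fly_id: str | None = None,
) -> Trajectory:
    """Simulate one fly's 5-minute (by default) walk.

    All samples lie within the platform disc. With ``restart_rate`` > 0 the
    track is split into multiple segments at random restart times,
    emulating tracker restarts after the fly left the platform.
    """
    rng = np.random.default_rng(fly_seed)
    n = config.n_steps
    arena = config.arena
    kappa = effect.fixation_kappa
    if kappa > 0:
        head_dev = rng.vonmises(0.0, kappa, n)
    else:
        head_dev = rng.uniform(-math.pi, math.pi, n)
    step_len = _draw_speeds(rng, effect, config.dt, n) * config.dt
    r0 = arena.platform_radius * math.sqrt(rng.random())
    phi0 = rng.uniform(0.0, 2.0 * math.pi)
    target0 = 1 if rng.random() < 0.5 else -1
    sx, sy = arena.stripe_centers[0]
    xs, ys = _step_kernel(
        r0 * math.cos(phi0),
        r0 * math.sin(phi0),
        target0,
        head_dev,
        step_len,
        arena.platform_radius,
        sx,
        sy,
        TARGET_SWITCH_MARGIN,
    )
    t = np.arange(n + 1) * config.dt
    if config.restart_rate > 0:
        breaks = np.flatnonzero(rng.random(n - 1) < config.restart_rate * config.dt) + 1
    else:
        breaks = np.array([], dtype=int)
    bounds = [0, *breaks.tolist(), n + 1]
    segments = [
        TrajectorySegment(t[a:b], xs[a:b], ys[a:b])
        for a, b in zip(bounds, bounds[1:])
        if b > a
    ]
    return Trajectory(
        fly_id=fly_id or f"{effect.label}_fly",
        genotype=effect.label,
        segments=segments,
    )


def simulate_cohort(
    config: SimulationConfig, effects: list[GenotypeEffect]
) -> CohortTrajectorySet:
    """Simulate a multi-genotype cohort, ``n_flies_per_group`` flies each.

    Per-fly random streams derive from ``(config.seed, group index, fly
    index)`` via :class:`numpy.random.SeedSequence`, so enlarging a cohort
    never reshuffles the flies already simulated.
    """
    if not effects:
        raise ConfigError("at least one genotype effect is required")
    labels = [e.label for e in effects]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate genotype labels: {labels}")
    flies = []
    for gi, effect in enumerate(effects):
        for fi in range(config.n_flies_per_group):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(gi, fi))
            flies.append(
                simulate_trajectory(
                    config, effect, ss, fly_id=f"{effect.label}_{fi:03d}"
                )
            )
    return CohortTrajectorySet(flies=flies, group_labels=labels)


def per_response_probabilities(effect: GenotypeEffect) -> np.ndarray:
    """Response probability at each of the six sucrose concentrations."""
    logc = np.log10(np.array(SUCROSE_CONCENTRATIONS))
    return expit(effect.per_slope * (logc - math.log10(effect.per_half_conc)))


def simulate_per_cohort(
    effects: list[GenotypeEffect], n: int, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Simulate a sugar-response table: *n* flies per genotype.

    Returns a long-format table with columns ``fly_id, genotype,
    stim_label, response`` — eight rows per fly, in presentation order.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    labels = [e.label for e in effects]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate genotype labels: {labels}")
    rows: list[tuple[str, str, str, int]] = []
    for gi, effect in enumerate(effects):
        probs = per_response_probabilities(effect)
        for fi in range(n):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(gi, fi, 1))
            rng = np.random.default_rng(ss)
            resp = np.empty(8, dtype=int)
            resp[0] = rng.random() < WATER_FALSE_POSITIVE_P
            resp[1:7] = rng.random(6) < probs
            resp[7] = rng.random() < PROBOSCIS_RESPONSE_P
            fly_id = f"{effect.label}_{fi:03d}"
            rows.extend(
                (fly_id, effect.label, lab, int(r))
                for lab, r in zip(STIM_LABELS, resp)
            )
    return pd.DataFrame(rows, columns=["fly_id", "genotype", "stim_label", "response"])


def differential_dominance_effects() -> list[GenotypeEffect]:
    """Default dominance-series cohort: wild type, heterozygote, homozygote.

    Walking speed is overdominant (het fastest, hom slowest; het exceeds
    wild type by 20 %), stripe fixation is dominant (het and hom share the
    same elevated fixation), and sugar response declines from wild type to
    homozygote with expected score medians 3/2/1.
    """
    wt = GenotypeEffect(
        label="wt", speed_mean=12.0, fixation_kappa=1.5, per_half_conc=0.6
    )
    het = replace(wt, label="het", speed_mean=14.4, fixation_kappa=4.0, per_half_conc=3.0)
    hom = replace(wt, label="hom", speed_mean=7.0, fixation_kappa=4.0, per_half_conc=20.0)
    return [wt, het, hom]
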