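"""Per-fly Buridan measures: median walking speed and stripe deviation.

Walking speed is traveled distance over time between consecutive samples;
inter-sample speeds above 50 mm/s are treated as ballistic jumps and
excluded from the per-fly median. Stripe deviation is the angle between the
instantaneous velocity vector and the vector from the fly's position to the
centre of the frontal stripe — of the two stripes, the one yielding the
smaller angle. Small stripe deviation means tight fixation. Frames where the
fly is essentially at rest carry no usable velocity direction and are
excluded from the angle computation by a movement threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import ArenaGeometry
from .errors import NoValidFramesError
from .trajectory import CohortTrajectorySet, Trajectory

#: Speeds strictly above this (mm/s) are jumps, excluded from the median.
JUMP_THRESHOLD = 50.0
#: Frames slower than this (mm/s) are "at rest" for the angle computation.
MOVEMENT_THRESHOLD = 1.0


@dataclass
class FlyMetrics:
    """Per-fly summary of one Buridan session."""

    fly_id: str
    genotype: str
    median_speed: float
    stripe_deviation: float
    n_frames: int
    n_jump_frames: int
    n_moving_frames: int
    total_time: float


def frame_speeds(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous speeds between consecutive samples within segments.

    Returns ``(t, speed)`` where each speed is the Euclidean displacement
    over the time difference of a consecutive sample pair and ``t`` is the
    later sample's timestamp. No pair spans a segment boundary (tracker
    restarts).
    """
    ts, vs = [], []
    for seg in traj.segments:
        if seg.n_samples < 2:
            continue
        dt = np.diff(seg.t)
        v = np.hypot(np.diff(seg.x), np.diff(seg.y)) / dt
        ts.append(seg.t[1:])
        vs.append(v)
    if not ts:
        return np.array([]), np.array([])
    return np.concatenate(ts), np.concatenate(vs)


def median_speed(traj: Trajectory, jump_threshold: float = JUMP_THRESHOLD) -> float:
    """Median of retained inter-sample speeds, mm/s.

    Speeds strictly exceeding *jump_threshold* are jumps and excluded;
    a speed exactly at the threshold is retained.
    """
    _, v = frame_speeds(traj)
    kept = v[v <= jump_threshold]
    if kept.size == 0:
        raise NoValidFramesError(
            f"fly {traj.fly_id}: no non-jump frames for median speed"
        )
    return float(np.median(kept))


def _frontal_angles(
    traj: Trajectory,
    arena: ArenaGeometry,
    movement_threshold: float,
    jump_threshold: float,
) -> np.ndarray:
    """Per-moving-frame frontal-stripe deviation angles, radians."""
    centers = arena.stripe_centers
    out = []
    for seg in traj.segments:
        if seg.n_samples < 2:
            continue
        dt = np.diff(seg.t)
        dx = np.diff(seg.x)
        dy = np.diff(seg.y)
        speed = np.hypot(dx, dy) / dt
        moving = (speed >= movement_threshold) & (speed <= jump_threshold)
        if not moving.any():
            continue
        px = seg.x[:-1][moving]
        py = seg.y[:-1][moving]
        vx = dx[moving]
        vy = dy[moving]
        angles = []
        for cx, cy in centers:
            tx = cx - px
            ty = cy - py
            # |angle| between velocity and position-to-stripe vectors
            angles.append(np.abs(np.arctan2(vx * ty - vy * tx, vx * tx + vy * ty)))
        out.append(np.minimum(angles[0], angles[1]))
    if not out:
        return np.array([])
    return np.concatenate(out)


def stripe_deviation(
    traj: Trajectory,
    arena: ArenaGeometry,
    movement_threshold: float = MOVEMENT_THRESHOLD,
    jump_threshold: float = JUMP_THRESHOLD,
    summary: str = "median",
) -> float:
    """Per-fly stripe-deviation summary in degrees.

    The per-frame statistic is the absolute angle between the velocity
    vector and the vector to the frontal stripe's centre; the frontal
    stripe is recomputed every frame as the angle-minimising one. The
    per-fly summary is the median of frame angles by default (``summary=
    "mean"`` switches to the mean).
    """
    ang = _frontal_angles(traj, arena, movement_threshold, jump_threshold)
    if ang.size == 0:
        raise NoValidFramesError(
            f"fly {traj.fly_id}: no moving frames for stripe deviation"
        )
    if summary == "median":
        return float(np.degrees(np.median(ang)))
    if summary == "mean":
        return float(np.degrees(np.mean(ang)))
    raise ValueError(f"unknown summary {summary!r}")


def fly_metrics(
    traj: Trajectory,
    arena: ArenaGeometry,
    jump_threshold: float = JUMP_THRESHOLD,
    movement_threshold: float = MOVEMENT_THRESHOLD,
    deviation_summary: str = "median",
) -> FlyMetrics:
    """Compute both Buridan measures plus frame accounting for one fly."""
    _, v = frame_speeds(traj)
    n_frames = int(v.size)
    n_jumps = int((v > jump_threshold).sum())
    n_moving = int(((v >= movement_threshold) & (v <= jump_threshold)).sum())
    return FlyMetrics(
        fly_id=traj.fly_id,
        genotype=traj.genotype,
        median_speed=median_speed(traj, jump_threshold),
        stripe_deviation=stripe_deviation(
            traj, arena, movement_threshold, jump_threshold, deviation_summary
        ),
        n_frames=n_frames,
        n_jump_frames=n_jumps,
        n_moving_frames=n_moving,
        total_time=traj.total_time,
    )


def tukey_box_stats(values: np.ndarray) -> dict[str, float]:
    """Tukey boxplot five-number summary: median, quartiles, 1.5*IQR whiskers."""
    values = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    in_lo = values[values >= q1 - 1.5 * iqr]
    in_hi = values[values <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(in_lo.min()) if in_lo.size else float("nan"),
        "whisker_high": float(in_hi.max()) if in_hi.size else float("nan"),
        "n_outliers": int(((values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)).sum()),
    }


def cohort_metrics(
    cohort: CohortTrajectorySet,
    arena: ArenaGeometry,
    jump_threshold: float = JUMP_THRESHOLD,
    movement_threshold: float = MOVEMENT_THRESHOLD,
    deviation_summary: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Per-fly metrics table plus group summaries for a whole cohort.

    Returns ``(per_fly, groups, exclusions)``. ``per_fly`` has one row per
    retained fly. ``groups`` reports, per genotype, n, the mean and SEM of
    per-fly median speeds (bar-plot convention) and the Tukey boxplot
    statistics of per-fly stripe deviations. Flies without valid frames are
    excluded and logged in ``exclusions``, never silently dropped.
    """
    rows = []
    exclusions: list[dict] = []
    for traj in cohort.flies:
        try:
            m = fly_metrics(
                traj, arena, jump_threshold, movement_threshold, deviation_summary
            )
        except NoValidFramesError as err:
            exclusions.append({"fly_id": traj.fly_id, "reason": str(err)})
            continue
        rows.append(
            {
                "fly_id": m.fly_id,
                "genotype": m.genotype,
                "median_speed_mm_s": m.median_speed,
                "stripe_deviation_deg": m.stripe_deviation,
                "n_frames": m.n_frames,
                "n_jump_frames": m.n_jump_frames,
                "n_moving_frames": m.n_moving_frames,
                "total_time_s": m.total_time,
            }
        )
    per_fly = pd.DataFrame(rows)
    group_rows = []
    for label in cohort.group_labels:
        sub = per_fly[per_fly["genotype"] == label] if len(per_fly) else per_fly
        if len(sub) == 0:
            continue
        speeds = sub["median_speed_mm_s"].to_numpy()
        dev = sub["stripe_deviation_deg"].to_numpy()
        box = tukey_box_stats(dev)
        group_rows.append(
            {
                "genotype": label,
                "n": len(sub),
                "speed_mean": float(speeds.mean()),
                "speed_sem": float(speeds.std(ddof=1) / np.sqrt(len(sub)))
                if len(sub) > 1
                else 0.0,
                **{f"deviation_{k}": v for k, v in box.items()},
            }
        )
    return per_fly, pd.DataFrame(group_rows), exclusions
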