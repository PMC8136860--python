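"""Trajectory containers.

A fly's track is an ordered list of segments: the tracker is restarted
whenever the fly leaves the platform, so speeds are never computed across a
segment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MalformedTrajectoryError


@dataclass
class TrajectorySegment:
    """One uninterrupted tracked bout: time (s) and position (mm) samples."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise MalformedTrajectoryError("t, x, y must be 1-D arrays of equal length")
        if self.t.size and (
            np.isnan(self.t).any() or np.isnan(self.x).any() or np.isnan(self.y).any()
        ):
            raise MalformedTrajectoryError("trajectory samples contain NaN")
        if self.t.size >= 2 and not (np.diff(self.t) > 0).all():
            raise MalformedTrajectoryError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t.size


@dataclass
class Trajectory:
    """A single fly's tracked positions with genotype metadata."""

    fly_id: str
    genotype: str
    segments: list[TrajectorySegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if a.t.size and b.t.size and b.t[0] <= a.t[-1]:
                raise MalformedTrajectoryError(
                    f"fly {self.fly_id}: segment time ranges overlap"
                )

    @property
    def n_samples(self) -> int:
        return sum(s.n_samples for s in self.segments)

    @property
    def total_time(self) -> float:
        """Total tracked time in seconds (sum of segment spans)."""
        return float(sum(s.t[-1] - s.t[0] for s in self.segments if s.t.size >= 2))


@dataclass
class CohortTrajectorySet:
    """Trajectories for one experiment, grouped by genotype label."""

    flies: list[Trajectory]
    group_labels: list[str]

    def by_genotype(self) -> dict[str, list[Trajectory]]:
        out: dict[str, list[Trajectory]] = {g: [] for g in self.group_labels}
        for fly in self.flies:
            out.setdefault(fly.genotype, []).append(fly)
        return out
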