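"""CSV/YAML dialects and the run manifest.

All CSV files are UTF-8, comma-separated with a mandatory header row and
'.' decimals. Coordinates are mm in the platform-centred frame with the
stripe axis along x (unless the arena says otherwise).

Dialects::

    trajectories.csv  fly_id, segment, t_s, x_mm, y_mm
    cohort.csv        fly_id, genotype, sex, role
    per.csv           fly_id, genotype, stim_label, response
    metrics.csv       fly_id, genotype, median_speed_mm_s,
                      stripe_deviation_deg, n_frames, n_jump_frames,
                      n_moving_frames, total_time_s
    scores.csv        fly_id, genotype, score, excluded, reason
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arena import ArenaGeometry
from .errors import ConfigError, MalformedTrajectoryError
from .simulate import GenotypeEffect, SimulationConfig
from .trajectory import CohortTrajectorySet, Trajectory, TrajectorySegment

TRAJECTORY_COLUMNS = ["fly_id", "segment", "t_s", "x_mm", "y_mm"]
COHORT_COLUMNS = ["fly_id", "genotype", "sex", "role"]
PER_COLUMNS = ["fly_id", "genotype", "stim_label", "response"]


def write_trajectories(cohort: CohortTrajectorySet, path: str | Path) -> None:
    frames = []
    for fly in cohort.flies:
        for si, seg in enumerate(fly.segments):
            frames.append(
                pd.DataFrame(
                    {
                        "fly_id": fly.fly_id,
                        "segment": si,
                        "t_s": seg.t,
                        "x_mm": seg.x,
                        "y_mm": seg.y,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_trajectories(
    path: str | Path, genotypes: dict[str, str] | None = None
) -> list[Trajectory]:
    """Read the trajectory CSV; *genotypes* maps fly_id -> genotype label."""
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedTrajectoryError(
            f"{path}: missing trajectory columns {sorted(missing)}"
        )
    bad = df[df[["t_s", "x_mm", "y_mm"]].isna().any(axis=1)]
    if len(bad):
        raise MalformedTrajectoryError(
            f"{path}: corrupted row at line {int(bad.index[0]) + 2}"
        )
    flies = []
    for fly_id, fsub in df.groupby("fly_id", sort=False):
        segments = [
            TrajectorySegment(
                ssub["t_s"].to_numpy(), ssub["x_mm"].to_numpy(), ssub["y_mm"].to_numpy()
            )
            for _, ssub in fsub.groupby("segment", sort=True)
        ]
        genotype = (genotypes or {}).get(str(fly_id), "unknown")
        flies.append(Trajectory(str(fly_id), genotype, segments))
    return flies


def write_cohort_manifest(
    cohort: CohortTrajectorySet,
    roles: dict[str, str],
    path: str | Path,
    sex: str = "f",
) -> None:
    """Write the fly -> genotype/role mapping; *roles* maps genotype -> role."""
    rows = [
        {
            "fly_id": fly.fly_id,
            "genotype": fly.genotype,
            "sex": sex,
            "role": roles.get(fly.genotype, ""),
        }
        for fly in cohort.flies
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing manifest columns {sorted(missing)}")
    return df


def write_per_table(table: pd.DataFrame, path: str | Path) -> None:
    table[PER_COLUMNS].to_csv(path, index=False)


def read_per_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PER_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing PER columns {sorted(missing)}")
    return df


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    simulation: SimulationConfig | None = None
    effects: list[GenotypeEffect] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)
    design: str = "dominance_triplet"
    alpha: float = 0.005
    jump_threshold: float = 50.0
    movement_threshold: float = 1.0
    repeat_k: int = 2
    strict_pr: bool = True
    per_n: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.jump_threshold <= 0 or self.movement_threshold <= 0:
            raise ConfigError("thresholds must be positive")


_EFFECT_FIELDS = set(GenotypeEffect.__dataclass_fields__)
_ARENA_FIELDS = set(ArenaGeometry.__dataclass_fields__)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Schema errors name the offending field path.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as err:
            raise ConfigError(f"{path}: YAML parse error: {err}") from err
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    arena_raw = raw.get("arena", {}) or {}
    unknown = set(arena_raw) - _ARENA_FIELDS
    if unknown:
        raise ConfigError(f"arena: unknown fields {sorted(unknown)}")
    arena = ArenaGeometry(**arena_raw)
    sim_raw = dict(raw.get("simulation", {}) or {})
    seed = int(raw.get("seed", 0))
    effects = []
    for i, spec in enumerate(raw.get("genotypes", []) or []):
        if "label" not in spec:
            raise ConfigError(f"genotypes[{i}].label: required")
        unknown = set(spec) - _EFFECT_FIELDS - {"role"}
        if unknown:
            raise ConfigError(f"genotypes[{i}]: unknown fields {sorted(unknown)}")
        effects.append(
            GenotypeEffect(**{k: v for k, v in spec.items() if k in _EFFECT_FIELDS})
        )
    roles = {
        spec["label"]: spec.get("role", spec["label"])
        for spec in raw.get("genotypes", []) or []
    }
    sim = SimulationConfig(arena=arena, seed=seed, **sim_raw)
    return PipelineConfig(
        seed=seed,
        arena=arena,
        simulation=sim,
        effects=effects,
        roles=roles,
        design=raw.get("design", "dominance_triplet"),
        alpha=float(raw.get("alpha", 0.005)),
        jump_threshold=float(raw.get("jump_threshold", 50.0)),
        movement_threshold=float(raw.get("movement_threshold", 1.0)),
        repeat_k=int(raw.get("repeat_k", 2)),
        strict_pr=bool(raw.get("strict_pr", True)),
        per_n=raw.get("per_n"),
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(
    path: str | Path,
    config: PipelineConfig,
    input_files: dict[str, str | Path],
    counts: dict[str, int],
    exclusions: list[dict] | None = None,
) -> None:
    """Write the reproducibility manifest atomically (write + rename)."""
    from . import __version__

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    cfg = _clean(asdict(config))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "input_sha256": {k: file_sha256(v) for k, v in input_files.items()},
        "counts": counts,
        "exclusions": exclusions or [],
    }
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(path)
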