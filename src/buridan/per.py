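"""Proboscis-extension (sugar-response) scoring.

Each fly receives, in order: a water-only (0 %) tarsal stimulation, six
sucrose tarsal stimulations of increasing concentration (0.1, 0.3, 0.6, 1,
3, 30 %), and a final 30 % sucrose stimulation applied directly to the
proboscis. A fly that responds to the water stimulation, or that fails to
respond to the final proboscis stimulation, is discarded. The retained
fly's score is the number of responses to the six sucrose tarsal
stimulations — an ordinal 0–6 value; only nonparametric statistics are
applied to it downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MalformedRecordError
from .metrics import tukey_box_stats
from .simulate import STIM_LABELS


@dataclass(frozen=True)
class PERRecord:
    """One fly's ordered responses to the eight stimulations."""

    fly_id: str
    genotype: str
    responses: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.responses) != 8:
            raise MalformedRecordError(
                f"fly {self.fly_id}: expected 8 ordered responses, "
                f"got {len(self.responses)}"
            )


@dataclass(frozen=True)
class PERScore:
    """Scoring outcome: a 0–6 score, or an exclusion with its reason."""

    fly_id: str
    genotype: str
    score: int | None
    excluded: bool
    exclusion_reason: str  # responded_to_water | no_proboscis_response | none


def score_fly(rec: PERRecord) -> PERScore:
    """Apply the exclusion rules, then count sucrose responses.

    Exclusion: response to the water-only stimulation, or no response to
    the final proboscis stimulation. The water stimulation never
    contributes to the score; retained flies score the count of responses
    among the six nonzero sucrose tarsal stimulations.
    """
    r = rec.responses
    if r[0]:
        return PERScore(rec.fly_id, rec.genotype, None, True, "responded_to_water")
    if not r[7]:
        return PERScore(rec.fly_id, rec.genotype, None, True, "no_proboscis_response")
    return PERScore(rec.fly_id, rec.genotype, int(sum(r[1:7])), False, "none")


def records_from_table(table: pd.DataFrame) -> list[PERRecord]:
    """Build :class:`PERRecord` objects from the long-format PER table."""
    required = {"fly_id", "genotype", "stim_label", "response"}
    missing = required - set(table.columns)
    if missing:
        raise MalformedRecordError(f"PER table missing columns: {sorted(missing)}")
    records = []
    for (fly_id, genotype), sub in table.groupby(["fly_id", "genotype"], sort=False):
        labels = tuple(sub["stim_label"])
        if labels != STIM_LABELS:
            raise MalformedRecordError(
                f"fly {fly_id}: stimulus labels {labels} do not match the "
                f"required order {STIM_LABELS}"
            )
        records.append(
            PERRecord(str(fly_id), str(genotype), tuple(bool(v) for v in sub["response"]))
        )
    return records


def score_cohort(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, int], list[str]]:
    """Score every fly in a long-format PER table.

    Returns ``(scores, group_vectors, exclusion_counts, warnings)``:
    a per-fly scores table (excluded flies included, carrying no score),
    per-genotype score vectors for the statistics stage (genotypes whose
    flies were all excluded are dropped with a warning), counts per
    exclusion reason, and the warning messages.
    """
    records = records_from_table(table)
    if not records:
        raise MalformedRecordError("PER table contains no records")
    scored = [score_fly(r) for r in records]
    scores = pd.DataFrame(
        {
            "fly_id": [s.fly_id for s in scored],
            "genotype": [s.genotype for s in scored],
            "score": [s.score if s.score is not None else pd.NA for s in scored],
            "excluded": [s.excluded for s in scored],
            "reason": [s.exclusion_reason for s in scored],
        }
    )
    counts = {
        "responded_to_water": sum(s.exclusion_reason == "responded_to_water" for s in scored),
        "no_proboscis_response": sum(
            s.exclusion_reason == "no_proboscis_response" for s in scored
        ),
    }
    group_vectors: dict[str, np.ndarray] = {}
    warnings: list[str] = []
    for genotype in dict.fromkeys(s.genotype for s in scored):
        vals = np.array(
            [s.score for s in scored if s.genotype == genotype and not s.excluded],
            dtype=float,
        )
        if vals.size == 0:
            warnings.append(f"group {genotype}: all flies excluded; group dropped")
            continue
        group_vectors[genotype] = vals
    return scores, group_vectors, counts, warnings


def group_box_stats(group_vectors: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey boxplot summaries of the per-genotype score vectors."""
    rows = [
        {"genotype": g, "n": len(v), **tukey_box_stats(v)}
        for g, v in group_vectors.items()
    ]
    return pd.DataFrame(rows)
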