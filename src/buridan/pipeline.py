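"""End-to-end analysis: metrics -> scoring -> statistics -> genetic calls.

The entry point :func:`analyze_experiment` takes trajectories grouped by
genotype plus an optional sugar-response table, runs each metric through
the comparison scheme (with the two-repeated-measurement correction on the
two Buridan measures), and produces the categorical call the design asks
for: an inheritance mode per metric for a dominance triplet, or a rescue
outcome per metric for a rescue design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import ArenaGeometry
from .calls import InheritanceCall, RescueCall, classify_inheritance, classify_rescue
from .errors import DesignError
from .metrics import cohort_metrics
from .per import score_cohort
from .stats import GroupedMeasurements, PairwiseStats, compare_groups, stats_report
from .trajectory import CohortTrajectorySet

log = logging.getLogger("buridan")

#: Buridan metrics share a session, hence the repeated-measurement factor.
BURIDAN_METRICS = ("median_speed_mm_s", "stripe_deviation_deg")


@dataclass
class ExperimentResult:
    """Everything one analysed experiment produced."""

    per_fly_metrics: pd.DataFrame
    group_summaries: pd.DataFrame
    per_scores: pd.DataFrame | None
    stats: dict[str, PairwiseStats]
    calls: dict[str, InheritanceCall | RescueCall]
    exclusions: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def stats_json(self) -> list[dict]:
        return [stats_report(s, m) for m, s in self.stats.items()]

    def calls_json(self) -> list[dict]:
        out = []
        for metric, call in self.calls.items():
            entry = {
                "metric": metric,
                "evidence": call.evidence,
                "sentence": call.sentence,
            }
            if isinstance(call, InheritanceCall):
                entry["mode"] = call.mode
            else:
                entry["outcome"] = call.outcome
            out.append(entry)
        return out


def _grouped(
    per_fly: pd.DataFrame, metric: str, labels: list[str], design: str
) -> GroupedMeasurements:
    values = []
    for lab in labels:
        v = per_fly.loc[per_fly["genotype"] == lab, metric].to_numpy(dtype=float)
        if v.size < 2:
            raise DesignError(
                f"group {lab}: only {v.size} flies with valid {metric}; need >= 2"
            )
        values.append(v)
    return GroupedMeasurements(metric, labels, values, design=design)


def analyze_experiment(
    cohort: CohortTrajectorySet,
    arena: ArenaGeometry,
    per_table: pd.DataFrame | None = None,
    roles: dict[str, str] | None = None,
    design: str = "dominance_triplet",
    alpha: float = 0.005,
    jump_threshold: float = 50.0,
    movement_threshold: float = 1.0,
    repeat_k: int = 2,
    strict_pr: bool = True,
) -> ExperimentResult:
    """Run the full analysis for one experiment.

    *roles* maps genotype labels to design roles (``wt``/``het``/``hom``
    for a dominance triplet; ``wt_ctrl``/``gal4_mut_ctrl``/
    ``uas_mut_ctrl``/``experimental`` for a rescue design). Unknown
    genotypes in *roles* raise a design error; flies without valid frames
    are excluded with a logged reason.
    """
    roles = roles or {g: g for g in cohort.group_labels}
    unknown = set(roles) - set(cohort.group_labels)
    if unknown:
        raise DesignError(f"roles name unknown genotypes: {sorted(unknown)}")
    per_fly, summaries, exclusions = cohort_metrics(
        cohort, arena, jump_threshold, movement_threshold
    )
    for exc in exclusions:
        log.warning("flagged fly excluded: %s", exc)
    labels = list(cohort.group_labels)
    warnings: list[str] = []
    stats: dict[str, PairwiseStats] = {}
    for metric in BURIDAN_METRICS:
        data = _grouped(per_fly, metric, labels, design)
        stats[metric] = compare_groups(data, alpha=alpha, repeat_k=repeat_k)
    per_scores = None
    if per_table is not None:
        per_scores, vectors, counts, w = score_cohort(per_table)
        warnings.extend(w)
        log.info("PER exclusions: %s", counts)
        labs = [g for g in labels if g in vectors]
        if len(labs) >= 2:
            data = GroupedMeasurements(
                "per_score", labs, [vectors[g] for g in labs], design=design
            )
            # ordinal scores: nonparametric branch only
            stats["per_score"] = compare_groups(
                data, alpha=alpha, repeat_k=1, branch="nonparametric"
            )
        else:
            warnings.append("fewer than 2 PER groups survive exclusion; PER stats skipped")
    calls: dict[str, InheritanceCall | RescueCall] = {}
    by_role = {r: g for g, r in roles.items()}
    for metric, st in stats.items():
        if design == "dominance_triplet":
            needed = {"wt", "het", "hom"}
            if not needed <= set(by_role):
                raise DesignError(
                    f"dominance design needs roles {sorted(needed)}, "
                    f"got {sorted(by_role)}"
                )
            if not all(by_role[r] in st.labels for r in needed):
                continue
            call = classify_inheritance(
                st, wt=by_role["wt"], het=by_role["het"], hom=by_role["hom"]
            )
        elif design in ("rescue_design", "overexpression_design"):
            needed = {"wt_ctrl", "gal4_mut_ctrl", "uas_mut_ctrl", "experimental"}
            missing = needed - set(by_role)
            if missing:
                raise DesignError(f"rescue design missing roles: {sorted(missing)}")
            if not all(by_role[r] in st.labels for r in needed):
                continue
            call = classify_rescue(
                st,
                experimental=by_role["experimental"],
                wt_ctrl=by_role["wt_ctrl"],
                mutant_ctrls=(by_role["gal4_mut_ctrl"], by_role["uas_mut_ctrl"]),
                strict_pr=strict_pr,
            )
        elif design == "two_group":
            continue
        else:
            raise DesignError(f"unknown design {design!r}")
        call.metric = metric
        calls[metric] = call
    return ExperimentResult(
        per_fly_metrics=per_fly,
        group_summaries=summaries,
        per_scores=per_scores,
        stats=stats,
        calls=calls,
        exclusions=exclusions,
        warnings=warnings,
    )


def render_report(result: ExperimentResult) -> str:
    """Human-readable markdown summary with letter-annotated group tables."""
    lines: list[str] = ["# Experiment report", ""]
    if not result.calls and not result.stats:
        lines.append("*Empty report: no statistics or calls were produced.*")
        return "\n".join(lines)
    for metric, st in result.stats.items():
        lines.append(f"## {metric}")
        lines.append("")
        branch = st.gate.branch if st.gate else "forced"
        lines.append(
            f"Test: {st.test_used} ({branch} branch), alpha = {st.alpha}, "
            f"repeat-measurement correction k = {st.repeat_k}"
        )
        lines.append("")
        lines.append("| group | n | central tendency | letters |")
        lines.append("|---|---|---|---|")
        order = sorted(st.labels, key=lambda g: -st.tendencies[g])
        if metric == "per_score" and result.per_scores is not None:
            ns = {
                g: int(
                    (
                        (result.per_scores["genotype"] == g)
                        & (~result.per_scores["excluded"])
                    ).sum()
                )
                for g in st.labels
            }
        else:
            ns = {
                g: int((result.per_fly_metrics["genotype"] == g).sum())
                for g in st.labels
            }
        for g in order:
            lines.append(
                f"| {g} | {ns[g]} | {st.tendencies[g]:.3g} | {st.letters[g]} |"
            )
        lines.append("")
        if metric == "per_score" and result.per_scores is not None:
            from .metrics import tukey_box_stats

            lines.append("| group | median | q1 | q3 | whiskers |")
            lines.append("|---|---|---|---|---|")
            retained = result.per_scores[~result.per_scores["excluded"]]
            for g in order:
                v = retained.loc[retained["genotype"] == g, "score"].to_numpy(float)
                box = tukey_box_stats(v)
                lines.append(
                    f"| {g} | {box['median']:g} | {box['q1']:g} | {box['q3']:g} "
                    f"| [{box['whisker_low']:g}, {box['whisker_high']:g}] |"
                )
            lines.append("")
        call = result.calls.get(metric)
        if call is not None:
            label = getattr(call, "mode", None) or getattr(call, "outcome", "")
            lines.append(f"**Call: {label}** — {call.sentence}.")
            lines.append("")
    if result.exclusions:
        lines.append("## Exclusions")
        lines.extend(f"- {e}" for e in result.exclusions)
        lines.append("")
    if result.warnings:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in result.warnings)
        lines.append("")
    return "\n".join(lines)
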