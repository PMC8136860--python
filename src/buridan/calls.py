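"""Categorical genetic calls from pairwise statistics.

Inheritance mode of a mutation is read off the wild-type / heterozygote /
homozygote comparison pattern: which pairs differ significantly, and where
the heterozygote's central tendency lies relative to the two homozygous
groups. A single locus may show different modes across phenotypes
(differential dominance). Transgenic rescue experiments are classified from
the experimental line's relation to the wild-type control and the two
mutant (driver-only / effector-only) controls; when those two controls
differ from each other the panel is uninterpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DesignError
from .stats import PairwiseStats

INHERITANCE_MODES = (
    "recessive",
    "dominant",
    "intermediate",
    "overdominant",
    "underdominant",
    "indeterminate",
)

RESCUE_OUTCOMES = ("FR", "PR", "NR", "uninterpretable")


@dataclass
class InheritanceCall:
    """Inheritance-mode call with its audit evidence."""

    mode: str
    metric: str
    evidence: dict = field(default_factory=dict)
    sentence: str = ""


@dataclass
class RescueCall:
    """Rescue-outcome call (full / partial / no rescue, or uninterpretable)."""

    outcome: str
    metric: str
    evidence: dict = field(default_factory=dict)
    sentence: str = ""


def classify_inheritance(
    stats: PairwiseStats,
    wt: str = "wt",
    het: str = "het",
    hom: str = "hom",
    tendencies: dict[str, float] | None = None,
) -> InheritanceCall:
    """Call the inheritance mode from a wt/het/hom comparison.

    Decision table (sig = corrected p < alpha):

    * hom not significantly different from wt -> ``indeterminate`` (the
      mutation shows no phenotype to classify).
    * het not sig vs wt -> ``recessive`` (regardless of het vs hom).
    * het sig vs wt, not sig vs hom -> ``dominant``.
    * het sig vs both: ``intermediate`` if the het tendency lies strictly
      between wt and hom; ``overdominant`` if it lies beyond wt on the side
      opposite hom; ``underdominant`` if beyond hom; any tie ->
      ``indeterminate``.

    The central tendency used for the ordering is the one the comparison
    itself reported (group mean on the parametric branch, median on the
    nonparametric branch) unless *tendencies* overrides it.
    """
    for lab in (wt, het, hom):
        if lab not in stats.labels:
            raise DesignError(f"missing group {lab!r} in pairwise statistics")
    tend = tendencies or stats.tendencies
    sig_wt_het = stats.significant(wt, het)
    sig_wt_hom = stats.significant(wt, hom)
    sig_het_hom = stats.significant(het, hom)
    evidence = {
        "sig_wt_het": sig_wt_het,
        "sig_wt_hom": sig_wt_hom,
        "sig_het_hom": sig_het_hom,
        "p_wt_het": stats.p(wt, het),
        "p_wt_hom": stats.p(wt, hom),
        "p_het_hom": stats.p(het, hom),
        "tendencies": {lab: tend[lab] for lab in (wt, het, hom)},
        "alpha": stats.alpha,
    }
    t_wt, t_het, t_hom = tend[wt], tend[het], tend[hom]
    if not sig_wt_hom:
        mode = "indeterminate"
    elif not sig_wt_het:
        mode = "recessive"
        if min(t_wt, t_hom) < t_het < max(t_wt, t_hom):
            evidence["intermediate_trend"] = True
    elif not sig_het_hom:
        mode = "dominant"
    else:
        # het significantly different from both homozygous groups
        if min(t_wt, t_hom) < t_het < max(t_wt, t_hom):
            mode = "intermediate"
        elif (t_het - t_wt) * (t_hom - t_wt) < 0:
            mode = "overdominant"
        elif (t_het - t_hom) * (t_wt - t_hom) < 0:
            mode = "underdominant"
        else:
            mode = "indeterminate"
    sentences = {
        "recessive": f"{het} is not statistically different from {wt} but "
        f"{hom} is, indicating a recessive phenotype",
        "dominant": f"{het} differs from {wt} but not from {hom}, "
        f"indicating dominant inheritance",
        "intermediate": f"{het} differs from both {wt} and {hom} and lies "
        f"between them, indicating intermediate inheritance",
        "overdominant": f"{het} differs from both {wt} and {hom} and exceeds "
        f"{wt} on the side opposite {hom}, indicating overdominant inheritance",
        "underdominant": f"{het} differs from both {wt} and {hom} and lies "
        f"beyond {hom}, indicating underdominant inheritance",
        "indeterminate": "the significance pattern does not support an "
        "inheritance-mode call",
    }
    return InheritanceCall(
        mode=mode, metric="", evidence=evidence, sentence=sentences[mode]
    )


def classify_rescue(
    stats: PairwiseStats,
    experimental: str = "experimental",
    wt_ctrl: str = "wt_ctrl",
    mutant_ctrls: tuple[str, str] = ("gal4_mut_ctrl", "uas_mut_ctrl"),
    strict_pr: bool = True,
    consistency_alpha: float | None = None,
) -> RescueCall:
    """Call the rescue outcome of a four-group transgenic design.

    Checked in order:

    1. ``uninterpretable`` — the two mutant controls differ significantly
       from each other (threshold *consistency_alpha*, defaulting to the
       comparison's alpha): inconsistent controls prevent interpreting the
       experimental group.
    2. ``FR`` (full rescue) — the experimental group differs significantly
       from both mutant controls but not from the wild-type control.
    3. ``PR`` (partial rescue) — the experimental group fails to reach
       significance against the wild-type control and against at least one
       mutant control (the default, conjunction reading). With
       ``strict_pr=False`` the disjunction reading applies: failing either
       of those comparisons suffices.
    4. ``NR`` (no rescue) — everything else, notably an experimental group
       that differs from wild type or matches both mutant controls.
    """
    ctrl_a, ctrl_b = mutant_ctrls
    for lab in (experimental, wt_ctrl, ctrl_a, ctrl_b):
        if lab not in stats.labels:
            raise DesignError(f"missing control or experimental group {lab!r}")
    thr = consistency_alpha if consistency_alpha is not None else stats.alpha
    controls_differ = stats.p(ctrl_a, ctrl_b) < thr
    sig_wt = stats.significant(experimental, wt_ctrl)
    sig_a = stats.significant(experimental, ctrl_a)
    sig_b = stats.significant(experimental, ctrl_b)
    evidence = {
        "sig_exp_wt": sig_wt,
        "sig_exp_mut_ctrl": {ctrl_a: sig_a, ctrl_b: sig_b},
        "controls_differ": controls_differ,
        "p_exp_wt": stats.p(experimental, wt_ctrl),
        "p_exp_mut_ctrl": {
            ctrl_a: stats.p(experimental, ctrl_a),
            ctrl_b: stats.p(experimental, ctrl_b),
        },
        "p_ctrl_ctrl": stats.p(ctrl_a, ctrl_b),
        "alpha": stats.alpha,
        "strict_pr": strict_pr,
    }
    if controls_differ:
        outcome = "uninterpretable"
        sentence = (
            "the two mutant control groups differ significantly from each "
            "other, which prevents the interpretation of the experimental group"
        )
    elif sig_a and sig_b and not sig_wt:
        outcome = "FR"
        sentence = (
            f"{experimental} differs significantly from both mutant controls "
            f"but not from {wt_ctrl}: full rescue"
        )
    elif (not sig_wt and not (sig_a and sig_b)) or (
        not strict_pr and (not sig_wt or not (sig_a and sig_b))
    ):
        outcome = "PR"
        sentence = (
            f"{experimental} fails to reach significance against {wt_ctrl} "
            f"and against at least one mutant control: partial rescue"
        )
    else:
        outcome = "NR"
        sentence = f"{experimental} remains mutant-like: no rescue"
    return RescueCall(outcome=outcome, metric="", evidence=evidence, sentence=sentence)
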