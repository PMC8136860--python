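"""Group-comparison statistics for behavioral phenotypes.

The scheme mirrors common practice in fly behavioral genetics: per-group
Shapiro-Wilk normality testing gates the choice between a parametric branch
(two-way ANOVA with Tukey HSD post hoc comparisons when a second design
factor is present, one-way otherwise; Welch's t for two-group designs) and
a nonparametric branch (all-pairs Wilcoxon rank-sum tests with Bonferroni
correction over the pairs of one metric family). Because walking speed and
stripe fixation are two measures taken from the same session, their
p-values receive an additional correction for two repeated measurements.
Significance uses a strict threshold (default alpha 0.005), and groups are
labelled with a compact letter display: two groups share a letter if and
only if they are not significantly different.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

from .errors import DesignError

#: Default family-wise significance threshold.
DEFAULT_ALPHA = 0.005
#: Shapiro-Wilk threshold for the branch decision.
NORMALITY_ALPHA = 0.05


@dataclass
class GroupedMeasurements:
    """Per-group measurement vectors entering a pairwise comparison.

    ``design`` is one of ``two_group``, ``dominance_triplet``,
    ``rescue_design``, ``overexpression_design``. ``batch`` optionally
    carries a second design factor (e.g. experiment batch) aligned with
    ``values``; when present, the parametric branch fits a two-factor
    model.
    """

    metric_name: str
    labels: list[str]
    values: list[np.ndarray]
    design: str = "two_group"
    batch: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise DesignError("labels and values must align")
        if len(self.labels) < 2:
            raise DesignError("need at least 2 groups")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for lab, v in zip(self.labels, self.values):
            if v.size < 2:
                raise DesignError(f"group {lab}: need at least 2 values")
            if not np.isfinite(v).all():
                raise DesignError(f"group {lab}: values must be finite")


@dataclass
class NormalityGate:
    """Outcome of the Shapiro-Wilk branch decision, with the audit trail."""

    branch: str  # "parametric" | "nonparametric"
    p_values: dict[str, float]
    warnings: list[str] = field(default_factory=list)


@dataclass
class PairwiseStats:
    """Pairwise corrected p-values, letters and group tendencies."""

    test_used: str  # anova_tukey | welch_t | wilcoxon_bonferroni | wilcoxon
    labels: list[str]
    p_raw: np.ndarray
    p_corrected: np.ndarray
    alpha: float
    letters: dict[str, str]
    tendencies: dict[str, float]
    gate: NormalityGate | None = None
    repeat_k: int = 1
    notes: list[str] = field(default_factory=list)

    def p(self, a: str, b: str) -> float:
        """Corrected p-value for the pair of group labels (a, b)."""
        return float(self.p_corrected[self.labels.index(a), self.labels.index(b)])

    def significant(self, a: str, b: str) -> bool:
        return self.p(a, b) < self.alpha


def normality_gate(data: GroupedMeasurements, alpha: float = NORMALITY_ALPHA) -> NormalityGate:
    """Choose the comparison branch from per-group Shapiro-Wilk tests.

    Nonparametric if any group rejects normality at *alpha*. Groups too
    small for the test (< 3 values) or with zero variance force the
    nonparametric branch with a warning — the test is undefined there.
    """
    pvals: dict[str, float] = {}
    warnings: list[str] = []
    branch = "parametric"
    for lab, v in zip(data.labels, data.values):
        if v.size < 3 or np.ptp(v) == 0:
            warnings.append(
                f"group {lab}: Shapiro-Wilk undefined (n={v.size}, "
                f"range={np.ptp(v):g}); falling back to nonparametric"
            )
            branch = "nonparametric"
            pvals[lab] = float("nan")
            continue
        p = float(sps.shapiro(v).pvalue)
        pvals[lab] = p
        if p < alpha:
            branch = "nonparametric"
    return NormalityGate(branch=branch, p_values=pvals, warnings=warnings)


def _tukey_pairwise(data: GroupedMeasurements, notes: list[str]) -> np.ndarray:
    """Tukey HSD p-values from the fitted linear model.

    With a second design factor the model is group*batch (main effects plus
    interaction) and the residual mean square of that fit studentises the
    pairwise group contrasts; without one, a plain one-way fit is used and
    a deviation note is logged. Unequal group sizes use the Tukey-Kramer
    standard error.
    """
    k = len(data.labels)
    means = np.array([v.mean() for v in data.values])
    ns = np.array([v.size for v in data.values])
    if data.batch is not None:
        import statsmodels.formula.api as smf

        frame = pd.DataFrame(
            {
                "y": np.concatenate(data.values),
                "group": np.concatenate(
                    [[lab] * v.size for lab, v in zip(data.labels, data.values)]
                ),
                "batch": np.concatenate([np.asarray(b) for b in data.batch]),
            }
        )
        cells = frame.groupby(["group", "batch"], observed=True).size()
        for g in frame["group"].unique():
            for b in frame["batch"].unique():
                if (g, b) not in cells.index:
                    raise DesignError(f"empty design cell: group={g}, batch={b}")
        fit = smf.ols("y ~ C(group) * C(batch)", data=frame).fit()
        mse = float(fit.mse_resid)
        df = float(fit.df_resid)
    else:
        notes.append(
            "no second design factor present; one-way ANOVA used for the "
            "Tukey HSD error term"
        )
        df = float(ns.sum() - k)
        mse = float(
            sum(((v - v.mean()) ** 2).sum() for v in data.values) / df
        )
    if df <= 0 or mse <= 0:
        raise DesignError("degenerate design: no residual variance for Tukey HSD")
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(means[i] - means[j]) / se
        pij = float(studentized_range.sf(q, k, df))
        p[i, j] = p[j, i] = min(max(pij, 0.0), 1.0)
    return p


def parametric_compare(
    data: GroupedMeasurements, alpha: float = DEFAULT_ALPHA
) -> PairwiseStats:
    """Parametric branch: Welch's t for two groups, else ANOVA + Tukey HSD.

    Tukey p-values are already multiplicity-adjusted across the group
    pairs, so the corrected matrix equals the raw one here; any repeat-
    measurement correction is applied separately.
    """
    notes: list[str] = []
    k = len(data.labels)
    if k == 2:
        res = sps.ttest_ind(data.values[0], data.values[1], equal_var=False)
        p = np.ones((2, 2))
        p[0, 1] = p[1, 0] = float(res.pvalue)
        test = "welch_t"
    else:
        p = _tukey_pairwise(data, notes)
        test = "anova_tukey"
    tendencies = {lab: float(v.mean()) for lab, v in zip(data.labels, data.values)}
    return PairwiseStats(
        test_used=test,
        labels=list(data.labels),
        p_raw=p.copy(),
        p_corrected=p.copy(),
        alpha=alpha,
        letters=compact_letter_display(data.labels, p, alpha),
        tendencies=tendencies,
        notes=notes,
    )


def nonparametric_compare(
    data: GroupedMeasurements, alpha: float = DEFAULT_ALPHA
) -> PairwiseStats:
    """Nonparametric branch: all-pairs rank-sum tests, Bonferroni-corrected.

    The Bonferroni family is the set of group pairs within this metric.
    Ties use the tie-corrected normal approximation; a pair in which every
    value is identical has no rank information and reports p = 1 with a
    warning note.
    """
    notes: list[str] = []
    k = len(data.labels)
    n_pairs = k * (k - 1) // 2
    raw = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        a, b = data.values[i], data.values[j]
        if np.ptp(np.concatenate([a, b])) == 0:
            notes.append(
                f"pair ({data.labels[i]}, {data.labels[j]}): zero variance, p set to 1"
            )
            pij = 1.0
        else:
            pij = float(
                sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            )
        raw[i, j] = raw[j, i] = pij
    corrected = np.minimum(raw * (n_pairs if n_pairs > 1 else 1), 1.0)
    np.fill_diagonal(corrected, 1.0)
    test = "wilcoxon_bonferroni" if n_pairs > 1 else "wilcoxon"
    tendencies = {lab: float(np.median(v)) for lab, v in zip(data.labels, data.values)}
    return PairwiseStats(
        test_used=test,
        labels=list(data.labels),
        p_raw=raw,
        p_corrected=corrected,
        alpha=alpha,
        letters=compact_letter_display(data.labels, corrected, alpha),
        tendencies=tendencies,
        notes=notes,
    )


def apply_repeat_correction(p_matrix: np.ndarray, k: int = 2) -> np.ndarray:
    """Correct for *k* repeated measurements: multiply p by k, cap at 1.

    Walking speed and stripe deviation are two measures of the same
    session, hence the default k = 2 for those metrics; sugar-response
    scores come from a separate experiment and receive no such correction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return np.minimum(np.asarray(p_matrix, dtype=float) * k, 1.0)


def compact_letter_display(
    labels: list[str] | tuple[str, ...], p_matrix: np.ndarray, alpha: float
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Two groups share at least one letter iff their corrected p-value is
    >= alpha (i.e. they are not significantly different). Intransitive
    patterns (a~b, b~c, a!=c) yield multi-letter memberships. The letter
    count is not guaranteed minimal, but fully absorbed.
    """
    labels = list(labels)
    k = len(labels)
    p = np.asarray(p_matrix, dtype=float)
    sets: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not p[i, j] < alpha:
            continue
        new_sets: list[set[int]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.extend((s - {i}, s - {j}))
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [
            s
            for idx, s in enumerate(new_sets)
            if s
            and not any(
                s < t or (s == t and idx > jdx) for jdx, t in enumerate(new_sets)
            )
        ]
    sets.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter_idx, s in enumerate(sets):
        letter = (
            alphabet[letter_idx]
            if letter_idx < 26
            else alphabet[letter_idx // 26 - 1] + alphabet[letter_idx % 26]
        )
        for gi in sorted(s):
            out[labels[gi]] += letter
    return out


def compare_groups(
    data: GroupedMeasurements,
    alpha: float = DEFAULT_ALPHA,
    repeat_k: int = 1,
    branch: str | None = None,
) -> PairwiseStats:
    """Run the full comparison scheme on one metric.

    Gates on normality (unless *branch* forces one), runs the chosen
    pairwise comparison, applies the repeated-measurement correction
    (``repeat_k`` = 2 for the two Buridan measures), and assigns letters
    from the final corrected matrix.
    """
    gate = normality_gate(data)
    chosen = branch or gate.branch
    if chosen == "parametric":
        result = parametric_compare(data, alpha)
    elif chosen == "nonparametric":
        result = nonparametric_compare(data, alpha)
    else:
        raise ValueError(f"unknown branch {chosen!r}")
    result.gate = gate
    if repeat_k > 1:
        result.p_corrected = apply_repeat_correction(result.p_corrected, repeat_k)
        np.fill_diagonal(result.p_corrected, 1.0)
        result.repeat_k = repeat_k
        result.letters = compact_letter_display(
            result.labels, result.p_corrected, alpha
        )
    return result


def stats_report(result: PairwiseStats, metric_name: str) -> dict:
    """JSON-serialisable report of one metric's comparison."""
    pairs = [
        {
            "a": result.labels[i],
            "b": result.labels[j],
            "p_raw": float(result.p_raw[i, j]),
            "p_corrected": float(result.p_corrected[i, j]),
            "significant": bool(result.p_corrected[i, j] < result.alpha),
        }
        for i, j in itertools.combinations(range(len(result.labels)), 2)
    ]
    return {
        "metric": metric_name,
        "test_used": result.test_used,
        "alpha": result.alpha,
        "repeat_correction_k": result.repeat_k,
        "branch": result.gate.branch if result.gate else None,
        "shapiro_p": result.gate.p_values if result.gate else None,
        "gate_warnings": result.gate.warnings if result.gate else [],
        "tendencies": result.tendencies,
        "letters": result.letters,
        "pairs": pairs,
        "notes": result.notes,
    }
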