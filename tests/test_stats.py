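"""Statistics scheme: gate behaviour, both branches, corrections, letters."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import buridan as b
from buridan.stats import DEFAULT_ALPHA, stats_report


def grouped(metric, **groups):
    labels = list(groups)
    return b.GroupedMeasurements(metric, labels, [np.asarray(groups[g], float) for g in labels])


class TestNormalityGate:
    def test_normal_groups_mostly_pass(self):
        rng = np.random.default_rng(0)
        hits = sum(
            b.normality_gate(
                grouped("m", a=rng.normal(0, 1, 50), b=rng.normal(0, 1, 50), c=rng.normal(0, 1, 50))
            ).branch
            == "parametric"
            for _ in range(100)
        )
        assert hits >= 85  # type-I rate of the gate over three groups

    def test_skewed_group_flips_the_branch(self):
        rng = np.random.default_rng(1)
        hits = sum(
            b.normality_gate(
                grouped("m", a=rng.normal(0, 1, 50), b=rng.lognormal(0, 1.0, 50))
            ).branch
            == "nonparametric"
            for _ in range(100)
        )
        assert hits >= 95

    def test_constant_group_falls_back_with_warning(self):
        gate = b.normality_gate(grouped("m", a=[1.0, 1.0, 1.0, 1.0], b=[1, 2, 3, 4]))
        assert gate.branch == "nonparametric"
        assert gate.warnings

    def test_tiny_group_falls_back(self):
        gate = b.normality_gate(grouped("m", a=[1.0, 2.0], b=[1, 2, 3, 4]))
        assert gate.branch == "nonparametric"


class TestParametric:
    def test_welch_equals_classic_t_under_equal_variance(self):
        """With equal n and exactly equal sample variances, Welch's t and
        the pooled two-sample t coincide."""
        from scipy import stats as sps

        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        c = a + 1.7  # same sample variance, shifted
        res = b.parametric_compare(grouped("m", a=a, b=c))
        classic = sps.ttest_ind(a, c, equal_var=True).pvalue
        assert res.p("a", "b") == pytest.approx(classic, abs=1e-9)
        assert res.test_used == "welch_t"

    def test_one_way_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(5)
        vals = {g: rng.normal(m, 2.0, n) for g, m, n in
                [("a", 10, 20), ("b", 12, 25), ("c", 11, 15)]}
        res = b.parametric_compare(grouped("m", **vals))
        data = np.concatenate(list(vals.values()))
        labels = np.concatenate([[g] * len(v) for g, v in vals.items()])
        sm = pairwise_tukeyhsd(data, labels)
        for (g1, g2), p in zip(
            itertools.combinations(sorted(vals), 2), sm.pvalues
        ):
            assert res.p(g1, g2) == pytest.approx(p, abs=1e-6)

    def test_strong_effects_all_pairs_significant(self):
        rng = np.random.default_rng(6)
        hits = 0
        reps = 100
        for _ in range(reps):
            res = b.parametric_compare(
                grouped(
                    "m",
                    wt=rng.normal(10, 2, 60),
                    het=rng.normal(12, 2, 60),
                    hom=rng.normal(7, 2, 60),
                )
            )
            if all(
                res.significant(x, y)
                for x, y in itertools.combinations(("wt", "het", "hom"), 2)
            ):
                hits += 1
        assert hits >= 99

    def test_two_factor_model_and_empty_cell_error(self):
        rng = np.random.default_rng(7)
        data = grouped("m", a=rng.normal(0, 1, 40), b=rng.normal(1, 1, 40))
        data.labels.append("c")
        data.values.append(rng.normal(2, 1, 40))
        data.batch = [np.repeat(["b1", "b2"], 20)] * 3
        res = b.parametric_compare(data)
        assert res.test_used == "anova_tukey"
        assert not res.notes  # two-factor model used, no deviation note
        data.batch = [
            np.repeat(["b1", "b2"], 20),
            np.repeat(["b1", "b2"], 20),
            np.repeat("b1", 40),  # group c never measured in batch b2
        ]
        with pytest.raises(b.DesignError, match="batch=b2"):
            b.parametric_compare(data)


class TestNonparametric:
    def test_identical_groups_give_p_one(self):
        res = b.nonparametric_compare(grouped("m", a=[1.0, 1, 1], b=[1.0, 1, 1]))
        assert res.p("a", "b") == 1.0
        assert res.notes  # zero-variance warning

    def test_bonferroni_factor_is_number_of_pairs(self):
        rng = np.random.default_rng(8)
        res = b.nonparametric_compare(
            grouped("m", a=rng.normal(0, 1, 20), b=rng.normal(0.5, 1, 20), c=rng.normal(1, 1, 20))
        )
        for i, j in itertools.combinations(range(3), 2):
            assert res.p_corrected[i, j] == pytest.approx(
                min(res.p_raw[i, j] * 3, 1.0)
            )

    def test_corrected_p_never_below_raw(self):
        rng = np.random.default_rng(9)
        res = b.nonparametric_compare(
            grouped("m", a=rng.normal(0, 1, 15), b=rng.normal(0, 1, 15), c=rng.normal(0, 1, 15))
        )
        assert (res.p_corrected >= res.p_raw - 1e-15).all()
        assert (res.p_corrected <= 1.0).all()


class TestRepeatCorrection:
    def test_doubling_crosses_alpha(self):
        out = b.apply_repeat_correction(np.array([[1.0, 0.004], [0.004, 1.0]]), k=2)
        assert out[0, 1] == pytest.approx(0.008)
        assert 0.008 > DEFAULT_ALPHA  # significance at 0.005 is lost

    def test_cap_at_one(self):
        assert b.apply_repeat_correction(np.array([0.9]), k=2)[0] == 1.0

    def test_k_one_is_identity(self):
        p = np.array([0.1, 0.5, 1.0])
        np.testing.assert_array_equal(b.apply_repeat_correction(p, k=1), p)


class TestCompactLetterDisplay:
    def test_all_pairs_distinct(self):
        p = np.full((3, 3), 0.0001)
        np.fill_diagonal(p, 1.0)
        letters = b.compact_letter_display(["x", "y", "z"], p, alpha=0.005)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_no_pair_distinct(self):
        p = np.ones((3, 3))
        letters = b.compact_letter_display(["x", "y", "z"], p, alpha=0.005)
        assert set(letters.values()) == {"a"}

    def test_intransitive_chain(self):
        # x ~ y, y ~ z, x != z  ->  x: a, y: ab, z: b
        p = np.array([[1.0, 0.5, 0.001], [0.5, 1.0, 0.5], [0.001, 0.5, 1.0]])
        letters = b.compact_letter_display(["x", "y", "z"], p, alpha=0.005)
        assert letters == {"x": "a", "y": "ab", "z": "b"}

    @settings(max_examples=200, derandomize=True)
    @given(
        st.integers(min_value=2, max_value=6),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_sharing_iff_condition(self, k, seed):
        """Two groups share a letter iff they are not significantly
        different, for random p-matrices."""
        rng = np.random.default_rng(seed)
        p = rng.random((k, k))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 1.0)
        alpha = 0.4  # large alpha so significant pairs actually occur
        labels = [f"g{i}" for i in range(k)]
        letters = b.compact_letter_display(labels, p, alpha)
        for i, j in itertools.combinations(range(k), 2):
            share = bool(set(letters[labels[i]]) & set(letters[labels[j]]))
            assert share == (not p[i, j] < alpha)
        assert all(letters[lab] for lab in labels)


class TestCompareGroups:
    def test_repeat_correction_applied_to_letters(self):
        rng = np.random.default_rng(10)
        data = grouped("speed", a=rng.normal(10, 1, 30), b=rng.normal(10.9, 1, 30))
        plain = b.compare_groups(data, alpha=0.005, repeat_k=1, branch="parametric")
        corrected = b.compare_groups(data, alpha=0.005, repeat_k=2, branch="parametric")
        assert corrected.p("a", "b") == pytest.approx(min(plain.p("a", "b") * 2, 1.0))

    def test_gate_is_logged(self):
        rng = np.random.default_rng(11)
        res = b.compare_groups(grouped("m", a=rng.normal(0, 1, 30), b=rng.normal(0, 1, 30)))
        assert res.gate is not None
        assert set(res.gate.p_values) == {"a", "b"}

    def test_report_is_json_serialisable(self):
        import json

        rng = np.random.default_rng(13)
        res = b.compare_groups(grouped("m", a=rng.normal(0, 1, 30), b=rng.normal(2, 1, 30)))
        json.dumps(stats_report(res, "m"))
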