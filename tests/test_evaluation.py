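"""Severity-group evaluation: F statistics, RP ratios, published arithmetic."""

import numpy as np
import pytest
from scipy import stats

from irtscore.evaluation import (
    SEVERITY_ORDER,
    anova_f,
    bonferroni_adjust,
    build_evaluation_table,
    group_summary,
    pairwise_f,
    relative_precision,
)
from irtscore.reference import load_reference_evaluation

PAIR_COLS = ["d01", "d02", "d03", "d12", "d13", "d23"]


@pytest.fixture(scope="module")
def labelled_scores(rng=np.random.default_rng(7)):
    labels = np.array(
        ["none"] * 300 + ["mild"] * 30 + ["moderate"] * 15 + ["severe"] * 10,
        dtype=object,
    )
    means = {"none": 2.0, "mild": 8.0, "moderate": 16.0, "severe": 30.0}
    scores = np.array([rng.normal(means[l], 4.0) for l in labels])
    return scores, labels


def test_group_summary_printed_mean_difference():
    """Published none/severe means 1.37 and 32.25 differ by 30.88."""
    scores = np.array([1.37] * 3 + [32.25] * 3)
    labels = np.array(["none"] * 3 + ["severe"] * 3, dtype=object)
    frame = group_summary(scores, labels)
    assert frame.loc["none", "diff_vs_severe"] == pytest.approx(30.88)
    assert frame.loc["none", "se"] == 0.0  # identical values


def test_group_summary_identical_groups_zero_differences(labelled_scores):
    scores, labels = labelled_scores
    same = np.where(np.isin(labels, ("none", "mild")), 5.0, 5.0)
    frame = group_summary(same, labels)
    for col in [c for c in frame.columns if c.startswith("diff")]:
        assert np.allclose(frame[col].dropna(), 0.0)


def test_anova_matches_scipy_oracle(labelled_scores):
    scores, labels = labelled_scores
    F, df1, df2, p = anova_f(scores, labels)
    groups = [scores[labels == g] for g in SEVERITY_ORDER]
    oracle = stats.f_oneway(*groups)
    assert F == pytest.approx(oracle.statistic, rel=1e-12)
    assert p == pytest.approx(oracle.pvalue, rel=1e-9)
    assert (df1, df2) == (3, len(scores) - 4)


def test_anova_null_pvalues_uniform(rng):
    """Equal-mean groups: ANOVA p-values pass a KS test for uniformity."""
    ps = []
    labels = np.array(["none"] * 40 + ["mild"] * 40 + ["severe"] * 40, dtype=object)
    for _ in range(300):
        ps.append(anova_f(rng.standard_normal(120), labels)[3])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_anova_degenerate_cases():
    labels = np.array(["none"] * 4 + ["mild"] * 4, dtype=object)
    F, *_ = anova_f(np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float), labels)
    assert F == 0.0  # duplicated halves
    F_inf, _, _, p = anova_f(np.array([1.0] * 4 + [2.0] * 4), labels)
    assert np.isinf(F_inf) and p == 0.0


def test_pairwise_f_equals_t_squared(rng):
    for _ in range(20):
        a = rng.normal(0, 1, rng.integers(5, 40))
        b = rng.normal(0.5, 1.3, rng.integers(5, 40))
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert pairwise_f(a, b) == pytest.approx(t**2, abs=1e-10)


def test_pairwise_f_monotone_in_shift(rng):
    a = rng.normal(0, 1, 30)
    b = rng.normal(0, 1, 30)
    base = pairwise_f(a, b + 1.0)
    assert pairwise_f(a, b + 2.0) > base
    assert pairwise_f(a, a) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "f,ref,expected",
    [(192.35, 164.82, 1.167), (75.94, 35.64, 2.131), (100.0, 100.0, 1.000)],
)
def test_relative_precision_printed_ratios(f, ref, expected):
    assert relative_precision(f, ref) == pytest.approx(expected, abs=5e-4)


def test_relative_precision_zero_reference_undefined():
    with pytest.raises(ValueError):
        relative_precision(10.0, 0.0)


def test_bonferroni():
    np.testing.assert_allclose(bonferroni_adjust([0.01], 6), [0.06])
    np.testing.assert_allclose(bonferroni_adjust([0.5], 6), [1.0])
    p = np.linspace(0, 1, 11)
    assert np.all(bonferroni_adjust(p, 6) >= p)
    with pytest.raises(ValueError):
        bonferroni_adjust([1.2], 6)


def test_evaluation_table_reference_rp_is_one(labelled_scores):
    scores, labels = labelled_scores
    sets = {"unweighted": scores, "weighted": scores * 2.3 + 1.0}
    table = build_evaluation_table(sets, labels)
    rp_ref = table.frame.query("method == 'unweighted' and quantity == 'RP'")
    for col in ["overall"] + PAIR_COLS:
        assert rp_ref[col].iloc[0] == pytest.approx(1.0)


def test_rp_scale_invariance_and_recomputation(labelled_scores):
    """An affine-rescaled method has RP 1 everywhere; RP cells equal
    independently recomputed F ratios."""
    scores, labels = labelled_scores
    rng = np.random.default_rng(3)
    other = scores + rng.normal(0, 2.0, scores.size)
    sets = {"unweighted": scores, "affine": 5.0 * scores, "noisy": other}
    table = build_evaluation_table(sets, labels)
    rp_aff = table.frame.query("method == 'affine' and quantity == 'RP'")
    for col in ["overall"] + PAIR_COLS:
        assert rp_aff[col].iloc[0] == pytest.approx(1.0, abs=1e-10)
    f_rows = table.frame[table.frame["quantity"] == "F"].set_index("method")
    rp_rows = table.frame[table.frame["quantity"] == "RP"].set_index("method")
    for col in ["overall"] + PAIR_COLS:
        want = f_rows.loc["noisy", col] / f_rows.loc["unweighted", col]
        assert rp_rows.loc["noisy", col] == pytest.approx(want, abs=1e-12)


def test_evaluation_table_rejects_mismatched_sets(labelled_scores):
    scores, labels = labelled_scores
    with pytest.raises(ValueError, match="scored"):
        build_evaluation_table(
            {"unweighted": scores, "short": scores[:-5]}, labels
        )


def test_published_table_rp_and_differences_internally_consistent():
    """Every published RP cell equals the ratio of the published F statistics,
    and every published mean difference matches the published means."""
    ref = load_reference_evaluation()
    f_rows = ref[ref["quantity"] == "F"].set_index("method")
    rp_rows = ref[ref["quantity"] == "RP"].set_index("method")
    cols = ["overall"] + PAIR_COLS
    # printed F carries a half-unit of rounding at 2 dp, printed RP at 3 dp
    for method in rp_rows.index:
        for col in cols:
            want = f_rows.loc[method, col] / f_rows.loc["unweighted", col]
            assert rp_rows.loc[method, col] == pytest.approx(want, abs=1e-3), (
                method, col)
    means = ref[ref["quantity"] == "mean"].set_index("method")
    diffs = ref[ref["quantity"] == "mean_diff"].set_index("method")
    group_cols = dict(zip(PAIR_COLS, [("none", "mild"), ("none", "moderate"),
                                      ("none", "severe"), ("mild", "moderate"),
                                      ("mild", "severe"), ("moderate", "severe")]))
    # two means rounded at 2 dp and the printed diff itself: +/- 0.015 slack
    for method in diffs.index:
        for col, (lo, hi) in group_cols.items():
            want = means.loc[method, hi] - means.loc[method, lo]
            assert diffs.loc[method, col] == pytest.approx(want, abs=0.0151), (
                method, col)
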