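"""Assumption screening: CFA indices, local dependence, Loevinger's H, item fit."""

import numpy as np
import pytest

from irtscore import SimulationConfig, simulate_grm_cohort
from irtscore.assumptions import (
    CfaFit,
    chi2_p_consistent,
    chi2w_item_fit,
    fit_indices,
    local_dependence_flags,
    loevinger_h,
    one_factor_cfa,
)
from irtscore.estimate import FitResult
from irtscore.quadrature import normal_grid
from irtscore.reference import load_reference_item_fit


# ---------------------------------------------------------------------------
# CFA
# ---------------------------------------------------------------------------


def _single_factor_sample(rng, n=2000, p=9, loading=0.75):
    f = rng.standard_normal(n)
    lam = np.full(p, loading)
    eps = rng.standard_normal((n, p)) * np.sqrt(1 - loading**2)
    return f[:, None] * lam[None, :] + eps


def test_cfa_fit_indices_formula_oracle():
    cfi, tli, rmsea = fit_indices(120.0, 27, 800.0, 36, 1000)
    assert rmsea == pytest.approx(np.sqrt(93.0 / (27 * 999)))
    assert cfi == pytest.approx(1 - 93.0 / 764.0)
    assert tli == pytest.approx(((800 / 36) - (120 / 27)) / ((800 / 36) - 1))


def test_cfa_saturated_model_has_zero_rmsea():
    cfi, tli, rmsea = fit_indices(27.0, 27, 500.0, 36, 1000)
    assert rmsea == 0.0
    assert cfi == 1.0


def test_cfa_strong_single_factor_passes_thresholds(rng):
    fit = one_factor_cfa(_single_factor_sample(rng))
    assert fit.cfi > 0.95
    assert fit.tli > 0.95
    assert fit.rmsea < 0.06
    assert np.abs(fit.residual_corr).max() < 0.20


def test_cfa_zero_variance_item_named(rng):
    Y = _single_factor_sample(rng, n=300)
    Y[:, 4] = 1.0
    with pytest.raises(ValueError, match="Weight"):
        one_factor_cfa(Y)


def test_local_dependence_flags_planted_residual():
    residual = np.zeros((9, 9))
    fit = CfaFit(10, 27, 100, 36, 1.0, 1.0, 0.0, np.ones(9), residual, 500)
    assert local_dependence_flags(fit) == []
    residual[2, 6] = residual[6, 2] = 0.35
    flagged = local_dependence_flags(fit)
    assert [(a, b) for a, b, _ in flagged] == [(3, 7)]


def test_local_dependence_detected_in_simulation(rng):
    """Two items sharing a nuisance factor get flagged in most replicates."""
    hits = 0
    for _ in range(25):
        Y = _single_factor_sample(rng, n=1500, loading=0.6)
        shared = rng.standard_normal(1500)
        Y[:, 0] += 0.9 * shared
        Y[:, 1] += 0.9 * shared
        flags = local_dependence_flags(one_factor_cfa(Y))
        if any({a, b} == {1, 2} for a, b, _ in flags):
            hits += 1
    assert hits >= 23  # >= 90% detection


# ---------------------------------------------------------------------------
# Loevinger's H
# ---------------------------------------------------------------------------


def test_h_perfect_guttman_scale_is_one():
    base = np.repeat(np.arange(5), 40)
    Y = np.column_stack([np.minimum(base, k) for k in range(1, 10)])
    res = loevinger_h(Y)
    assert res.H == pytest.approx(1.0)
    np.testing.assert_allclose(res.H_items, 1.0)
    # relabelling by a monotone transform keeps H = 1
    res2 = loevinger_h(Y**2)
    assert res2.H == pytest.approx(1.0)


def test_h_independent_items_near_zero(rng):
    Y = rng.integers(0, 7, size=(5000, 9)).astype(float)
    res = loevinger_h(Y)
    assert abs(res.H) < 0.05
    assert not res.pass_scale


def test_h_pairwise_enumeration_oracle():
    """H_ij against brute-force cov / cov_max from explicit joint counts."""
    # joint counts over (x, y) in {0,1}^2: [[40, 10], [5, 45]]
    x = np.array([0] * 50 + [1] * 50, dtype=float)
    y = np.array([0] * 40 + [1] * 10 + [0] * 5 + [1] * 45, dtype=float)
    cov = np.mean(x * y) - x.mean() * y.mean()
    cov_max = np.mean(np.sort(x) * np.sort(y)) - x.mean() * y.mean()
    Y = np.column_stack([x, y] + [x] * 7)  # pad to 9 items
    res = loevinger_h(Y)
    # item 2 pairs only with x-copies: its H_i is exactly cov/cov_max
    assert res.H_items[1] == pytest.approx(cov / cov_max)


def test_h_zero_variance_item_reported_undefined():
    Y = np.column_stack([np.ones(100)] + [np.arange(100) % 3] * 8).astype(float)
    res = loevinger_h(Y)
    assert res.undefined_items == (1,)
    assert np.isnan(res.H_items[0])


# ---------------------------------------------------------------------------
# chi2W item fit
# ---------------------------------------------------------------------------


def _fit_from(params, n):
    return FitResult(model="grm", params=params, loglik=0.0, n_params=0,
                     n_obs=n, converged=True, n_iter=0,
                     loglik_trace=np.array([0.0]))


def test_chi2w_null_calibration(reference_grm):
    """On data generated exactly from the evaluated parameters, the rejection
    rate at alpha = 0.05 stays at or below 0.10."""
    grid = normal_grid(41, 5.5)
    rejections = 0
    total = 0
    for rep in range(40):
        recs = simulate_grm_cohort(SimulationConfig(n=2000, seed=90000 + rep))
        frame = chi2w_item_fit(recs, _fit_from(reference_grm, 2000), grid=grid).frame
        ps = frame.loc[~frame["skipped"], "p"]
        rejections += int((ps < 0.05).sum())
        total += len(ps)
    assert rejections / total <= 0.10


def test_chi2w_detects_wrong_slope(reference_grm, grm_cohort_large):
    """Halving one item's discrimination in the evaluated parameters should
    light up that item's fit statistic."""
    from irtscore.params import GrmItemParams

    tampered = {"all": list(reference_grm["all"])}
    p = tampered["all"][0]
    tampered["all"][0] = GrmItemParams(a=p.a / 2.5, b=p.b)
    frame = chi2w_item_fit(
        grm_cohort_large, _fit_from(tampered, 2000), grid=normal_grid(41, 5.5)
    ).frame
    assert frame.loc[frame["item"] == 1, "p"].iloc[0] < 0.01


@pytest.mark.parametrize("chi2,p_text", [(3.07, "0.080"), (1.75, "0.186")])
def test_chi2w_printed_pairs_reproduce(chi2, p_text):
    from scipy import stats

    assert f"{stats.chi2.sf(chi2, 1):.3f}" == p_text


def test_reference_item_fit_pairs_consistent_with_df1():
    """All 18 published (chi2, p) pairs are chi-square(1)-tail consistent."""
    frame = load_reference_item_fit()
    assert len(frame) == 18
    for _, row in frame.iterrows():
        assert chi2_p_consistent(row["chi2"], row["p_text"]), (
            row["name"], row["chi2"], row["p_text"])
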