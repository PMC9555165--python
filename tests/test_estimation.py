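"""MMLE-EM estimation: likelihood oracles, EM behaviour, EAP, AIC/BIC/LRT."""

import numpy as np
import pytest
from scipy import stats

from irtscore import (
    EmConfig,
    SimulationConfig,
    eap_theta,
    fit_mmle_em,
    information_criteria,
    likelihood_ratio_test,
    marginal_loglik,
    normal_grid,
    simulate_grm_cohort,
)
from irtscore.estimate import FitResult, RefitNeeded
from irtscore.instrument import ItemResponse, ResponseRecord
from irtscore.params import GrmItemParams


def _fixture_cohort(n=20, seed=5):
    return simulate_grm_cohort(SimulationConfig(n=n, seed=seed))


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


def test_marginal_loglik_flat_items_are_theta_free():
    """With a = 0 every category probability is constant in theta, so the
    marginal equals the plain probability whatever the prior discretisation."""
    params = {"all": [GrmItemParams(a=1e-12, b=np.array([0.0])) for _ in range(9)]}
    rec = ResponseRecord(tuple(ItemResponse(0, 0) for _ in range(9)))
    want = 9 * np.log(0.5)
    assert marginal_loglik([rec], params, normal_grid(5, 3.0)) == pytest.approx(want, abs=1e-9)
    assert marginal_loglik([rec], params, normal_grid(501, 6.0)) == pytest.approx(want, abs=1e-9)


def test_marginal_loglik_grid_refinement_agrees(reference_grm, fine_grid):
    records = _fixture_cohort(20)
    ll_49 = marginal_loglik(records, reference_grm, normal_grid(49, 6.0))
    ll_fine = marginal_loglik(records, reference_grm, normal_grid(201, 6.0))
    assert ll_49 == pytest.approx(ll_fine, abs=1e-6 * abs(ll_fine))


def test_loglik_peaks_at_generating_values(reference_grm, grid, grm_cohort_large):
    """Perturbing thresholds away from the generating values lowers the
    marginal log-likelihood on a large simulated sample."""
    ll_true = marginal_loglik(grm_cohort_large, reference_grm, grid)
    for delta in (0.3, -0.3):
        perturbed = {
            "all": [GrmItemParams(a=p.a, b=p.b + delta) for p in reference_grm["all"]]
        }
        assert marginal_loglik(grm_cohort_large, perturbed, grid) < ll_true


def test_marginal_loglik_rejects_empty_and_tiny_grid(reference_grm):
    with pytest.raises(ValueError):
        marginal_loglik([], reference_grm)
    with pytest.raises(ValueError):
        normal_grid(1)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def test_em_symmetric_dichotomous_item_centres_threshold(grid):
    """A 50/50 dichotomised item yields a threshold at the latent centre."""
    rng = np.random.default_rng(1)
    # simulate 9 items; item 1 forced to an exact 50/50 split at theta ~ N(0,1)
    n = 600
    theta = rng.standard_normal(n)
    X = np.zeros((n, 9), dtype=np.int64)
    X[:, 0] = (theta + rng.logistic(0, 1, n) > 0).astype(np.int64)
    for i in range(1, 9):
        X[:, i] = (theta + rng.logistic(0, 1, n) > 0.5).astype(np.int64)
    fit = fit_mmle_em(X, "grm", grid=grid)
    assert abs(fit.params["all"][0].b[0]) < 0.15


def test_em_beats_coarse_grid_search_on_tiny_fixture(grid):
    """EM's optimum dominates a brute-force grid search over (a, b) values."""
    rng = np.random.default_rng(2)
    n = 200
    theta = rng.standard_normal(n)
    true = [(1.5, (-0.5, 0.8)), (0.9, (0.0, 1.2)), (2.2, (-1.0, 0.4))]
    X = np.zeros((n, 9), dtype=np.int64)
    for i, (a, bs) in enumerate(true * 3):
        cum = np.array([1.0 / (1.0 + np.exp(-a * (t - np.array(bs)))) for t in theta])
        u = rng.random(n)
        X[:, i] = (u < cum[:, 0]).astype(int) + (u < cum[:, 1]).astype(int)
    fit = fit_mmle_em(X, "grm", grid=grid)

    best_grid = -np.inf
    a_grid = [0.5, 1.0, 1.5, 2.0, 2.5]
    b1_grid = [-1.0, -0.5, 0.0, 0.5]
    gap_grid = [0.5, 1.0, 1.5]
    for a in a_grid:
        for b1 in b1_grid:
            for gap in gap_grid:
                params = {
                    "all": [
                        GrmItemParams(a=a, b=np.array([b1, b1 + gap], dtype=float))
                        for _ in range(9)
                    ]
                }
                best_grid = max(best_grid, marginal_loglik(X, params, grid))
    assert fit.loglik >= best_grid - 1e-3


def test_em_loglik_trace_monotone(grid, grm_cohort_small, em_config):
    fit = fit_mmle_em(grm_cohort_small, "grm", grid=grid, config=em_config)
    assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
    assert fit.converged


def test_em_nonconvergence_flagged_not_raised(grid, grm_cohort_small):
    fit = fit_mmle_em(
        grm_cohort_small, "grm", grid=grid, config=EmConfig(max_iter=2)
    )
    assert not fit.converged
    assert fit.n_iter == 2


def test_nrm_em_monotone_and_recovers_better_than_start(grid, nrm_cohort, em_config):
    fit = fit_mmle_em(nrm_cohort, "nrm", grid=grid, config=em_config)
    assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
    assert fit.loglik > fit.loglik_trace[0]


def test_dif_constraint_nesting_logliks(grid, grm_cohort_small, em_config):
    """all-free >= slope-shared >= all-shared, by construction of the nesting."""
    m0 = fit_mmle_em(grm_cohort_small, "grm", grid=grid, group_by="gender",
                     config=em_config)
    m1 = fit_mmle_em(grm_cohort_small, "grm", grid=grid, group_by="gender",
                     constraints={2: "thresholds_free"}, config=em_config, start=m0)
    m2 = fit_mmle_em(grm_cohort_small, "grm", grid=grid, group_by="gender",
                     constraints={2: "free"}, config=em_config, start=m1)
    assert m1.loglik >= m0.loglik - 1e-6
    assert m2.loglik >= m1.loglik - 1e-6
    assert m0.n_params < m1.n_params < m2.n_params


# ---------------------------------------------------------------------------
# information criteria and LRT
# ---------------------------------------------------------------------------


def test_information_criteria_formulas():
    aic, bic = information_criteria(-100.0, 10, 1000)
    assert aic == pytest.approx(220.0)
    assert bic == pytest.approx(200.0 + 10 * np.log(1000))
    _, bic_e2 = information_criteria(-100.0, 10, np.e**2)
    assert bic_e2 == pytest.approx(220.0, abs=1e-9)  # ln N = 2 at N = e^2
    with pytest.raises(ValueError):
        information_criteria(-100.0, 10, 1)


def test_aic_prefers_grm_on_grm_data(grid, grm_cohort_large, em_config):
    grm = fit_mmle_em(grm_cohort_large, "grm", grid=grid, config=em_config)
    nrm = fit_mmle_em(grm_cohort_large, "nrm", grid=grid, config=em_config)
    assert grm.aic < nrm.aic


def _fake_fit(loglik, n_params):
    return FitResult(model="grm", params={}, loglik=loglik, n_params=n_params,
                     n_obs=100, converged=True, n_iter=1,
                     loglik_trace=np.array([loglik]))


def test_lrt_identical_fits():
    chi2, df, p = likelihood_ratio_test(_fake_fit(-50.0, 5), _fake_fit(-50.0, 6))
    assert chi2 == 0.0 and df == 1 and p == pytest.approx(1.0)


def test_lrt_chi2_table_value():
    chi2, df, p = likelihood_ratio_test(_fake_fit(-51.92, 5), _fake_fit(-50.0, 6))
    assert chi2 == pytest.approx(3.84)
    assert p == pytest.approx(stats.chi2.sf(3.84, 1), abs=1e-12)
    assert p == pytest.approx(0.050, abs=5e-4)


def test_lrt_negative_chi2_raises_refit_signal():
    with pytest.raises(RefitNeeded):
        likelihood_ratio_test(_fake_fit(-49.0, 5), _fake_fit(-50.0, 6))
    with pytest.raises(ValueError):
        likelihood_ratio_test(_fake_fit(-50.0, 6), _fake_fit(-50.0, 5))


# ---------------------------------------------------------------------------
# EAP
# ---------------------------------------------------------------------------


def test_eap_empty_record_returns_prior(reference_grm, grid):
    rec = ResponseRecord((None,) * 9)
    theta, sd = eap_theta(rec, reference_grm, grid)
    assert theta == pytest.approx(0.0, abs=1e-9)
    assert sd == pytest.approx(1.0, abs=0.05)  # truncated-grid prior SD


def test_eap_orders_extreme_response_patterns(reference_grm, grid):
    low = ResponseRecord(tuple(ItemResponse(0, 0) for _ in range(9)))
    high = ResponseRecord(tuple(ItemResponse(3, 3) for _ in range(9)))
    t_low, _ = eap_theta(low, reference_grm, grid)
    t_high, _ = eap_theta(high, reference_grm, grid)
    assert t_high > t_low


def test_eap_matches_fine_riemann_oracle(reference_grm):
    """Grid EAP against a very fine Riemann-sum posterior mean."""
    records = _fixture_cohort(15, seed=9)
    t_grid, sd_grid = eap_theta(records, reference_grm, normal_grid(61, 6.0))
    t_fine, sd_fine = eap_theta(records, reference_grm, normal_grid(20001, 6.0))
    np.testing.assert_allclose(t_grid, t_fine, atol=1e-4)
    np.testing.assert_allclose(sd_grid, sd_fine, atol=1e-4)
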