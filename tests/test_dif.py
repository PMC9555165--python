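"""Gender DIF: LRT structure, adjusted fits, and the substitution rule."""

import numpy as np
import pytest

from irtscore import (
    EmConfig,
    SimulationConfig,
    fit_mmle_em,
    simulate_grm_cohort,
    simulate_nrm_cohort,
)
from irtscore.dif import (
    dif_test_item,
    fit_dif_adjusted,
    endorsement_counts,
    substitute_missing_categories,
)
from irtscore.params import (
    NrmItemParams,
    SOURCE_OTHER_GENDER,
    SOURCE_PREVIOUS_FREQUENCY,
)
from irtscore.quadrature import normal_grid


@pytest.fixture(scope="module")
def dif_grid():
    return normal_grid(31, 5.0)


@pytest.fixture(scope="module")
def dif_config():
    return EmConfig(tol_loglik=1e-6, max_iter=400)


def test_small_group_skipped(dif_grid):
    recs = simulate_grm_cohort(SimulationConfig(n=60, seed=0, female_fraction=0.9))
    with pytest.warns(UserWarning, match="fewer than"):
        res = dif_test_item(recs, 1, "grm", dif_grid, min_group=30)
    assert res.skipped


def test_dif_flags_shifted_item_more_than_clean_item(dif_grid, dif_config):
    """With a +0.7 female threshold shift on item 2, item 2's UDIF statistic
    dominates clean item 3's across replicates."""
    wins = 0
    for rep in range(6):
        recs = simulate_grm_cohort(
            SimulationConfig(n=800, seed=4000 + rep, dif_shifts={2: 0.7})
        )
        r_dif = dif_test_item(recs, 2, "grm", dif_grid, dif_config)
        r_clean = dif_test_item(recs, 3, "grm", dif_grid, dif_config)
        if r_dif.chi2_udif > r_clean.chi2_udif:
            wins += 1
    assert wins >= 5


def test_dif_adjusted_empty_set_collapses_to_pooled(dif_grid, dif_config,
                                                    grm_cohort_small):
    adj = fit_dif_adjusted(grm_cohort_small, "grm", (), dif_grid, dif_config)
    pooled = fit_mmle_em(grm_cohort_small, "grm", grid=dif_grid,
                         group_by="gender", config=dif_config)
    assert adj.fit.loglik == pytest.approx(pooled.loglik, abs=1e-4)
    for g in ("male", "female"):
        for p_adj, p_pool in zip(adj.params[g], pooled.params[g]):
            assert p_adj.a == pytest.approx(p_pool.a, abs=1e-5)


def test_dif_adjusted_structure_and_recovery(dif_grid, dif_config):
    """Gender-specific thresholds on items 2 and 5: the adjusted fit keeps one
    slope per item, differs across genders only there, and tracks the
    gender-specific truth more closely than the pooled fit."""
    shift = 0.5
    recs = simulate_grm_cohort(
        SimulationConfig(n=1500, seed=77, dif_shifts={2: shift, 5: shift})
    )
    adj = fit_dif_adjusted(recs, "grm", (2, 5), dif_grid, dif_config)
    pooled = fit_mmle_em(recs, "grm", grid=dif_grid, config=dif_config)

    from irtscore import load_reference_grm

    truth = load_reference_grm("pooled")["all"]
    for item in (2, 5):
        pm, pf = adj.params["male"][item - 1], adj.params["female"][item - 1]
        assert pm.a == pytest.approx(pf.a)  # shared slope
        assert not np.allclose(pm.b, pf.b, equal_nan=True)
        true_m = truth[item - 1].b
        true_f = truth[item - 1].b + shift
        mask = np.isfinite(pm.b) & np.isfinite(pf.b)
        rmse_adj = np.sqrt(np.nanmean(
            np.concatenate([(pm.b - true_m)[mask] ** 2, (pf.b - true_f)[mask] ** 2])
        ))
        pp = pooled.params["all"][item - 1].b
        rmse_pooled = np.sqrt(np.nanmean(
            np.concatenate([(pp - true_m)[mask] ** 2, (pp - true_f)[mask] ** 2])
        ))
        assert rmse_adj < rmse_pooled
    for item in (1, 3, 4, 6, 7, 8, 9):
        pm, pf = adj.params["male"][item - 1], adj.params["female"][item - 1]
        assert pm.a == pytest.approx(pf.a)
        np.testing.assert_allclose(pm.b, pf.b, equal_nan=True)


# ---------------------------------------------------------------------------
# substitution rule
# ---------------------------------------------------------------------------


def _nrm(a_by_label, c_by_label):
    labels = (0, 11, 12, 13, 21, 22, 23, 31, 32, 33)
    a = np.array([a_by_label.get(lab, np.nan) for lab in labels])
    c = np.array([c_by_label.get(lab, np.nan) for lab in labels])
    a[0], c[0] = 0.0, 0.0
    return NrmItemParams(a=a, c=c)


def _counts(present_by_gender):
    out = {}
    for gender, present in present_by_gender.items():
        counts = np.zeros((9, 10), dtype=np.int64)
        labels = (0, 11, 12, 13, 21, 22, 23, 31, 32, 33)
        for item, labs in present.items():
            for lab in labs:
                counts[item - 1, labels.index(lab)] = 5
        out[gender] = counts
    return out


def test_substitution_other_gender_then_previous_frequency():
    all_labels = (0, 11, 12, 13, 21, 22, 23, 31, 32, 33)
    full = {lab: 1.0 * lab for lab in all_labels if lab}
    male_missing = [lab for lab in all_labels if lab not in (0, 32, 12, 13)]
    male = _nrm({lab: 2.0 * lab for lab in male_missing},
                {lab: 0.5 for lab in male_missing})
    female = _nrm(full, {lab: 0.25 for lab in full})
    counts = _counts({
        "male": {i: male_missing for i in range(1, 10)},
        "female": {i: [lab for lab in all_labels if lab] for i in range(1, 10)},
    })
    out = substitute_missing_categories(
        {"male": [male] * 9, "female": [female] * 9}, counts
    )
    m = out["male"][1]
    # 32 absent for males only: copied from the female cell, exactly
    assert m.value(32) == out["female"][1].value(32)
    assert m.substituted[32] == SOURCE_OTHER_GENDER


def test_substitution_previous_frequency_transitive():
    """12 and 13 missing in both genders: both inherit 11's value."""
    present = [0, 11, 21, 22, 23, 31, 32, 33]
    a_vals = {lab: float(lab) for lab in present if lab}
    c_vals = {lab: 0.1 for lab in present if lab}
    params = {"male": [_nrm(a_vals, c_vals)] * 9, "female": [_nrm(a_vals, c_vals)] * 9}
    counts = _counts({"male": {i: present[1:] for i in range(1, 10)},
                      "female": {i: present[1:] for i in range(1, 10)}})
    out = substitute_missing_categories(params, counts)
    for g in ("male", "female"):
        p = out[g][4]
        assert p.value(12) == p.value(11)
        assert p.value(13) == p.value(11)
        assert p.substituted[12] == SOURCE_PREVIOUS_FREQUENCY
        assert p.substituted[13] == SOURCE_PREVIOUS_FREQUENCY


def test_substitution_no_missing_cells_is_identity():
    all_labels = [lab for lab in (11, 12, 13, 21, 22, 23, 31, 32, 33)]
    a_vals = {lab: float(lab) for lab in all_labels}
    c_vals = {lab: -0.3 for lab in all_labels}
    params = {"male": [_nrm(a_vals, c_vals)] * 9, "female": [_nrm(a_vals, c_vals)] * 9}
    counts = _counts({"male": {i: all_labels for i in range(1, 10)},
                      "female": {i: all_labels for i in range(1, 10)}})
    out = substitute_missing_categories(params, counts)
    for g in ("male", "female"):
        for p in out[g]:
            assert p.substituted == {}


def test_substitution_unresolvable_intensity_raises():
    """Frequency-1 cell empty in both genders with nothing below: hard error."""
    present = [0, 11, 12, 13, 22, 23, 31, 32, 33]  # 21 missing, so is its floor
    a_vals = {lab: 1.0 for lab in present if lab}
    c_vals = {lab: 1.0 for lab in present if lab}
    params = {"male": [_nrm(a_vals, c_vals)] * 9, "female": [_nrm(a_vals, c_vals)] * 9}
    counts = _counts({"male": {i: present[1:] for i in range(1, 10)},
                      "female": {i: present[1:] for i in range(1, 10)}})
    with pytest.raises(ValueError, match="21"):
        substitute_missing_categories(params, counts)


def test_constructed_sparsity_triggers_substitution_end_to_end(dif_grid):
    """Forcing male cell (item 4, label 32) empty in the generator produces a
    fit whose completed parameters flag exactly that substitution path."""
    recs = simulate_nrm_cohort(
        SimulationConfig(n=1200, seed=21, absent_cells=((4, "male", 32),))
    )
    counts = endorsement_counts(recs)
    assert counts["male"][3, 8] == 0  # label 32 is index 8
    adj = fit_dif_adjusted(recs, "nrm", dif_items=(4,), grid=dif_grid,
                           config=EmConfig(tol_loglik=1e-5, max_iter=200))
    p = adj.params["male"][3]
    assert 32 in p.substituted
    assert np.isfinite(p.a[8]) and np.isfinite(p.c[8])
    # every substituted cell matches its source exactly
    if p.substituted[32] == SOURCE_OTHER_GENDER:
        assert p.value(32) == adj.params["female"][3].value(32)
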