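"""Outfit statistics, homogeneity check, and item characteristic curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from fsrasch import (
    ItemParameters,
    conditional_loglik,
    fit_cml,
    graphical_model_check,
    icc,
    outfit,
    simulate,
    simulate_misfit,
    standardized_residuals,
    SimulationConfig,
)
from fsrasch.persons import PersonScores, score_households


def _manual_scores(theta):
    """PersonScores stub with prescribed abilities."""
    n = len(theta)
    return PersonScores(
        pd.DataFrame(
            {
                "household_id": range(n),
                "district": "",
                "raw_score": np.nan,
                "theta": theta,
                "se": np.nan,
                "extreme": False,
                "partial": False,
                "classification": "",
            }
        )
    )


def test_residual_hand_values():
    """z = (X - P)/sqrt(PQ): X=1, P=0.8 -> 0.5; X=0, P=0.5 -> -1."""
    params = ItemParameters(item_id=["a", "b"], beta=np.array([0.0, 0.0]))
    # theta = ln 4 gives P = 0.8 on both items; theta = 0 gives P = 0.5
    data = np.array([[1.0, 0.0], [0.0, 1.0]])
    Z, mask = standardized_residuals(data, params, _manual_scores([np.log(4), 0.0]))
    np.testing.assert_allclose(Z[0, 0], 0.5, rtol=1e-12)  # X=1, P=0.8
    np.testing.assert_allclose(Z[1, 0], -1.0, rtol=1e-12)  # X=0, P=0.5
    np.testing.assert_allclose(Z[1, 1], 1.0, rtol=1e-12)
    assert mask.all()


def test_outfit_matches_hand_computation():
    """Tiny 2x2 case recomputed with explicit arithmetic."""
    params = ItemParameters(item_id=["a", "b"], beta=np.array([0.5, -0.5]))
    theta = np.array([0.3, -0.2])
    data = np.array([[1.0, 0.0], [1.0, 1.0]])
    stats = outfit(data, params, _manual_scores(theta))
    P = expit(theta[:, None] + np.array([0.5, -0.5])[None, :])
    z2 = (data - P) ** 2 / (P * (1 - P))
    expected_msq = z2.sum(axis=0) / (2 - 1)
    np.testing.assert_allclose(stats.frame["outfit_msq"], expected_msq, rtol=1e-10)
    np.testing.assert_allclose(stats.frame["outfit_chisq"], z2.sum(axis=0), rtol=1e-10)
    assert (stats.frame["df"] == 1).all()


def test_residual_means_near_zero_on_model_true_data():
    """ML person scoring forces per-household residual sums to zero, so
    per-item residual means vanish as n grows."""
    ds = simulate(SimulationConfig.from_preset("tororo", seed=3, n=10000))
    fit = fit_cml(ds.matrix)
    scores = score_households(ds.matrix, fit.params)
    Z, _ = standardized_residuals(ds.matrix, fit.params, scores)
    assert np.abs(Z.mean(axis=0)).max() < 0.05


def test_mean_square_scale_on_model_true_data():
    """Mean z^2 per item sits just below 1 (score-conditioning absorbs part
    of the within-household variance) but nowhere near the misfit bands."""
    ds = simulate(SimulationConfig.from_preset("tororo", seed=3, n=10000))
    fit = fit_cml(ds.matrix)
    scores = score_households(ds.matrix, fit.params)
    stats = outfit(ds.matrix, fit.params, scores)
    msq = stats.frame["outfit_msq"]
    assert 0.8 < msq.mean() < 1.05
    assert msq.min() > 0.6 and msq.max() < 1.4


def test_high_discrimination_item_overfits():
    """An item generated with slope 3 shows outfit MSQ well below 1."""
    cfg = SimulationConfig.from_preset("tororo", seed=15, n=1000)
    ds = simulate_misfit(cfg, ["E7"], slope=3.0)
    fit = fit_cml(ds.matrix)
    scores = score_households(ds.matrix, fit.params)
    stats = outfit(ds.matrix, fit.params, scores)
    msq7 = stats.frame.set_index("item").loc["E7", "outfit_msq"]
    n_used = stats.frame["df"].iloc[0] + 1
    assert msq7 < 1 - 3 * np.sqrt(2 / n_used)


def test_low_discrimination_item_underfits():
    cfg = SimulationConfig.from_preset("tororo", seed=16, n=1000)
    ds = simulate_misfit(cfg, ["E7"], slope=0.3)
    fit = fit_cml(ds.matrix)
    scores = score_households(ds.matrix, fit.params)
    stats = outfit(ds.matrix, fit.params, scores)
    assert stats.frame.set_index("item").loc["E7", "outfit_msq"] > 1.1


def test_duplicated_data_doubles_loglik(toy_two_item):
    """Basis of the LR identity: copies in both subgroups give LR = 0."""
    beta = fit_cml(toy_two_item).params.beta
    ll1 = conditional_loglik(beta, toy_two_item)
    ll2 = conditional_loglik(beta, np.tile(toy_two_item, (2, 1)))
    np.testing.assert_allclose(ll2, 2 * ll1, rtol=1e-12)
    # and the subgroup optima coincide with the pooled optimum
    np.testing.assert_allclose(
        fit_cml(np.tile(toy_two_item, (2, 1))).params.beta, beta, atol=1e-7
    )


def test_model_check_on_model_true_data(tororo_dataset):
    res = graphical_model_check(tororo_dataset.matrix)
    assert res.lr_stat >= 0
    assert res.df == len(res.items_used) - 1
    assert 0 <= res.p_value <= 1
    assert not res.reject(0.001)  # model-true data should not reject strongly
    assert res.median_score == np.median(tororo_dataset.matrix.raw_scores())


def test_model_check_invariant_to_row_order(tororo_dataset, rng):
    m = tororo_dataset.matrix
    res1 = graphical_model_check(m)
    perm = rng.permutation(m.n)
    from fsrasch.coding import BinaryResponseMatrix

    shuffled = BinaryResponseMatrix(
        X=m.X[perm],
        household_id=[m.household_id[i] for i in perm],
        item_id=m.item_id,
        district=None,
    )
    res2 = graphical_model_check(shuffled)
    np.testing.assert_allclose(res1.lr_stat, res2.lr_stat, atol=1e-6)


def test_model_check_detects_structural_misfit():
    """Strong discrimination heterogeneity breaks score-group invariance."""
    cfg = SimulationConfig.from_preset("tororo", seed=21, n=1000)
    ds = simulate_misfit(cfg, ["E4", "E6", "E9", "E10"], slope=3.0)
    res = graphical_model_check(ds.matrix)
    assert res.p_value < 0.05


def test_icc_half_probability_at_difficulty(tororo_fit):
    data = icc(tororo_fit.params, theta_grid=tororo_fit.params.eta)
    for j, item in enumerate(tororo_fit.params.item_id):
        np.testing.assert_allclose(data.curves[item].iloc[j], 0.5, atol=1e-12)


def test_icc_published_value():
    """At theta = 0 an item of difficulty -1.793 is affirmed with P = 0.857."""
    params = ItemParameters(item_id=["E2"], beta=np.array([1.793]))
    data = icc(params, theta_grid=np.array([0.0]))
    np.testing.assert_allclose(data.curves["E2"].iloc[0], 0.857, atol=5e-4)


def test_icc_curves_ordered_and_non_crossing(tororo_fit):
    data = icc(tororo_fit.params)
    eta = tororo_fit.params.eta
    order = np.argsort(eta)
    curves = data.curves.to_numpy()
    # harder items are pointwise below easier items: no crossings
    for a, b in zip(order[:-1], order[1:]):
        assert (curves[:, a] >= curves[:, b]).all()
    assert data.item_order == [tororo_fit.params.item_id[j] for j in order]
    assert ((curves > 0) & (curves < 1)).all()
    assert (np.diff(curves, axis=0) > 0).all()
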