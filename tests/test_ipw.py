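"""Strategy probabilities, cumulative weights, and the IPW estimator."""

import numpy as np
import pytest

import pregstrat as ps
from pregstrat.nuisance import TreatmentModelSet
from conftest import enumeration_gformula_two_period, make_two_period_cohort


def _constant_cohort(n=12, K=4, follow_k=3):
    """All subjects undelivered until K, following strategy follow_k."""
    A = (np.arange(1, K + 1)[None, :] >= follow_k).astype(float).repeat(n, 0)
    W = np.zeros((n, K))
    D = np.zeros((n, K), dtype=int)
    D[:, -1] = 1
    return ps.from_arrays(W, A, D, np.linspace(0, 1, n))


def test_strategy_probability_branches():
    c = _constant_cohort()
    models = TreatmentModelSet.from_constant(0.3, c.K)
    # t < k, undelivered: probability of remaining untreated = 0.7
    np.testing.assert_allclose(ps.strategy_probability(models, c, 3, 1), 0.7)
    # t = k: initiation probability = 0.3
    np.testing.assert_allclose(ps.strategy_probability(models, c, 3, 3), 0.3)
    # t > k: adherence automatic
    np.testing.assert_allclose(ps.strategy_probability(models, c, 3, 4), 1.0)


def test_strategy_probability_is_one_after_delivery():
    n, K = 6, 3
    W = np.zeros((n, K))
    A = np.zeros((n, K))
    D = np.zeros((n, K), dtype=int)
    D[:, 0] = 1  # delivered at t=1
    D[:, 1:] = 1
    A[:, 1:] = np.nan
    W[:, 1:] = np.nan
    c = ps.from_arrays(W, A, D, np.zeros(n))
    models = TreatmentModelSet.from_constant(0.3, K)
    for t in (2, 3):
        np.testing.assert_allclose(ps.strategy_probability(models, c, 3, t), 1.0)


def test_cumulative_weight_hand_product():
    # constant initiation probability 0.3, K=4, k=3: the follower weight at
    # any t >= 3 is 1 / (0.7 * 0.7 * 0.3) ~= 6.8027
    c = _constant_cohort(follow_k=3)
    models = TreatmentModelSet.from_constant(0.3, c.K)
    traj = ps.compute_weights(c, 3, models)
    np.testing.assert_allclose(traj.final(), 1 / (0.7 * 0.7 * 0.3), rtol=1e-12)
    np.testing.assert_allclose(traj.w[:, 3], traj.w[:, 2])


def test_strategy_breakers_get_zero_weight():
    c = _constant_cohort(follow_k=3)  # everyone initiates at 3
    models = TreatmentModelSet.from_constant(0.3, c.K)
    for k in (2, 4, 5):
        traj = ps.compute_weights(c, k, models)
        assert (traj.final() == 0).all()
        # weight is zero exactly where adherence is broken
        assert ((traj.w == 0) == (traj.S == 0)).all()


def test_never_initiator_delivering_early_keeps_first_factor_only():
    n, K = 5, 3
    W = np.zeros((n, K))
    A = np.zeros((n, K))
    D = np.zeros((n, K), dtype=int)
    D[:, 0] = 1
    D[:, 1:] = 1
    A[:, 1:] = np.nan
    W[:, 1:] = np.nan
    c = ps.from_arrays(W, A, D, np.zeros(n))
    models = TreatmentModelSet.from_constant(0.25, K)
    traj = ps.compute_weights(c, 3, models)
    # only the t=1 remain-untreated factor is random: w = 1/0.75 at every t
    np.testing.assert_allclose(traj.w, 1 / 0.75)


def test_positivity_error_when_a_follower_has_zero_probability():
    c = _constant_cohort(follow_k=3)
    S = ps.strategy_indicators(c, 3)
    probs = np.ones((c.n, c.K))
    probs[:, 2] = 0.0
    with pytest.raises(ps.PositivityError):
        ps.cumulative_weights(probs, S, 3)


def test_equal_weights_reduce_to_sample_mean():
    c = _constant_cohort(follow_k=2)
    models = TreatmentModelSet.from_constant(0.5, c.K)
    est = ps.ipw_estimate(c, 2, models=models)
    np.testing.assert_allclose(est.estimate, c.Y.mean(), rtol=1e-12)
    assert est.diagnostics["n_followers"] == c.n


def test_saturated_weights_average_to_one_and_match_enumeration():
    c = make_two_period_cohort(n=800, seed=7)
    models = ps.fit_treatment_models(c, learner="saturated", prob_floor=0.0)
    for k in (2, 3):
        traj = ps.compute_weights(c, k, models)
        # MLE cell frequencies make the weighted follower count exactly n
        np.testing.assert_allclose(traj.final().mean(), 1.0, atol=1e-10)
        est = ps.ipw_estimate(c, k, models=models)
        oracle = enumeration_gformula_two_period(c, k)
        np.testing.assert_allclose(est.estimate, oracle, atol=1e-10)


def test_rct_like_cohort_recovers_strategy_arm_mean():
    # known constant initiation probabilities supplied as oracle models:
    # IPW must match the counterfactual strategy mean within MC error
    spec = ps.ScenarioSpec(scenario=2, n=100_000, seed=42)
    flat = ps.SimCoefficients(a_on_w=0.0)   # randomised initiation
    spec = ps.ScenarioSpec(scenario=2, n=100_000, seed=42, coefficients=flat)
    c = ps.simulate_cohort(spec)
    from scipy.special import expit
    p_init = float(expit(flat.a_intercept))
    models = TreatmentModelSet.from_constant(p_init, c.K)
    truth = ps.counterfactual_truth(spec, (3,), n_truth=400_000, seed=5)
    est = ps.ipw_estimate(c, 3, models=models)
    se = 3.0 / np.sqrt(est.diagnostics["ess"])
    assert abs(est.estimate - truth.means[3]) < se + 3 * truth.mean_ses[3]


def test_weight_truncation_at_top_percentile_changes_nothing(two_period_cohort):
    c = two_period_cohort
    models = ps.fit_treatment_models(c, learner="saturated", prob_floor=0.0)
    a = ps.ipw_estimate(c, 2, models=models)
    b = ps.ipw_estimate(c, 2, models=models, truncate_percentile=100.0)
    assert a.estimate == b.estimate


def test_msm_saturated_in_strategy_matches_per_strategy_means(two_period_cohort):
    c = two_period_cohort
    models = ps.fit_treatment_models(c, learner="saturated", prob_floor=0.0)
    msm = ps.ipw_msm(c, models, ks=(2, 3))
    for k in (2, 3):
        direct = ps.ipw_estimate(c, k, models=models)
        np.testing.assert_allclose(msm[k].estimate, direct.estimate, atol=1e-10)


def test_no_followers_raises_estimation_error():
    c = _constant_cohort(follow_k=3)
    models = TreatmentModelSet.from_constant(0.3, c.K)
    with pytest.raises(ps.EstimationError, match="follows strategy"):
        ps.ipw_estimate(c, 2, models=models)
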