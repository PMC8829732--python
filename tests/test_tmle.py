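"""Targeting steps, score equations, and the full longitudinal TMLE."""

import numpy as np
import pytest

import pregstrat as ps
from pregstrat.tmle import AffineScaler, tmle_targeting_step
from conftest import enumeration_gformula_two_period


def test_targeting_with_constant_offset_recovers_weighted_mean():
    # initial prediction 0.5 everywhere, equal weights on followers:
    # the intercept-only logistic with constant offset solves to the
    # follower mean of the pseudo-outcome
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 200).astype(float)
    w = np.ones(200)
    updated, eps, info = tmle_targeting_step(np.full(200, 0.5), y, w)
    np.testing.assert_allclose(updated, y.mean(), atol=1e-9)
    assert abs(info["score_after"]) < 1e-8


def test_epsilon_is_zero_when_the_score_is_already_solved():
    # predictions equal to the weighted mean structure: nothing to update
    y = np.array([0.0, 1.0, 1.0, 0.0])
    p = np.full(4, 0.5)
    updated, eps, _ = tmle_targeting_step(p, y, np.ones(4))
    assert eps == 0.0
    np.testing.assert_array_equal(updated, p)


def test_all_zero_weights_raise():
    with pytest.raises(ps.EstimationError, match="zero"):
        tmle_targeting_step(np.full(3, 0.4), np.ones(3), np.zeros(3))


def test_separation_is_not_fatal():
    # all pseudo-outcomes are 1: the analytic score has no finite root;
    # the solver pushes the intercept to (or near) the search boundary and
    # the updated predictions saturate at one
    updated, eps, info = tmle_targeting_step(
        np.full(5, 0.5), np.ones(5), np.ones(5)
    )
    assert eps > 10
    assert (updated > 0.999999).all()
    assert abs(info["score_after"]) < 1e-6


def test_two_period_walkthrough_structure(two_period_cohort):
    """The K=2 step sequence: regress Y among D(1)=0 at the strategy
    exposures, fluctuate with w^k(2), reintegrate Y for the delivered,
    regress on W(1) at A(1)=0, fluctuate with w^k(1), average."""
    c = two_period_cohort
    models = ps.fit_treatment_models(c, learner="logistic")
    res = ps.tmle_estimate(c, 2, models=models, outcome_learner="logistic")
    recs = res.diagnostics["fluctuations"]
    assert [r.t for r in recs] == [2, 1]
    n_undelivered = int((c.D[:, 0] == 0).sum())
    assert recs[0].n_subset == n_undelivered   # update subset = D(1)=0
    assert recs[1].n_subset == c.n             # everyone at the first step
    assert 0.0 <= res.estimate <= 1.0
    # weighted scores solved at both steps
    for r in recs:
        assert abs(r.score_after) < 1e-6


@pytest.mark.parametrize("k", [1, 2, 3])
def test_saturated_tmle_equals_enumeration_with_zero_fluctuations(
    two_period_cohort, k
):
    c = two_period_cohort
    models = ps.fit_treatment_models(c, learner="saturated", prob_floor=0.0)
    res = ps.tmle_estimate(c, k, models=models, outcome_learner="saturated")
    oracle = enumeration_gformula_two_period(c, k)
    np.testing.assert_allclose(res.estimate, oracle, atol=1e-8)
    assert all(abs(e) < 1e-8 for e in res.diagnostics["epsilons"])


def test_score_equations_hold_on_a_four_period_cohort(scenario2_cohort):
    for k in (2, 4, 5):
        for learners in (("logistic", "logistic"), ("saturated", "saturated")):
            res = ps.tmle_estimate(
                scenario2_cohort, k,
                treatment_learner=learners[0], outcome_learner=learners[1],
            )
            assert res.diagnostics["max_abs_score"] < 1e-6, (k, learners)


def test_tmle_equals_gcomp_under_constant_weights(two_period_cohort):
    # oracle constant treatment probabilities: every update subset sees a
    # flat weight, so the targeting steps keep the saturated g-computation
    from pregstrat.nuisance import TreatmentModelSet
    c = two_period_cohort
    models = TreatmentModelSet.from_constant(0.5, c.K)
    t_res = ps.tmle_estimate(c, 3, models=models, outcome_learner="saturated")
    g_res = ps.gcomp_estimate(c, 3, learner="saturated")
    np.testing.assert_allclose(t_res.estimate, g_res.estimate, atol=1e-8)


def test_continuous_outcome_scaling_round_trip_and_range(two_period_cohort):
    c = two_period_cohort
    grams = ps.LongitudinalCohort(
        subject_ids=c.subject_ids, K=c.K, W=c.W, A=c.A, D=c.D, T_D=c.T_D,
        Y=2500.0 + 1500.0 * c.Y + 10.0 * np.arange(c.n) % 7,
        covariate_names=c.covariate_names,
    )
    res = ps.tmle_estimate(grams, 2, treatment_learner="logistic")
    assert res.diagnostics["scaled"]
    assert grams.Y.min() <= res.estimate <= grams.Y.max()


def test_bound_continuous_outcome_contract():
    y = np.array([2500.0, 4000.0])
    scaled, sc = ps.bound_continuous_outcome(y, delta=0.0)
    np.testing.assert_allclose(scaled, [0.0, 1.0])
    scaled2, sc2 = ps.bound_continuous_outcome(y, delta=0.005)
    np.testing.assert_allclose(scaled2, [0.005, 0.995])
    rng = np.random.default_rng(1)
    z = rng.normal(3000, 400, 50)
    s, scaler = ps.bound_continuous_outcome(z, delta=0.01)
    np.testing.assert_allclose(scaler.inverse(s), z, rtol=1e-12)
    with pytest.raises(ps.EstimationError, match="zero range"):
        ps.bound_continuous_outcome(np.full(5, 3.0))


def test_affine_scaler_scalar_inverse():
    sc = AffineScaler(0.0, 10.0, 0.0)
    assert sc.inverse(0.5) == 5.0
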