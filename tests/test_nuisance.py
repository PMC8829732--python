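"""Treatment-probability and outcome-step models on the correct subsets."""

import numpy as np
import pytest

import pregstrat as ps
from pregstrat.nuisance import SaturatedModel, fit_outcome_step


def _crosstab_initiation(cohort, t):
    """Empirical initiation proportion per covariate-history cell at time t."""
    obs_a = cohort.exposure_filled()
    at_risk = cohort.d_prev(t) == 0
    if t > 1:
        at_risk &= ~(np.cumsum(obs_a, axis=1)[:, t - 2] > 0)
    X, _ = cohort.w_history(t)
    out = {}
    for cell in {tuple(row) for row in X[at_risk]}:
        mask = at_risk & (X == np.array(cell)).all(axis=1)
        out[cell] = obs_a[mask, t - 1].mean()
    return out, at_risk


def test_saturated_treatment_models_match_crosstab_proportions(two_period_cohort):
    c = two_period_cohort
    models = ps.fit_treatment_models(c, learner="saturated", prob_floor=0.0)
    for t in (1, 2):
        expected, at_risk = _crosstab_initiation(c, t)
        p = models.predict_initiation(c, t)
        X, _ = c.w_history(t)
        for cell, prop in expected.items():
            mask = at_risk & (X == np.array(cell)).all(axis=1)
            np.testing.assert_allclose(p[mask], prop, atol=1e-12)


def test_treatment_models_only_see_at_risk_untreated_person_time(two_period_cohort):
    c = two_period_cohort
    models = ps.fit_treatment_models(c, learner="saturated", prob_floor=0.0)
    # at t=2 the fit excludes delivered subjects and prior initiators, so
    # the recorded at-risk n must match the mask size exactly
    obs_a = c.exposure_filled()
    expected_n = int(((c.D[:, 0] == 0) & (obs_a[:, 0] == 0)).sum())
    assert models.at_risk_n[1] == expected_n
    assert models.at_risk_n[0] == c.n


def test_degenerate_initiation_cell_raises_positivity_error():
    n = 30
    W = np.zeros((n, 2))
    A = np.zeros((n, 2))
    A[:10, 0] = 1
    A[:10, 1] = 1          # sustained; nobody initiates at t=2
    D = np.column_stack([np.zeros(n), np.ones(n)]).astype(int)
    c = ps.from_arrays(W, A, D, np.ones(n))
    with pytest.raises(ps.PositivityError, match="time 2"):
        ps.fit_treatment_models(c, learner="saturated")


def test_predictions_are_strictly_inside_unit_interval_after_flooring(
    two_period_cohort,
):
    models = ps.fit_treatment_models(
        two_period_cohort, learner="saturated", prob_floor=0.01
    )
    for t in (1, 2):
        p = models.predict_initiation(two_period_cohort, t)
        p = p[np.isfinite(p)]
        assert (p >= 0.01).all() and (p <= 0.99).all()


@pytest.mark.parametrize("mode", ["intervene", "strict"])
def test_saturated_outcome_step_equals_subset_cell_means(two_period_cohort, mode):
    c = two_period_cohort
    k, t = 2, 2
    preds, info = fit_outcome_step(c.Y, c, t=t, k=k, learner="saturated", mode=mode)
    riskset = c.d_prev(t) == 0
    S = ps.strategy_indicators(c, k)
    consistent = riskset & (S[:, t - 1] == 1)
    X, _ = c.w_history(t)
    for cell in {tuple(row) for row in X[riskset]}:
        in_cell = (X == np.array(cell)).all(axis=1)
        fit_cell = consistent & in_cell
        if fit_cell.sum() == 0:
            continue
        np.testing.assert_allclose(
            preds[riskset & in_cell], c.Y[fit_cell].mean(), atol=1e-12
        )
    assert np.isnan(preds[~riskset]).all()
    assert info["n_fit"] > 0


def test_constant_pseudo_outcome_predicts_the_constant(two_period_cohort):
    c = two_period_cohort
    const = np.full(c.n, 0.37)
    for learner in ("saturated", "logistic", "intercept"):
        preds, _ = fit_outcome_step(const, c, t=1, k=2, learner=learner)
        np.testing.assert_allclose(preds[np.isfinite(preds)], 0.37, atol=1e-8)


def test_outcome_step_with_everyone_delivered_raises():
    n = 20
    W = np.column_stack([np.zeros(n), np.full(n, np.nan)])
    A = np.column_stack([np.zeros(n), np.full(n, np.nan)])
    D = np.ones((n, 2), dtype=int)  # all delivered at t=1
    c = ps.from_arrays(W, A, D, np.ones(n))
    with pytest.raises(ps.EstimationError, match=r"t=2"):
        fit_outcome_step(c.Y, c, t=2, k=3, learner="saturated")


def test_saturated_model_falls_back_hierarchically_for_unseen_cells():
    X = np.array([[0, 0], [0, 1], [1, 0]])
    y = np.array([0.0, 1.0, 0.5])
    m = SaturatedModel().fit(X, y)
    # seen cell -> exact mean; unseen (1,1) -> collapse to second column
    np.testing.assert_allclose(m.predict(np.array([[0, 1]])), [1.0])
    np.testing.assert_allclose(m.predict(np.array([[1, 1]])), [1.0])
    # unseen level in the last column -> overall mean
    np.testing.assert_allclose(m.predict(np.array([[0, 7]])), [0.5])
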