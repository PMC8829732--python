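"""Biased/naive analyses used as foils, and the analytic toy-trial calculator.

Three comparators:

* :func:`toy_trial_expectations` — closed-form expected proportions for the
  two-arm toy trial (initiate-late vs never) in which early deliveries can
  never receive treatment, showing how a naive per-protocol grouping
  manufactures a spurious benefit while the ITT comparison stays null.
* :func:`standard_ipw_estimate` — the "standard" IPW implementation that
  censors all early deliveries (keeps only subjects undelivered until the
  final interval) and weights by the inverse probability of the *observed*
  exposure path. Conditioning on full-term delivery blocks the component
  of the effect mediated by delivery time and opens a collider path through
  unmeasured common causes of delivery and outcome, so this estimator is
  biased whenever delivery time matters.
* :func:`naive_regression_estimate` — a single linear regression of Y on
  all exposures and covariates with post-delivery values zero-filled,
  ignoring delivery time entirely.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import statsmodels.api as sm

from .cohort import LongitudinalCohort
from .errors import EstimationError
from .inference import EstimateResult
from .nuisance import DEFAULT_PROB_FLOOR, TreatmentModelSet, fit_treatment_models

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# analytic toy trial
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ToyTrialSpec:
    """Two-arm trial: initiate at the late time point vs never initiate.

    A fraction ``p_early`` of pregnancies delivers before the initiation
    time and therefore can never be exposed. Treatment has no effect by
    construction; outcome risk depends only on delivery timing.
    """

    p_early: float = 0.10
    risk_early: float = 0.50
    risk_full: float = 0.05
    allocation: float = 0.5

    def __post_init__(self):
        for name in ("p_early", "risk_early", "risk_full", "allocation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class ToyTrialTable:
    """Expected composition and outcome probabilities of both analyses."""

    pp_early_exposed: float
    pp_early_unexposed: float
    pp_outcome_exposed: float
    pp_outcome_unexposed: float
    itt_early_per_arm: float
    itt_outcome_treated: float
    itt_outcome_control: float
    exposed_group_empty: bool


def toy_trial_expectations(spec: ToyTrialSpec) -> ToyTrialTable:
    """Exact closed-form expectations for the per-protocol and ITT analyses.

    Per-protocol: the "exposed" group contains only treated-arm full-term
    deliveries; the "unexposed" group pools *all* early deliveries (they
    could not be treated regardless of assignment) with control-arm
    full-terms — a delivery-time-selected mixture.  ITT pools by assignment.
    """
    a, pe = spec.allocation, spec.p_early
    re_, rf = spec.risk_early, spec.risk_full
    exposed_mass = a * (1 - pe)
    unexposed_mass = pe + (1 - a) * (1 - pe)
    empty = exposed_mass == 0
    if empty:
        logger.warning("per-protocol exposed group is empty (p_early=1 or allocation=0)")
    pp_early_unexp = pe / unexposed_mass if unexposed_mass > 0 else np.nan
    pp_out_unexp = (
        (pe * re_ + (1 - a) * (1 - pe) * rf) / unexposed_mass
        if unexposed_mass > 0 else np.nan
    )
    itt = pe * re_ + (1 - pe) * rf
    return ToyTrialTable(
        pp_early_exposed=0.0 if not empty else np.nan,
        pp_early_unexposed=pp_early_unexp,
        pp_outcome_exposed=rf if not empty else np.nan,
        pp_outcome_unexposed=pp_out_unexp,
        itt_early_per_arm=pe,
        itt_outcome_treated=itt,
        itt_outcome_control=itt,
        exposed_group_empty=empty,
    )


# --------------------------------------------------------------------------
# standard (full-term-censoring) IPW
# --------------------------------------------------------------------------

def observed_path_probability(
    cohort: LongitudinalCohort, models: TreatmentModelSet
) -> np.ndarray:
    """Cumulative probability of each subject's observed exposure path.

    Valid for monotone (sustained) exposure: factors are (1 - p_t) while
    untreated, p_t at initiation, and 1 afterwards. Only defined (used)
    for subjects undelivered until the final interval.
    """
    n, K = cohort.n, cohort.K
    first = cohort.first_initiation()
    prob = np.ones(n)
    for t in range(1, K + 1):
        p = models.predict_initiation(cohort, t)
        pre = first >= t          # untreated entering t (or initiating now)
        at = first == t
        factor = np.where(at, p, np.where(pre, 1.0 - p, 1.0))
        factor = np.where(np.isnan(factor), 1.0, factor)
        prob *= factor
    # sanity: exposure must be monotone for the path factorisation to hold
    if (np.diff(np.nan_to_num(cohort.A, nan=1.0), axis=1) < 0).any():
        raise EstimationError(
            "observed exposure is not monotone; the standard-IPW path "
            "probability assumes sustained exposure"
        )
    return prob


def standard_ipw_estimate(
    cohort: LongitudinalCohort,
    models: TreatmentModelSet | None = None,
    learner: str | object = "logistic",
    prob_floor: float = DEFAULT_PROB_FLOOR,
) -> dict:
    """Full-term-censoring IPW comparator.

    Restricts to subjects undelivered until the final interval
    (``D(K-1)=0``), weights each by the inverse cumulative probability of
    their observed exposure path, and estimates per-initiation-time group
    means of Y plus adjacent contrasts. Early-delivered subjects receive
    zero weight by construction.
    """
    if models is None:
        models = fit_treatment_models(cohort, learner, prob_floor)
    K = cohort.K
    fullterm = cohort.d_prev(K) == 0
    if not fullterm.any():
        raise EstimationError("no full-term deliveries to analyse")
    prob = observed_path_probability(cohort, models)
    w = np.where(fullterm, 1.0 / prob, 0.0)
    first = cohort.first_initiation()
    group = np.where(np.isinf(first), K + 1, first).astype(int)

    means: dict[int, EstimateResult] = {}
    for g in range(1, K + 2):
        mask = fullterm & (group == g)
        wsum = w[mask].sum()
        if wsum > 0:
            means[g] = EstimateResult(
                method="standard-ipw", k=g,
                estimate=float(np.sum(w[mask] * cohort.Y[mask]) / wsum),
                diagnostics={"n": int(mask.sum()), "sum_weights": float(wsum)},
            )
    contrasts: dict[tuple[int, int], EstimateResult] = {}
    for g in range(1, K + 1):
        if g in means and g + 1 in means:
            contrasts[(g, g + 1)] = EstimateResult(
                method="standard-ipw", k=(g, g + 1),
                estimate=means[g].estimate - means[g + 1].estimate,
            )
    return {"means": means, "contrasts": contrasts, "weights": w}


# --------------------------------------------------------------------------
# naive regression
# --------------------------------------------------------------------------

def naive_regression_estimate(cohort: LongitudinalCohort) -> dict:
    """Single linear model of Y on all A(t) and W(t), zero-filled after
    delivery; returns the exposure coefficients.

    Delivered subjects contribute zeros (not missing values) for their
    post-delivery exposures and covariates, mimicking the conventional
    analysis that ignores delivery timing. Collinear columns are dropped
    and logged.
    """
    n, K, p = cohort.n, cohort.K, cohort.n_covariates
    A0 = cohort.exposure_filled()
    W0 = np.nan_to_num(cohort.W, nan=0.0).reshape(n, K * p)
    names = [f"A_{t}" for t in range(1, K + 1)] + [
        f"W_{name}__t{t}"
        for t in range(1, K + 1)
        for name in cohort.covariate_names
    ]
    X = np.column_stack([A0, W0])

    keep = np.ptp(X, axis=0) > 0
    dropped = [nm for nm, kp in zip(names, keep) if not kp]
    X = X[:, keep]
    kept_names = [nm for nm, kp in zip(names, keep) if kp]
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        logger.warning(
            "naive regression design is rank deficient (%d < %d); "
            "coefficients computed by pseudoinverse", rank, Xc.shape[1]
        )
    fit = sm.OLS(cohort.Y, Xc).fit()
    coef = dict(zip(["const"] + kept_names, np.asarray(fit.params)))
    if dropped:
        logger.warning("dropped constant columns: %s", dropped)
    exposure_coefs = {
        t: coef.get(f"A_{t}", np.nan) for t in range(1, K + 1)
    }
    return {
        "exposure_coefs": exposure_coefs,
        "all_coefs": coef,
        "dropped": dropped,
        "model": fit,
    }
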