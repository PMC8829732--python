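"""Longitudinal targeted maximum likelihood estimation of E(Y^k).

The procedure follows the G-computation backward recursion but, after each
conditional-mean fit, runs a *targeting* (fluctuation) step: an
intercept-only logistic regression of the pseudo-outcome with the logit of
the current predictions as offset and the cumulative strategy weights
``w^k(t)`` as observation weights, restricted to subjects still undelivered
at ``t-1``. Only these random components are fluctuated; subjects already
delivered keep their known outcome. Solving the intercept makes the
weighted residual score zero at every step, which is what delivers double
robustness: the estimator is consistent if either the treatment-probability
models or the outcome regressions are consistent.

Continuous outcomes are affinely mapped into [0, 1] so the logistic
fluctuation applies unchanged, and the final estimate is mapped back.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import LongitudinalCohort
from .errors import ConvergenceError, EstimationError
from .inference import EstimateResult
from .ipw import compute_weights
from .nuisance import (
    DEFAULT_PROB_FLOOR,
    TreatmentModelSet,
    fit_outcome_step,
    fit_treatment_models,
)

_PRED_EPS = 1e-12          # clip before logit; keeps offsets finite
_SCORE_TOL = 1e-10         # weighted-mean-residual tolerance at the solution
_EPS_BOUND = 40.0          # search bound for the fluctuation intercept


@dataclasses.dataclass
class FluctuationRecord:
    """Bookkeeping for one targeting step of the backward recursion."""

    t: int
    epsilon: float
    score_before: float       # weighted mean residual at epsilon = 0
    score_after: float        # weighted mean residual at the solution
    n_subset: int
    sum_weights: float
    note: str = ""


@dataclasses.dataclass
class AffineScaler:
    """Invertible affine map of a bounded outcome onto [delta, 1-delta]."""

    lo: float
    hi: float
    delta: float = 0.0

    def scale(self, y: np.ndarray) -> np.ndarray:
        u = (np.asarray(y, float) - self.lo) / (self.hi - self.lo)
        return self.delta + (1 - 2 * self.delta) * u

    def inverse(self, v: np.ndarray | float):
        u = (np.asarray(v, float) - self.delta) / (1 - 2 * self.delta)
        out = self.lo + u * (self.hi - self.lo)
        return float(out) if np.ndim(v) == 0 else out


def bound_continuous_outcome(
    y: np.ndarray, delta: float = 0.0
) -> tuple[np.ndarray, AffineScaler]:
    """Map a continuous outcome into [delta, 1-delta]; returns the scaler."""
    y = np.asarray(y, dtype=float)
    lo, hi = float(np.min(y)), float(np.max(y))
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise EstimationError("outcome has zero range; cannot scale to [0, 1]")
    if not 0 <= delta < 0.5:
        raise ValueError("delta must be in [0, 0.5)")
    scaler = AffineScaler(lo, hi, delta)
    return scaler.scale(y), scaler


def tmle_targeting_step(
    predictions: np.ndarray,
    pseudo_outcome: np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, float, dict]:
    """Solve the intercept-only logistic fluctuation with offset.

    All arrays are restricted to the update subset (undelivered subjects).
    Returns (updated predictions, epsilon, info). The solution makes the
    weighted residual mean ``sum(w * (q - p)) / sum(w)`` zero.
    """
    p = np.clip(np.asarray(predictions, float), _PRED_EPS, 1 - _PRED_EPS)
    q = np.asarray(pseudo_outcome, float)
    w = np.asarray(weights, float)
    if p.shape != q.shape or p.shape != w.shape:
        raise ValueError("mismatched shapes in targeting step")
    wsum = w.sum()
    if wsum <= 0:
        raise EstimationError(
            "all fluctuation weights are zero (no followers in update subset)"
        )
    offset = logit(p)

    def mean_score(eps: float) -> float:
        return float(np.sum(w * (q - expit(offset + eps))) / wsum)

    s0 = mean_score(0.0)
    note = ""
    if abs(s0) <= _SCORE_TOL:
        eps = 0.0
        updated = p
    else:
        # the score is strictly decreasing in eps, so bracket and bisect
        lo, hi = -1.0, 1.0
        while mean_score(lo) < 0 and lo > -_EPS_BOUND:
            lo *= 2
        while mean_score(hi) > 0 and hi < _EPS_BOUND:
            hi *= 2
        lo, hi = max(lo, -_EPS_BOUND), min(hi, _EPS_BOUND)
        if mean_score(lo) < 0 or mean_score(hi) > 0:
            # separation: score has no root; take the boundary (best fit)
            eps = lo if abs(mean_score(lo)) < abs(mean_score(hi)) else hi
            note = "separation: epsilon at search boundary"
        else:
            eps = brentq(mean_score, lo, hi, xtol=1e-13)
        updated = expit(offset + eps)
        if not note and abs(mean_score(eps)) > 1e-6:
            raise ConvergenceError(
                f"fluctuation fit did not solve the score: "
                f"residual mean {mean_score(eps):.3e}"
            )
    info = {
        "score_before": s0,
        "score_after": mean_score(eps),
        "sum_weights": float(wsum),
        "note": note,
    }
    return updated, float(eps), info


def tmle_estimate(
    cohort: LongitudinalCohort,
    k: int,
    models: TreatmentModelSet | None = None,
    treatment_learner: str | object = "logistic",
    outcome_learner: str | object = "auto",
    prob_floor: float = DEFAULT_PROB_FLOOR,
    mode: str = "intervene",
    scale_delta: float = 0.005,
) -> EstimateResult:
    """TMLE of E(Y^k): backward recursion with one targeting step per time.

    For binary (or already [0,1]-bounded) Y the recursion runs on the
    natural scale; otherwise Y is affinely scaled into
    [scale_delta, 1 - scale_delta] first and the estimate is mapped back.
    """
    if not 1 <= k <= cohort.K + 1:
        raise EstimationError(f"strategy k={k} outside 1..{cohort.K + 1}")
    if models is None:
        models = fit_treatment_models(cohort, treatment_learner, prob_floor)
    traj = compute_weights(cohort, k, models)

    y = cohort.Y.astype(float)
    bounded = y.min() >= 0 and y.max() <= 1
    scaler = None
    if not bounded:
        ys, scaler = bound_continuous_outcome(y, scale_delta)
    else:
        ys = y

    if outcome_learner == "auto":
        outcome_learner = "logistic"

    records: list[FluctuationRecord] = []
    Q = ys.copy()
    for t in range(cohort.K, 0, -1):
        riskset = cohort.d_prev(t) == 0
        preds, _ = fit_outcome_step(Q, cohort, t, k, outcome_learner, mode)
        preds = np.clip(preds[riskset], 0.0, 1.0)
        updated, eps, info = tmle_targeting_step(
            preds, Q[riskset], traj.w[riskset, t - 1]
        )
        records.append(
            FluctuationRecord(
                t=t, epsilon=eps,
                score_before=info["score_before"],
                score_after=info["score_after"],
                n_subset=int(riskset.sum()),
                sum_weights=info["sum_weights"],
                note=info["note"],
            )
        )
        Qt = ys.copy()          # delivered subjects keep their known outcome
        Qt[riskset] = updated
        Q = Qt
    est = float(Q.mean())
    if scaler is not None:
        est = scaler.inverse(est)
    diag = {
        "fluctuations": records,
        "max_abs_score": max(abs(r.score_after) for r in records),
        "epsilons": [r.epsilon for r in records],
        "at_risk_n": list(models.at_risk_n),
        "n_followers": int((traj.final() > 0).sum()),
        "scaled": scaler is not None,
    }
    return EstimateResult(method="tmle", k=k, estimate=est, diagnostics=diag)
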