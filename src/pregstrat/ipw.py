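"""Treatment-strategy inverse probability weighting.

The probability of following strategy ``k`` at time ``t`` is

    P(S^k(t)=1 | W̄(t), S^k(t-1)=1, D̄(t-1)) =
        P(A(t)=I(k=t) | W̄(t), Ā(t-1)=0, D(t-1)=0)   if t <= k and D(t-1)=0
        1                                             otherwise

so only initiation probabilities up to time ``k`` for undelivered subjects
are random; delivery makes continued adherence automatic. The cumulative
weight ``w^k(t) = S^k(t) / prod_{l<=t} P(S^k(l)=1 | ...)`` upweights
followers and zeroes out everyone who broke the strategy. The IPW estimate
of E(Y^k) is the fitted intercept of the weighted intercept-only regression
of Y, i.e. the weighted mean of Y among followers through K.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm

from .cohort import LongitudinalCohort, strategy_indicators
from .errors import EstimationError, PositivityError
from .inference import EstimateResult
from .nuisance import DEFAULT_PROB_FLOOR, TreatmentModelSet, fit_treatment_models


@dataclasses.dataclass
class WeightTrajectory:
    """Cumulative strategy weights w^k(t), one row per subject."""

    k: int
    w: np.ndarray              # (n, K)
    probabilities: np.ndarray  # (n, K) per-time strategy probabilities
    S: np.ndarray              # (n, K) adherence indicators

    def final(self) -> np.ndarray:
        return self.w[:, -1]


def strategy_probability(
    models: TreatmentModelSet,
    cohort: LongitudinalCohort,
    k: int,
    t: int,
) -> np.ndarray:
    """Per-subject P(S^k(t)=1 | history) for one time point."""
    if not 1 <= t <= cohort.K:
        raise ValueError(f"time {t} outside 1..{cohort.K}")
    out = np.ones(cohort.n)
    if t > k:
        return out
    riskset = cohort.d_prev(t) == 0
    p_init = models.predict_initiation(cohort, t)
    if np.isnan(p_init[riskset]).any():
        raise EstimationError(
            f"initiation probability unavailable for undelivered subjects at t={t}"
        )
    out[riskset] = p_init[riskset] if t == k else 1.0 - p_init[riskset]
    return out


def strategy_probabilities(
    models: TreatmentModelSet, cohort: LongitudinalCohort, k: int
) -> np.ndarray:
    """(n, K) matrix of per-time strategy-adherence probabilities."""
    return np.column_stack(
        [strategy_probability(models, cohort, k, t) for t in range(1, cohort.K + 1)]
    )


def cumulative_weights(
    probabilities: np.ndarray,
    S: np.ndarray,
    k: int,
) -> WeightTrajectory:
    """w^k(t) = S^k(t) / prod_{l<=t} P(S^k(l)=1 | ...)."""
    probabilities = np.asarray(probabilities, dtype=float)
    S = np.asarray(S)
    cum = np.cumprod(probabilities, axis=1)
    follower_zero = (S == 1) & (cum <= 0)
    if follower_zero.any():
        i, t = np.argwhere(follower_zero)[0]
        raise PositivityError(
            f"zero strategy probability for a follower (subject index {i}, "
            f"time {t + 1}, strategy {k})"
        )
    with np.errstate(divide="ignore"):
        w = np.where(S == 1, 1.0 / cum, 0.0)
    return WeightTrajectory(k=k, w=w, probabilities=probabilities, S=S)


def compute_weights(
    cohort: LongitudinalCohort,
    k: int,
    models: TreatmentModelSet,
) -> WeightTrajectory:
    """Convenience: adherence indicators + probabilities + cumulative weights."""
    S = strategy_indicators(cohort, k)
    probs = strategy_probabilities(models, cohort, k)
    return cumulative_weights(probs, S, k)


def _truncate(w: np.ndarray, percentile: float | None) -> np.ndarray:
    if percentile is None:
        return w
    pos = w[w > 0]
    if pos.size == 0:
        return w
    cap = np.percentile(pos, percentile)
    return np.minimum(w, cap)


def _weight_diagnostics(wK: np.ndarray, n: int) -> dict:
    pos = wK[wK > 0]
    ess = float(pos.sum() ** 2 / (pos ** 2).sum()) if pos.size else 0.0
    return {
        "n_followers": int(pos.size),
        "max_weight": float(pos.max()) if pos.size else np.nan,
        "mean_weight": float(wK.sum() / n),
        "ess": ess,
    }


def ipw_estimate(
    cohort: LongitudinalCohort,
    k: int,
    models: TreatmentModelSet | None = None,
    weights: WeightTrajectory | None = None,
    learner: str | object = "logistic",
    prob_floor: float = DEFAULT_PROB_FLOOR,
    truncate_percentile: float | None = None,
) -> EstimateResult:
    """IPW estimate of E(Y^k): weighted mean of Y over followers through K."""
    if weights is None:
        if models is None:
            models = fit_treatment_models(cohort, learner, prob_floor)
        weights = compute_weights(cohort, k, models)
    wK = _truncate(weights.final(), truncate_percentile)
    total = wK.sum()
    if total <= 0:
        raise EstimationError(
            f"no subject follows strategy {k} through K={cohort.K}"
        )
    est = float(np.sum(wK * cohort.Y) / total)
    diag = _weight_diagnostics(wK, cohort.n)
    if models is not None:
        diag["at_risk_n"] = list(models.at_risk_n)
    if truncate_percentile is not None:
        diag["truncate_percentile"] = truncate_percentile
    return EstimateResult(method="ipw", k=k, estimate=est, diagnostics=diag)


def ipw_msm(
    cohort: LongitudinalCohort,
    models: TreatmentModelSet,
    ks: tuple[int, ...] | None = None,
) -> dict[int, EstimateResult]:
    """Joint weighted regression of Y on strategy indicators.

    A subject's history can be compatible with several strategies at once,
    so the stacked dataset holds one record per (subject, compatible
    strategy) carrying that strategy's weight — this realises the
    summed-weight marginal structural model while keeping per-strategy
    bookkeeping explicit. Saturated in strategy, the fitted per-strategy
    means coincide with the strategy-wise IPW estimates.
    """
    if ks is None:
        ks = tuple(range(1, cohort.K + 2))
    rows_y, rows_w, rows_k = [], [], []
    for k in ks:
        traj = compute_weights(cohort, k, models)
        wK = traj.final()
        mask = wK > 0
        rows_y.append(cohort.Y[mask])
        rows_w.append(wK[mask])
        rows_k.append(np.full(mask.sum(), k))
    y = np.concatenate(rows_y)
    w = np.concatenate(rows_w)
    kcol = np.concatenate(rows_k)
    if y.size == 0:
        raise EstimationError("no subject follows any requested strategy")
    X = np.column_stack([(kcol == k).astype(float) for k in ks])
    present = X.sum(axis=0) > 0
    if not present.all():
        missing = [k for k, ok in zip(ks, present) if not ok]
        raise EstimationError(f"no followers for strategies {missing}")
    fit = sm.WLS(y, X, weights=w).fit()
    return {
        k: EstimateResult(
            method="ipw-msm", k=k, estimate=float(fit.params[j]),
            diagnostics={"n_records": int(X[:, j].sum())},
        )
        for j, k in enumerate(ks)
    }
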