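"""Iterated-conditional-expectation G-computation with delivery pass-through.

The backward recursion initialises ``Q̄_{K+1} = Y`` and, for t = K..1,

    Q̄_t^k = D(t-1) * Y + (1 - D(t-1)) * E[Q̄_{t+1}^k | D(t-1)=0, W̄(t),
                                            exposure fixed by strategy k]

so the outcome of a subject already delivered by ``t-1`` is known and
passed through unchanged, while undelivered subjects receive a model
prediction with the exposure history set to the strategy values
(``Ā(k-1)=0`` and ``A(k)=1`` once ``t >= k``; the never-initiate strategy
sets every exposure to zero). The estimate of E(Y^k) is the sample mean of
``Q̄_1^k``.
"""

from __future__ import annotations

import numpy as np

from .cohort import LongitudinalCohort
from .errors import EstimationError
from .inference import EstimateResult
from .nuisance import fit_outcome_step, resolve_outcome_learner


def gcomp_backward_step(
    current: np.ndarray,
    cohort: LongitudinalCohort,
    t: int,
    k: int,
    learner: str | object = "auto",
    mode: str = "intervene",
) -> np.ndarray:
    """One backward step: regress Q̄_{t+1} and reintegrate known outcomes."""
    learner = resolve_outcome_learner(learner, current)
    preds, _ = fit_outcome_step(current, cohort, t, k, learner, mode)
    if learner in ("logistic", "saturated", "intercept"):
        preds = np.clip(preds, 0.0, 1.0)
    delivered = cohort.d_prev(t) == 1
    return np.where(delivered, cohort.Y, preds)


def gcomp_estimate(
    cohort: LongitudinalCohort,
    k: int,
    learner: str | object = "auto",
    mode: str = "intervene",
    return_trajectory: bool = False,
) -> EstimateResult:
    """G-computation estimate of E(Y^k) via the full backward recursion."""
    if not 1 <= k <= cohort.K + 1:
        raise EstimationError(f"strategy k={k} outside 1..{cohort.K + 1}")
    Q = cohort.Y.astype(float).copy()
    trajectory = {cohort.K + 1: Q.copy()}
    for t in range(cohort.K, 0, -1):
        Q = gcomp_backward_step(Q, cohort, t, k, learner, mode)
        if np.isnan(Q).any():
            raise EstimationError(f"undefined iterated outcome at t={t}, k={k}")
        trajectory[t] = Q.copy()
    est = float(Q.mean())
    diag = {"learner": learner if isinstance(learner, str) else type(learner).__name__,
            "mode": mode}
    if return_trajectory:
        diag["trajectory"] = trajectory
    return EstimateResult(method="gcomp", k=k, estimate=est, diagnostics=diag)
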