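"""Nuisance models: per-time exposure-initiation probabilities and the
conditional-mean outcome regressions consumed by IPW, G-computation and TMLE.

Treatment models estimate, for each time ``t``,
``P(A(t)=1 | W̄(t), Ā(t-1)=0, D(t-1)=0)`` on the at-risk subset of subjects
who are undelivered and have not yet initiated. Outcome steps estimate the
nested expectations of the backward recursion among undelivered subjects,
with the exposure history fixed to the target strategy's values at
prediction time.

Learners: ``"saturated"`` (exact cell frequencies over a discrete history,
with hierarchical cell collapse for unseen cells), ``"logistic"``
(main-terms logistic regression), ``"linear"`` (OLS, for unbounded
pseudo-outcomes), ``"intercept"`` (intercept-only, used to study
misspecification), or any object with ``fit(X, y)`` / ``predict(X)``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .cohort import LongitudinalCohort, strategy_indicators
from .errors import EstimationError, PositivityError

DEFAULT_PROB_FLOOR = 1e-3


# --------------------------------------------------------------------------
# learners
# --------------------------------------------------------------------------

class SaturatedModel:
    """Exact conditional frequencies over discrete feature cells.

    Prediction for a cell never seen during fitting falls back to the mean
    of the coarser cell obtained by dropping the *earliest* feature columns
    one at a time (oldest history first), ending at the overall mean.
    """

    def __init__(self) -> None:
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None
        self._tables: dict[int, tuple] = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SaturatedModel":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y, dtype=float)
        self._tables = {}
        return self

    def _table(self, start: int):
        """Cell-mean lookup built from feature columns start..q-1."""
        if start in self._tables:
            return self._tables[start]
        X = self._X[:, start:]
        if X.shape[1] == 0:
            tab = (None, None, float(self._y.mean()), None)
        else:
            levels = [np.unique(col) for col in X.T]
            radices = np.array([len(lv) for lv in levels])
            mult = np.concatenate([np.cumprod(radices[::-1])[-2::-1], [1]])
            code = np.zeros(X.shape[0], dtype=np.int64)
            for j, lv in enumerate(levels):
                code += np.searchsorted(lv, X[:, j]) * mult[j]
            size = int(np.prod(radices))
            cnt = np.bincount(code, minlength=size)
            tot = np.bincount(code, weights=self._y, minlength=size)
            with np.errstate(invalid="ignore"):
                means = tot / cnt
            tab = (levels, mult, means, cnt)
        self._tables[start] = tab
        return tab

    def _predict_from(self, X: np.ndarray, start: int) -> np.ndarray:
        levels, mult, means, cnt = self._table(start)
        if levels is None:
            return np.full(X.shape[0], means)
        Xs = X[:, start:]
        code = np.zeros(Xs.shape[0], dtype=np.int64)
        seen = np.ones(Xs.shape[0], dtype=bool)
        for j, lv in enumerate(levels):
            idx = np.searchsorted(lv, Xs[:, j])
            idx_clip = np.clip(idx, 0, len(lv) - 1)
            seen &= lv[idx_clip] == Xs[:, j]
            code += idx_clip * mult[j]
        out = np.where(seen, means[np.where(seen, code, 0)], np.nan)
        empty = ~np.isfinite(out)
        if empty.any():
            out[empty] = self._predict_from(X[empty], start + 1)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._predict_from(X, 0)

    @property
    def n_cells(self) -> int:
        levels, _, means, cnt = self._table(0)
        return 1 if levels is None else int((cnt > 0).sum())


class LogisticModel:
    """Main-terms logistic regression (statsmodels GLM, binomial family).

    Accepts fractional responses in [0, 1] (quasi-binomial), as needed for
    the iterated pseudo-outcomes.
    """

    def __init__(self) -> None:
        self._params: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticModel":
        Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            # degenerate response: closed form, avoids separation issues
            self._params = np.zeros(Xc.shape[1])
            p = min(max(y[0], 1e-12), 1 - 1e-12)
            self._params[0] = np.log(p / (1 - p))
            return self
        try:
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception as exc:  # pragma: no cover - defensive
            raise EstimationError(f"logistic fit failed: {exc}") from exc
        self._params = np.asarray(res.params)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
        eta = Xc @ self._params
        return 1.0 / (1.0 + np.exp(-eta))


class LinearModel:
    """Main-terms OLS for unbounded pseudo-outcomes."""

    def __init__(self) -> None:
        self._params: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearModel":
        Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
        self._params = np.linalg.lstsq(Xc, np.asarray(y, float), rcond=None)[0]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
        return Xc @ self._params


class InterceptModel:
    """Intercept-only learner (sample mean); used for deliberate
    misspecification in robustness experiments."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "InterceptModel":
        self._mean = float(np.mean(y))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self._mean)


_LEARNERS = {
    "saturated": SaturatedModel,
    "logistic": LogisticModel,
    "linear": LinearModel,
    "intercept": InterceptModel,
}


def make_learner(spec):
    """Resolve a learner spec (name or fit/predict object) to a fresh model."""
    if isinstance(spec, str):
        try:
            return _LEARNERS[spec]()
        except KeyError:
            raise ValueError(
                f"unknown learner {spec!r}; choose from {sorted(_LEARNERS)}"
            ) from None
    if isinstance(spec, type):
        return spec()
    if hasattr(spec, "fit") and hasattr(spec, "predict"):
        return spec.__class__()
    raise ValueError(f"invalid learner spec: {spec!r}")


# --------------------------------------------------------------------------
# treatment models
# --------------------------------------------------------------------------

class _ConstantModel:
    def __init__(self, p: float):
        self._p = float(p)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self._p)


@dataclasses.dataclass
class TreatmentModelSet:
    """One fitted initiation-probability model per time ``t = 1..K``."""

    models: list
    at_risk_n: list[int]
    learner: str
    prob_floor: float = DEFAULT_PROB_FLOOR

    def predict_initiation(self, cohort: LongitudinalCohort, t: int) -> np.ndarray:
        """P(A(t)=1 | W̄(t), Ā(t-1)=0, D(t-1)=0) for undelivered subjects.

        Returns NaN for subjects with D(t-1)=1 (no probability is needed
        there: strategy adherence continues with probability one).
        """
        riskset = cohort.d_prev(t) == 0
        X, _ = cohort.w_history(t)
        out = np.full(cohort.n, np.nan)
        p = self.models[t - 1].predict(X[riskset])
        if self.prob_floor > 0:
            p = np.clip(p, self.prob_floor, 1 - self.prob_floor)
        out[riskset] = p
        return out

    @classmethod
    def from_constant(cls, p, K: int) -> "TreatmentModelSet":
        """Oracle model set with known per-time initiation probabilities."""
        ps = np.broadcast_to(np.asarray(p, dtype=float), (K,))
        return cls(
            models=[_ConstantModel(pi) for pi in ps],
            at_risk_n=[0] * K,
            learner="constant",
            prob_floor=0.0,
        )


def fit_treatment_models(
    cohort: LongitudinalCohort,
    learner: str | object = "logistic",
    prob_floor: float = DEFAULT_PROB_FLOOR,
) -> TreatmentModelSet:
    """Fit the K initiation models on the correct at-risk subsets.

    At each time ``t`` the fitting subset is subjects with ``D(t-1)=0`` who
    have not initiated by ``t-1``; the response is ``A(t)``; the features
    are the full covariate history ``W̄(t)``. Raises
    :class:`PositivityError` when nobody (or everybody) at risk initiates.
    """
    obs_a = cohort.exposure_filled()
    initiated_by = np.cumsum(obs_a, axis=1) > 0
    models, sizes = [], []
    for t in range(1, cohort.K + 1):
        at_risk = cohort.d_prev(t) == 0
        if t > 1:
            at_risk &= ~initiated_by[:, t - 2]
        m = int(at_risk.sum())
        if m == 0:
            raise PositivityError(f"no at-risk, untreated subjects at time {t}")
        y = obs_a[at_risk, t - 1]
        n1 = y.sum()
        if n1 == 0 or n1 == m:
            raise PositivityError(
                f"positivity violation at time {t}: "
                f"{int(n1)} of {m} at-risk subjects initiate"
            )
        X, _ = cohort.w_history(t)
        models.append(make_learner(learner).fit(X[at_risk], y))
        sizes.append(m)
    name = learner if isinstance(learner, str) else type(learner).__name__
    return TreatmentModelSet(models, sizes, name, prob_floor)


# --------------------------------------------------------------------------
# outcome steps
# --------------------------------------------------------------------------

def _strategy_exposure_row(k: int, m: int) -> np.ndarray:
    """Exposure values A(1..m) fixed by strategy k (k > m => all zero)."""
    row = np.zeros(m)
    if k <= m:
        row[k - 1] = 1.0
    return row


def fit_outcome_step(
    pseudo_outcome: np.ndarray,
    cohort: LongitudinalCohort,
    t: int,
    k: int,
    learner: str | object = "logistic",
    mode: str = "intervene",
) -> tuple[np.ndarray, dict]:
    """One conditional-mean fit of the backward recursion at time ``t``.

    Returns predictions (length n, NaN for subjects delivered by ``t-1``)
    evaluated at the strategy-``k`` exposure values, plus a small info dict.

    mode="intervene" (default): fit among all subjects with ``D(t-1)=0``
    with the observed exposure history ``A(1..min(t,k))`` as predictors,
    then predict with that history set to the strategy values
    (``Ā(k-1)=0`` and, if ``k <= t``, ``A(k)=1``).
    mode="strict": fit only among strategy-consistent subjects
    (``S^k(t)=1``), covariate history only.
    """
    if mode not in ("intervene", "strict"):
        raise ValueError(f"unknown outcome-step mode {mode!r}")
    riskset = cohort.d_prev(t) == 0
    Xw, _ = cohort.w_history(t)
    m = min(t, k) if k <= cohort.K else t

    if mode == "strict":
        fit_mask = riskset & (strategy_indicators(cohort, k)[:, t - 1] == 1)
        X_fit = Xw[fit_mask]
        X_pred = Xw[riskset]
    else:
        fit_mask = riskset
        A_obs = cohort.exposure_filled()[:, :m]
        X_all = np.column_stack([Xw, A_obs])
        X_fit = X_all[fit_mask]
        X_pred = np.column_stack([
            Xw[riskset],
            np.broadcast_to(
                _strategy_exposure_row(k, m), (int(riskset.sum()), m)
            ),
        ])

    if fit_mask.sum() == 0:
        raise EstimationError(
            f"empty outcome-model fitting subset at (t={t}, k={k})"
        )
    y_fit = np.asarray(pseudo_outcome, dtype=float)[fit_mask]
    if np.isnan(y_fit).any():
        raise EstimationError(
            f"pseudo-outcome missing inside the fitting subset (t={t}, k={k})"
        )
    model = make_learner(learner).fit(X_fit, y_fit)
    preds = np.full(cohort.n, np.nan)
    preds[riskset] = model.predict(X_pred)
    info = {"t": t, "k": k, "n_fit": int(fit_mask.sum()), "mode": mode}
    return preds, info


def resolve_outcome_learner(learner, values: np.ndarray):
    """'auto' -> logistic on [0,1]-valued pseudo-outcomes, OLS otherwise."""
    if learner != "auto":
        return learner
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return "logistic" if (v.min() >= 0 and v.max() <= 1) else "linear"
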