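"""Synthetic pregnancy cohorts with a delivery-time competing-event
structure, a forced-assignment counterfactual-truth oracle, and the
repeated-sampling study harness.

The generator draws binary data ``(W(1), A(1), W(2), A(2), D(2), W(3),
A(3), D(3), W(4), A(4), Y)`` over K = 4 periods:

* ``W(1)`` is exogenous; ``U`` is an *unmeasured* common cause of early
  delivery and the outcome (never emitted in the cohort);
* exposure is sustained perfectly — once initiated it stays on — and
  initiation at ``t`` depends on the current covariate ``W(t)``;
* deliveries can occur at t = 2, 3 (driven by current exposure and ``U``)
  and are certain by t = 4; covariates/exposure are NA after delivery;
* the outcome depends on ``W(1)``, ``W(2)``, ``U``, on delivery timing with
  a per-period-earlier odds ratio ``beta``, and optionally directly on
  ``A(2)`` or ``A(4)``.

Four scenarios: (1) no delivery-time effect, no direct effect (beta = 1);
(2) beta = 2 only; (3) beta = 2 plus a direct A(2) effect;
(4) beta = 2 plus a direct A(4) effect.

All log-odds coefficients default to moderate (log 2) effects and are
overridable; no claim is made to any particular published coefficient set.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import cohort as cohort_mod
from .cohort import LongitudinalCohort
from .errors import PregstratError

K_SIM = 4
LOG2 = float(np.log(2.0))


@dataclasses.dataclass(frozen=True)
class SimCoefficients:
    """Structural-equation coefficients (log-odds scale unless noted)."""

    p_w1: float = 0.5            # P(W(1) = 1)
    p_u: float = 0.5             # P(U = 1)
    a_intercept: float = logit(0.25)
    a_on_w: float = LOG2         # current W(t) -> initiation
    w_intercept: float = logit(0.4)
    w_on_prev_w: float = LOG2
    w_on_prev_a: float = LOG2
    d_intercept: float = logit(0.15)
    d_on_a: float = -LOG2        # exposure lowers the early-delivery odds
    d_on_u: float = LOG2
    y_intercept: float = logit(0.15)
    y_on_w1: float = LOG2
    y_on_w2: float = LOG2
    y_on_u: float = LOG2
    direct_effect: float = LOG2  # A(2)->Y (scenario 3) or A(4)->Y (scenario 4)


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One of the four data-generating scenarios."""

    scenario: int
    n: int = 1000
    seed: int | None = None
    coefficients: SimCoefficients = SimCoefficients()
    delivery_effect_form: str = "per_period"   # or "indicator"
    beta_override: float | None = None

    def __post_init__(self):
        if self.scenario not in (1, 2, 3, 4):
            raise PregstratError(f"invalid scenario id {self.scenario}")
        if self.delivery_effect_form not in ("per_period", "indicator"):
            raise PregstratError(
                f"unknown delivery_effect_form {self.delivery_effect_form!r}"
            )

    @property
    def beta(self) -> float:
        """Delivery-time -> outcome odds ratio: 1 in scenario 1, else 2."""
        if self.beta_override is not None:
            return self.beta_override
        return 1.0 if self.scenario == 1 else 2.0

    @property
    def a2_direct(self) -> bool:
        return self.scenario == 3

    @property
    def a4_direct(self) -> bool:
        return self.scenario == 4


@dataclasses.dataclass
class CounterfactualTruth:
    """True strategy means E(Y^k) and adjacent contrasts from the oracle."""

    means: dict[int, float]
    mean_ses: dict[int, float]
    contrasts: dict[tuple[int, int], float]
    contrast_ses: dict[tuple[int, int], float]
    n: int


def _delivery_effect(spec: ScenarioSpec, t_d: np.ndarray) -> np.ndarray:
    earliness = K_SIM - t_d
    if spec.delivery_effect_form == "indicator":
        earliness = (t_d < K_SIM).astype(float)
    return np.log(spec.beta) * earliness


def _outcome_probability(
    spec: ScenarioSpec,
    w1: np.ndarray,
    w2: np.ndarray,
    u: np.ndarray,
    t_d: np.ndarray,
    a2: np.ndarray,
    a4: np.ndarray,
) -> np.ndarray:
    c = spec.coefficients
    eta = (
        c.y_intercept
        + c.y_on_w1 * w1
        + c.y_on_w2 * w2
        + c.y_on_u * u
        + _delivery_effect(spec, t_d)
    )
    if spec.a2_direct:
        eta = eta + c.direct_effect * a2
    if spec.a4_direct:
        eta = eta + c.direct_effect * a4
    return expit(eta)


def simulate_cohort(
    spec: ScenarioSpec, return_debug: bool = False
) -> LongitudinalCohort | tuple[LongitudinalCohort, dict]:
    """Draw one observational cohort from the scenario's structural equations.

    With ``return_debug=True`` also returns the unmeasured ``U`` and the
    unmasked variable arrays (for oracle checks only — the cohort itself
    never contains ``U``).
    """
    c = spec.coefficients
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    W = np.zeros((n, K_SIM))
    A = np.zeros((n, K_SIM))
    D = np.zeros((n, K_SIM), dtype=np.int8)

    W[:, 0] = rng.random(n) < c.p_w1
    U = (rng.random(n) < c.p_u).astype(float)
    A[:, 0] = rng.random(n) < expit(c.a_intercept + c.a_on_w * W[:, 0])
    for t in range(2, K_SIM + 1):
        i = t - 1
        W[:, i] = rng.random(n) < expit(
            c.w_intercept + c.w_on_prev_a * A[:, i - 1] + c.w_on_prev_w * W[:, i - 1]
        )
        # perfect sustained adherence: initiation only while untreated
        new_init = rng.random(n) < expit(c.a_intercept + c.a_on_w * W[:, i])
        A[:, i] = np.where(A[:, i - 1] == 1, 1.0, new_init)
        if t < K_SIM:
            hazard = rng.random(n) < expit(
                c.d_intercept + c.d_on_a * A[:, i] + c.d_on_u * U
            )
            D[:, i] = np.where(D[:, i - 1] == 1, 1, hazard)
    D[:, K_SIM - 1] = 1
    t_d = D.argmax(axis=1) + 1

    a4 = np.where(t_d == K_SIM, A[:, 3], 0.0)
    p_y = _outcome_probability(spec, W[:, 0], W[:, 1], U, t_d, A[:, 1], a4)
    Y = (rng.random(n) < p_y).astype(float)

    W_masked, A_masked = W.copy(), A.copy()
    t_grid = np.arange(1, K_SIM + 1)[None, :]
    post = t_grid > t_d[:, None]
    W_masked[post] = np.nan
    A_masked[post] = np.nan

    built = cohort_mod.from_arrays(
        W_masked, A_masked, D, Y, covariate_names=("w",)
    )
    if return_debug:
        return built, {"U": U, "W": W, "A": A, "p_y": p_y}
    return built


def counterfactual_truth(
    spec: ScenarioSpec,
    k: int | Sequence[int] = (2, 3, 4, 5),
    n_truth: int = 10**6,
    seed: int | None = None,
) -> CounterfactualTruth:
    """True E(Y^k) by forced-assignment simulation with common random numbers.

    The same structural equations are simulated with exposure forced to
    ``A(t) = I(t >= k)`` while undelivered (delivery still responds to the
    forced exposure). One set of uniform draws is shared across all
    strategies, so per-subject potential outcomes are coupled and contrast
    standard errors shrink accordingly.
    """
    ks = (k,) if isinstance(k, (int, np.integer)) else tuple(k)
    for kk in ks:
        if not 1 <= kk <= K_SIM + 1:
            raise PregstratError(f"strategy k={kk} outside 1..{K_SIM + 1}")
    c = spec.coefficients
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = n_truth
    w1 = (rng.random(n) < c.p_w1).astype(float)
    u = (rng.random(n) < c.p_u).astype(float)
    u_w = rng.random((n, K_SIM - 1))     # W(2..4)
    u_d = rng.random((n, 2))             # D(2), D(3)
    u_y = rng.random(n)

    y_by_k: dict[int, np.ndarray] = {}
    for kk in ks:
        W = np.zeros((n, K_SIM))
        W[:, 0] = w1
        A = np.zeros((n, K_SIM))
        D = np.zeros((n, K_SIM), dtype=np.int8)
        A[:, 0] = 1.0 if kk == 1 else 0.0
        for t in range(2, K_SIM + 1):
            i = t - 1
            W[:, i] = u_w[:, i - 1] < expit(
                c.w_intercept + c.w_on_prev_a * A[:, i - 1] + c.w_on_prev_w * W[:, i - 1]
            )
            A[:, i] = 1.0 if t >= kk else 0.0
            if t < K_SIM:
                hazard = u_d[:, i - 1] < expit(
                    c.d_intercept + c.d_on_a * A[:, i] + c.d_on_u * u
                )
                D[:, i] = np.where(D[:, i - 1] == 1, 1, hazard)
        D[:, K_SIM - 1] = 1
        t_d = D.argmax(axis=1) + 1
        # exposure cannot occur after delivery
        a2 = np.where(t_d >= 2, A[:, 1], 0.0)
        a4 = np.where(t_d == K_SIM, A[:, 3], 0.0)
        p_y = _outcome_probability(spec, w1, W[:, 1], u, t_d, a2, a4)
        y_by_k[kk] = (u_y < p_y).astype(float)

    means = {kk: float(y.mean()) for kk, y in y_by_k.items()}
    mean_ses = {
        kk: float(y.std(ddof=1) / np.sqrt(n)) for kk, y in y_by_k.items()
    }
    contrasts, contrast_ses = {}, {}
    for k1, k2 in zip(ks, ks[1:]):
        diff = y_by_k[k1] - y_by_k[k2]
        contrasts[(k1, k2)] = float(diff.mean())
        contrast_ses[(k1, k2)] = float(diff.std(ddof=1) / np.sqrt(n))
    return CounterfactualTruth(means, mean_ses, contrasts, contrast_ses, n)


# --------------------------------------------------------------------------
# repeated-sampling study
# --------------------------------------------------------------------------

STRATEGY_KS = (2, 3, 4, 5)
ADJACENT_CONTRASTS = ((2, 3), (3, 4), (4, 5))


def make_study_estimators(
    treatment_learner: str | object = "saturated",
    outcome_learner: str | object = "saturated",
    mode: str = "strict",
    prob_floor: float = 1e-3,
    which: Iterable[str] = ("ipw", "gcomp", "tmle", "standard_ipw"),
) -> dict[str, Callable[[LongitudinalCohort], dict]]:
    """Build named estimator callables returning adjacent-contrast dicts."""
    from .comparators import standard_ipw_estimate
    from .gcomp import gcomp_estimate
    from .ipw import ipw_estimate
    from .nuisance import fit_treatment_models
    from .tmle import tmle_estimate

    def _contrasts_from_means(means: Mapping[int, float]) -> dict:
        return {
            (k1, k2): means[k1] - means[k2] for k1, k2 in ADJACENT_CONTRASTS
        }

    def _ipw(cohort):
        models = fit_treatment_models(cohort, treatment_learner, prob_floor)
        means = {
            k: ipw_estimate(cohort, k, models=models).estimate
            for k in STRATEGY_KS
        }
        return _contrasts_from_means(means)

    def _gcomp(cohort):
        means = {
            k: gcomp_estimate(cohort, k, learner=outcome_learner, mode=mode).estimate
            for k in STRATEGY_KS
        }
        return _contrasts_from_means(means)

    def _tmle(cohort):
        models = fit_treatment_models(cohort, treatment_learner, prob_floor)
        means = {
            k: tmle_estimate(
                cohort, k, models=models,
                outcome_learner=outcome_learner, mode=mode,
            ).estimate
            for k in STRATEGY_KS
        }
        return _contrasts_from_means(means)

    def _standard_ipw(cohort):
        res = standard_ipw_estimate(cohort, learner=treatment_learner,
                                    prob_floor=prob_floor)
        return {
            pair: res["contrasts"][pair].estimate
            for pair in ADJACENT_CONTRASTS
            if pair in res["contrasts"]
        }

    registry = {
        "ipw": _ipw,
        "gcomp": _gcomp,
        "tmle": _tmle,
        "standard_ipw": _standard_ipw,
    }
    return {name: registry[name] for name in which}


def run_simulation_study(
    scenarios: Sequence[int] = (1, 2, 3, 4),
    reps: int = 1000,
    n: int = 1000,
    estimators: Mapping[str, Callable] | None = None,
    seed: int | None = None,
    n_truth: int = 10**6,
    coefficients: SimCoefficients | None = None,
    delivery_effect_form: str = "per_period",
) -> pd.DataFrame:
    """Bias / Monte-Carlo-error table over repeated simulated cohorts.

    For every scenario x adjacent contrast x estimator: mean(estimate -
    truth), the across-repetition standard deviation (``mc_sd``, the
    Monte-Carlo standard error of a single estimate) and the standard
    error of the mean bias (``bias_se = mc_sd / sqrt(reps)``). Estimator
    failures inside a repetition are counted, not fatal.
    """
    if estimators is None:
        estimators = make_study_estimators()
    coefficients = coefficients or SimCoefficients()
    root = np.random.SeedSequence(seed)
    truth_seed, *scen_seeds = root.spawn(len(scenarios) + 1)
    records = []
    for scen, scen_ss in zip(scenarios, scen_seeds):
        base = ScenarioSpec(
            scenario=scen, n=n, coefficients=coefficients,
            delivery_effect_form=delivery_effect_form,
        )
        truth = counterfactual_truth(
            base, STRATEGY_KS, n_truth=n_truth,
            seed=int(truth_seed.generate_state(1)[0] % (2**31)),
        )
        rep_seeds = scen_ss.generate_state(reps) % (2**31)
        estimates: dict[tuple[str, tuple[int, int]], list[float]] = {
            (name, pair): []
            for name in estimators for pair in ADJACENT_CONTRASTS
        }
        failures = {name: 0 for name in estimators}
        for r in range(reps):
            spec = dataclasses.replace(base, seed=int(rep_seeds[r]))
            cohort = simulate_cohort(spec)
            for name, fn in estimators.items():
                try:
                    out = fn(cohort)
                except PregstratError:
                    failures[name] += 1
                    continue
                for pair, value in out.items():
                    estimates[(name, pair)].append(value)
        for name in estimators:
            for pair in ADJACENT_CONTRASTS:
                vals = np.asarray(estimates[(name, pair)])
                if vals.size == 0:
                    continue
                true_val = truth.contrasts[pair]
                records.append({
                    "scenario": scen,
                    "contrast": f"{pair[0]}v{pair[1]}",
                    "estimator": name,
                    "truth": true_val,
                    "bias": float(vals.mean() - true_val),
                    "mc_sd": float(vals.std(ddof=1)),
                    "bias_se": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                    "mean_estimate": float(vals.mean()),
                    "reps_ok": int(vals.size),
                    "failures": failures[name],
                })
    return pd.DataFrame.from_records(records)
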