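"""Shared fixtures: a dense discrete two-period cohort and simulated
scenario cohorts, plus the independent brute-force oracles used to check
the estimators (direct-enumeration g-formula; definition-level adherence)."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

import pregstrat as ps


def make_two_period_cohort(n: int = 600, seed: int = 20) -> ps.LongitudinalCohort:
    """Discrete two-period cohort (W(1), A(1), D(1), W(2), A(2), Y), K=2.

    Binary everything, moderate effects, all history cells populated at
    the default n, exposure sustained once initiated, with an unmeasured
    cause of both delivery and outcome baked into the draws.
    """
    rng = np.random.default_rng(seed)
    w1 = (rng.random(n) < 0.5).astype(float)
    u = (rng.random(n) < 0.4).astype(float)
    a1 = (rng.random(n) < expit(-1.0 + 0.8 * w1)).astype(float)
    d1 = (rng.random(n) < expit(-1.2 + 0.5 * a1 + 0.8 * u)).astype(float)
    w2 = (rng.random(n) < expit(-0.3 + 0.6 * w1 + 0.5 * a1)).astype(float)
    a2_new = (rng.random(n) < expit(-0.8 + 0.7 * w2)).astype(float)
    a2 = np.where(a1 == 1, 1.0, a2_new)
    p_y = np.where(
        d1 == 1,
        expit(-0.5 + 0.7 * w1 + 0.6 * u),
        expit(-1.0 + 0.5 * w1 + 0.4 * w2 + 0.6 * u),
    )
    y = (rng.random(n) < p_y).astype(float)

    W = np.stack([w1, np.where(d1 == 1, np.nan, w2)], axis=1)
    A = np.stack([a1, np.where(d1 == 1, np.nan, a2)], axis=1)
    D = np.stack([d1, np.ones(n)], axis=1).astype(int)
    return ps.from_arrays(W, A, D, y, covariate_names=("w",))


@pytest.fixture(scope="session")
def two_period_cohort() -> ps.LongitudinalCohort:
    return make_two_period_cohort()


@pytest.fixture(scope="session")
def scenario2_cohort() -> ps.LongitudinalCohort:
    return ps.simulate_cohort(ps.ScenarioSpec(scenario=2, n=1500, seed=11))


def enumeration_gformula_two_period(cohort: ps.LongitudinalCohort, k: int) -> float:
    """Brute-force g-formula E(Y^k) by direct enumeration of discrete cells.

    Works from the raw arrays with empirical conditional frequencies —
    independent of the package's backward-recursion, weighting and
    targeting code paths. K must be 2; k in {1, 2, 3}.
    """
    assert cohort.K == 2 and k in (1, 2, 3)
    w1 = cohort.W[:, 0, 0]
    w2 = cohort.W[:, 1, 0]
    a1 = cohort.A[:, 0]
    a2 = cohort.A[:, 1]
    d1 = cohort.D[:, 0].astype(float)
    y = cohort.Y
    a1_star = 1.0 if k == 1 else 0.0

    def mean_of(mask):
        assert mask.sum() > 0, "oracle hit an empty cell; enlarge the fixture"
        return y[mask].mean()

    total = 0.0
    n = cohort.n
    for v1 in np.unique(w1):
        sel1 = w1 == v1
        p_w1 = sel1.mean()
        base = sel1 & (a1 == a1_star)
        p_d1 = d1[base].mean()
        # delivered at t=1: outcome determined, A(2) never happens
        inner = p_d1 * mean_of(base & (d1 == 1))
        undeliv = base & (d1 == 0)
        a2_star = 1.0 if k <= 2 else 0.0
        for v2 in np.unique(w2[np.isfinite(w2)]):
            cell = undeliv & (w2 == v2)
            p_w2 = cell.sum() / undeliv.sum()
            inner += (1 - p_d1) * p_w2 * mean_of(cell & (a2 == a2_star))
        total += p_w1 * inner
    return float(total)


def adherence_oracle(cohort: ps.LongitudinalCohort, k: int, t: int) -> np.ndarray:
    """Definition-level re-derivation of S^k(t), one subject at a time."""
    out = np.zeros(cohort.n, dtype=int)
    for i in range(cohort.n):
        ok = True
        for l in range(1, t + 1):
            delivered_before_l = l >= 2 and cohort.D[i, l - 2] == 1
            if delivered_before_l:
                continue  # nothing can violate the strategy after delivery
            a = cohort.A[i, l - 1]
            if l < k and a == 1:
                ok = False
            if l == k and a != 1:
                ok = False
            # l > k: post-initiation values do not affect the start-time rule
        out[i] = int(ok)
    return out


def random_small_cohort(rng: np.random.Generator, n: int = 40, K: int = 3):
    """Arbitrary small cohort with valid structure for property tests."""
    T_D = rng.integers(1, K + 1, n)
    T_D[rng.random(n) < 0.3] = K  # keep some full-term mass
    D = (np.arange(1, K + 1)[None, :] >= T_D[:, None]).astype(int)
    first = np.where(rng.random(n) < 0.5, rng.integers(1, K + 1, n), 10**6)
    A = (np.arange(1, K + 1)[None, :] >= first[:, None]).astype(float)
    W = rng.integers(0, 2, (n, K)).astype(float)
    post = np.arange(1, K + 1)[None, :] > T_D[:, None]
    A[post] = np.nan
    W[post] = np.nan
    Y = rng.integers(0, 2, n).astype(float)
    return ps.from_arrays(W, A, D, Y)
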