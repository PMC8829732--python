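"""Observed-data structure for pregnancy cohorts with delivery interruption.

The observed data for each subject are ``({W(t), A(t), D(t); t=1..K}, Y)``:
time-varying covariates ``W``, a binary exposure ``A``, a monotone
delivered-by indicator ``D`` with ``D(K)=1`` for everyone, and an outcome
``Y`` measured at delivery for every pregnancy regardless of delivery time.
Once a subject delivers at time ``T_D``, exposure and covariates are no
longer defined: ``W(t)=A(t)=NA`` for ``t > T_D``.

A *treatment strategy* ``k`` is the rule "initiate exposure at time ``k``
unless delivery has already occurred"; ``k = K+1`` means never initiate.
One observed history can be compatible with several strategies at once,
which :func:`strategy_indicators` encodes as the indicator ``S^k(t)``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CohortStructureError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "time", "A", "D")
COVARIATE_PREFIX = "W_"


@dataclasses.dataclass(frozen=True)
class LongitudinalCohort:
    """Validated subject-time panel with delivery-interruption semantics.

    Arrays are subject-major; time is 1-based in the API and stored in
    axis positions ``0..K-1``. ``W`` and ``A`` hold ``NaN`` for ``t > T_D``.
    """

    subject_ids: np.ndarray          # (n,)
    K: int
    W: np.ndarray                    # (n, K, p) float
    A: np.ndarray                    # (n, K) float, NaN after delivery
    D: np.ndarray                    # (n, K) int8, monotone, D[:, K-1] == 1
    T_D: np.ndarray                  # (n,) int, first t with D(t) = 1
    Y: np.ndarray                    # (n,) float
    covariate_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.W.shape[2]

    def d_prev(self, t: int) -> np.ndarray:
        """D(t-1) as a 0/1 vector; D(0)=0 by convention."""
        if t < 1 or t > self.K:
            raise ValueError(f"time {t} outside 1..{self.K}")
        if t == 1:
            return np.zeros(self.n, dtype=np.int8)
        return self.D[:, t - 2]

    def exposure_filled(self) -> np.ndarray:
        """A with post-delivery NA replaced by 0 (no exposure can occur)."""
        return np.nan_to_num(self.A, nan=0.0)

    def w_history(self, t: int) -> tuple[np.ndarray, list[str]]:
        """Covariate history W̄(t) as a 2D block with column labels."""
        block = self.W[:, :t, :].reshape(self.n, -1)
        names = [
            f"{name}__t{l}"
            for l in range(1, t + 1)
            for name in self.covariate_names
        ]
        return block, names

    def first_initiation(self) -> np.ndarray:
        """First observed exposure time per subject; +inf if never exposed."""
        obs = self.exposure_filled() > 0
        any_init = obs.any(axis=1)
        first = obs.argmax(axis=1) + 1.0
        first[~any_init] = np.inf
        return first

    def take(self, indices: np.ndarray) -> "LongitudinalCohort":
        """Subject-level subset/resample (whole trajectories)."""
        return LongitudinalCohort(
            subject_ids=np.arange(len(indices)),
            K=self.K,
            W=self.W[indices],
            A=self.A[indices],
            D=self.D[indices],
            T_D=self.T_D[indices],
            Y=self.Y[indices],
            covariate_names=self.covariate_names,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format view (one row per subject-time, Y repeated)."""
        n, K = self.n, self.K
        rows = {
            "subject_id": np.repeat(self.subject_ids, K),
            "time": np.tile(np.arange(1, K + 1), n),
            "A": self.A.reshape(-1),
            "D": self.D.reshape(-1).astype(float),
            "Y": np.repeat(self.Y, K),
        }
        for j, name in enumerate(self.covariate_names):
            rows[f"{COVARIATE_PREFIX}{name}"] = self.W[:, :, j].reshape(-1)
        return pd.DataFrame(rows)


def _fail(subject, message: str) -> None:
    raise CohortStructureError(f"subject {subject!r}: {message}")


def from_arrays(
    W: np.ndarray,
    A: np.ndarray,
    D: np.ndarray,
    Y: np.ndarray,
    covariate_names: Sequence[str] | None = None,
    subject_ids: np.ndarray | None = None,
) -> LongitudinalCohort:
    """Build a validated cohort directly from aligned arrays.

    ``W`` may be (n, K) or (n, K, p). Post-delivery entries of ``W``/``A``
    must already be NaN. Raises :class:`CohortStructureError` on any
    violation of the data structure.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim == 2:
        W = W[:, :, None]
    A = np.asarray(A, dtype=float)
    D = np.asarray(D)
    Y = np.asarray(Y, dtype=float)
    n, K = A.shape
    if D.shape != (n, K) or W.shape[:2] != (n, K) or Y.shape != (n,):
        raise CohortStructureError("array shapes are inconsistent")
    if covariate_names is None:
        covariate_names = tuple(f"w{j + 1}" for j in range(W.shape[2]))
    if subject_ids is None:
        subject_ids = np.arange(n)

    if np.isnan(np.asarray(D, dtype=float)).any():
        raise CohortStructureError("delivery indicator contains missing values")
    D = D.astype(np.int8)
    if not set(np.unique(D)) <= {0, 1}:
        raise CohortStructureError("delivery indicator must be binary")
    if (np.diff(D, axis=1) < 0).any():
        bad = np.where((np.diff(D, axis=1) < 0).any(axis=1))[0][0]
        _fail(subject_ids[bad], "delivery indicator not monotone")
    if not (D[:, K - 1] == 1).all():
        bad = np.where(D[:, K - 1] != 1)[0][0]
        _fail(subject_ids[bad], f"not delivered by final time K={K}")
    T_D = D.argmax(axis=1) + 1

    if np.isnan(Y).any():
        bad = np.where(np.isnan(Y))[0][0]
        _fail(subject_ids[bad], "missing outcome Y")

    # NA pattern: W(t), A(t) must be missing strictly after T_D and present
    # strictly before it; at t = T_D either is accepted (exposure precedes
    # delivery within a period, but some sources blank the delivery row)
    t_grid = np.arange(1, K + 1)[None, :]
    post = t_grid > T_D[:, None]
    pre = t_grid < T_D[:, None]
    if np.isfinite(A[post]).any():
        bad = np.where((post & np.isfinite(A)).any(axis=1))[0][0]
        _fail(subject_ids[bad], "exposure recorded after delivery")
    if np.isfinite(W[post]).any():
        bad = np.where((post[:, :, None] & np.isfinite(W)).any(axis=(1, 2)))[0][0]
        _fail(subject_ids[bad], "covariate recorded after delivery")
    if np.isnan(A[pre]).any():
        bad = np.where((pre & np.isnan(A)).any(axis=1))[0][0]
        _fail(subject_ids[bad], "missing exposure before delivery")
    if np.isnan(W[pre]).any():
        bad = np.where((pre[:, :, None] & np.isnan(W)).any(axis=(1, 2)))[0][0]
        _fail(subject_ids[bad], "missing covariate before delivery")
    obs_a = np.nan_to_num(A, nan=0.0)
    if not set(np.unique(obs_a)) <= {0.0, 1.0}:
        raise CohortStructureError("exposure must be binary")

    return LongitudinalCohort(
        subject_ids=np.asarray(subject_ids),
        K=K,
        W=W,
        A=A,
        D=D,
        T_D=T_D,
        Y=Y,
        covariate_names=tuple(covariate_names),
    )


def validate_cohort(
    raw_panel: pd.DataFrame | str | Path,
    covariate_prefix: str = COVARIATE_PREFIX,
) -> LongitudinalCohort:
    """Validate a long-format panel and return a :class:`LongitudinalCohort`.

    Expected columns: ``subject_id, time, A, D, Y, W_*`` (any number of
    prefixed covariate columns). ``Y`` may be repeated on every row of a
    subject or present only on the delivery row. Missing values are empty
    fields / NaN. A censoring column ``C`` is accepted but ignored.
    """
    if isinstance(raw_panel, (str, Path)):
        df = pd.read_csv(raw_panel)
    else:
        df = raw_panel.copy()

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortStructureError(f"missing required columns: {missing}")
    if "C" in df.columns:
        logger.warning(
            "censoring column 'C' found; censoring processes are not "
            "modelled and the column is ignored"
        )
    wcols = sorted(c for c in df.columns if c.startswith(covariate_prefix))
    if not wcols:
        raise CohortStructureError(
            f"no covariate columns with prefix {covariate_prefix!r}"
        )

    df = df.sort_values(["subject_id", "time"])
    times = np.sort(df["time"].unique())
    K = int(times.max())
    if not np.array_equal(times, np.arange(1, K + 1)):
        raise CohortStructureError(f"time values must be exactly 1..{K}")
    counts = df.groupby("subject_id", sort=True)["time"].agg(["size", "nunique"])
    if (counts["size"] != K).any() or (counts["nunique"] != K).any():
        bad = counts.index[counts["size"] != K]
        if len(bad) == 0:
            bad = counts.index[counts["nunique"] != K]
        _fail(bad[0], f"K inconsistent across subjects (expected {K} rows)")

    subject_ids = counts.index.to_numpy()
    n = len(subject_ids)
    A = df["A"].to_numpy(dtype=float).reshape(n, K)
    D_raw = df["D"].to_numpy(dtype=float).reshape(n, K)
    W = np.stack(
        [df[c].to_numpy(dtype=float).reshape(n, K) for c in wcols], axis=2
    )

    if "Y" not in df.columns:
        raise CohortStructureError("missing outcome column Y")
    Ymat = df["Y"].to_numpy(dtype=float).reshape(n, K)
    Y = np.full(n, np.nan)
    for i in range(n):
        vals = Ymat[i][np.isfinite(Ymat[i])]
        if vals.size == 0:
            _fail(subject_ids[i], "missing outcome Y")
        if np.ptp(vals) > 0:
            _fail(subject_ids[i], "conflicting outcome values across rows")
        Y[i] = vals[0]

    return from_arrays(
        W, A, D_raw, Y,
        covariate_names=tuple(c[len(covariate_prefix):] for c in wcols),
        subject_ids=subject_ids,
    )


def strategy_indicators(cohort: LongitudinalCohort, k: int) -> np.ndarray:
    """Adherence matrix ``S^k(t)`` for one strategy, shape (n, K).

    ``S^k(t) = 1`` iff the observed (A, D) history through ``t`` is
    compatible with "initiate at ``k`` unless already delivered": no
    exposure at any time before ``k``, and — if ``k`` is reached
    undelivered and ``k <= t`` — exposure exactly at ``k``. A subject who
    never initiated and delivered at ``T_D`` follows every strategy with
    ``k > T_D``. Post-initiation exposure values are ignored (the rule
    assigns a start time only). Non-increasing in ``t`` by construction.
    """
    K = cohort.K
    if not 1 <= k <= K + 1:
        raise ValueError(f"strategy k={k} outside 1..{K + 1}")
    obs_a = cohort.exposure_filled() > 0
    initiated_by = np.cumsum(obs_a, axis=1) > 0      # any exposure by t
    S = np.ones((cohort.n, K), dtype=np.int8)
    for t in range(1, K + 1):
        pre = min(t, k - 1)
        ok = np.ones(cohort.n, dtype=bool)
        if pre >= 1:
            ok &= ~initiated_by[:, pre - 1]
        if k <= t:
            undelivered_at_k = cohort.d_prev(k) == 0
            ok &= (~undelivered_at_k) | obs_a[:, k - 1]
        S[:, t - 1] = ok
    return S


def strategy_indicator(cohort: LongitudinalCohort, k: int, t: int) -> np.ndarray:
    """``S^k(t)`` as a 0/1 vector over subjects."""
    if not 1 <= t <= cohort.K:
        raise ValueError(f"time {t} outside 1..{cohort.K}")
    return strategy_indicators(cohort, k)[:, t - 1]
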