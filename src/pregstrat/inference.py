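"""Estimate containers, contrasts, nonparametric bootstrap, and reporting.

Confidence intervals come from a subject-level (whole-trajectory)
nonparametric bootstrap in which every nuisance model is refit inside each
replicate. Contrasts of two strategies on the same cohort use *paired*
replicates, never differenced marginal intervals.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import LongitudinalCohort
from .errors import EstimationError, PregstratError

CSV_COLUMNS = ["method", "k1", "k2", "estimate", "ci_lo", "ci_hi", "level", "B"]


@dataclasses.dataclass
class EstimateResult:
    """Point estimate of E(Y^k) or a contrast E(Y^k1) - E(Y^k2)."""

    method: str
    k: int | tuple[int, int] | None
    estimate: float
    ci: tuple[float, float] | None = None
    level: float | None = None
    B: int = 0
    diagnostics: dict = dataclasses.field(default_factory=dict)
    replicates: np.ndarray | None = None

    @property
    def is_contrast(self) -> bool:
        return isinstance(self.k, tuple)

    def row(self) -> dict:
        k1, k2 = (self.k if self.is_contrast else (self.k, None))
        lo, hi = self.ci if self.ci is not None else (None, None)
        return {
            "method": self.method, "k1": k1, "k2": k2,
            "estimate": self.estimate, "ci_lo": lo, "ci_hi": hi,
            "level": self.level, "B": self.B,
        }


def contrast(result_k1: EstimateResult, result_k2: EstimateResult) -> EstimateResult:
    """Difference of two strategy means, with a paired-bootstrap CI.

    Both results must come from the same method on the same cohort; when
    both carry bootstrap replicates (aligned by replicate index) the CI is
    the percentile interval of the replicate-wise differences.
    """
    if result_k1.method != result_k2.method:
        raise EstimationError(
            f"cannot contrast estimates from different methods: "
            f"{result_k1.method!r} vs {result_k2.method!r}"
        )
    est = result_k1.estimate - result_k2.estimate
    ci = None
    level = result_k1.level
    B = 0
    reps = None
    r1, r2 = result_k1.replicates, result_k2.replicates
    if r1 is not None and r2 is not None:
        if len(r1) != len(r2):
            raise EstimationError("bootstrap replicates are not aligned")
        reps = np.asarray(r1) - np.asarray(r2)
        B = len(reps)
        level = level or 0.95
        ci = percentile_interval(reps, level)
    return EstimateResult(
        method=result_k1.method,
        k=(result_k1.k, result_k2.k),
        estimate=est, ci=ci, level=level, B=B, replicates=reps,
    )


def percentile_interval(replicates: np.ndarray, level: float):
    """Percentile CI; columns are treated separately for 2-D replicates."""
    alpha = (1.0 - level) / 2.0
    replicates = np.asarray(replicates)
    lo, hi = np.quantile(replicates, [alpha, 1.0 - alpha], axis=0)
    if replicates.ndim == 1:
        return float(lo), float(hi)
    return lo, hi


@dataclasses.dataclass
class BootstrapResult:
    ci: tuple[float, float]
    replicates: np.ndarray
    n_failures: int
    level: float
    seed: int | None


def bootstrap_ci(
    estimator: Callable[[LongitudinalCohort], float],
    cohort: LongitudinalCohort,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    max_failure_frac: float = 0.2,
) -> BootstrapResult:
    """Percentile bootstrap of an end-to-end estimator closure.

    Resamples subjects (entire trajectories) with replacement; the
    estimator — including all nuisance-model fits — runs from scratch on
    each replicate. The estimator may return a scalar or a vector (one CI
    per component). Replicates where the estimator raises a package error
    (e.g. a positivity violation in a resample) are excluded and counted;
    more than ``max_failure_frac`` failures aborts.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = cohort.n
    reps, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            value = estimator(cohort.take(idx))
        except PregstratError:
            failures += 1
            continue
        reps.append(
            float(value) if np.ndim(value) == 0
            else np.asarray(value, dtype=float)
        )
    if failures > max_failure_frac * B:
        raise EstimationError(
            f"bootstrap unstable: {failures}/{B} replicates failed"
        )
    replicates = np.asarray(reps)
    return BootstrapResult(
        ci=percentile_interval(replicates, level),
        replicates=replicates,
        n_failures=failures,
        level=level,
        seed=seed,
    )


def results_frame(results: Sequence[EstimateResult]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results], columns=CSV_COLUMNS)


def report(
    results: Sequence[EstimateResult],
    out_prefix: str | Path,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the results table as CSV and JSON plus a reproducibility log.

    Returns the mapping of artefact name to written path. The CSV has
    exactly the columns ``method,k1,k2,estimate,ci_lo,ci_hi,level,B``.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    frame = results_frame(results)
    paths = {
        "csv": out_prefix.with_suffix(".csv"),
        "json": out_prefix.with_suffix(".json"),
        "log": Path(str(out_prefix) + ".log.json"),
    }
    frame.to_csv(paths["csv"], index=False)
    records = frame.where(pd.notna(frame), None).to_dict(orient="records")
    paths["json"].write_text(json.dumps(records, indent=2))
    import pregstrat
    log = {
        "config": config or {},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "pregstrat": pregstrat.__version__,
        },
    }
    paths["log"].write_text(json.dumps(log, indent=2))
    return paths
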