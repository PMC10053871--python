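"""Patient-level bootstrap for the full clone-censor-weight pipeline.

The resampling unit is the original patient, never the clone: the two
clones of one patient are deterministic copies and must enter or leave a
replicate together.  Each replicate draws n patients with replacement,
reassigns ids (a patient drawn twice becomes two pseudo-patients), and
re-runs the entire pipeline — cloning, grace censoring, censoring-model
fitting, weighting, estimation — so that the weighting step's variability
propagates into the intervals.  Intervals are percentile bootstrap.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .cox import CoxConvergenceError


@dataclass
class BootstrapResult:
    """Point estimate, replicate draws, and a percentile interval."""

    estimate: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    B: int
    seed: int
    level: float = 0.95
    n_failed: int = 0


def bootstrap_ci(
    cohort: Cohort,
    pipeline: Callable[[Cohort], object],
    statistics: Mapping[str, Callable[[object], float]],
    B: int = 500,
    seed: int = 0,
    level: float = 0.95,
    max_failure_fraction: float = 0.10,
) -> dict[str, BootstrapResult]:
    """Percentile bootstrap intervals for named statistics of a pipeline.

    ``pipeline`` maps a cohort to an analysis result; each extractor in
    ``statistics`` maps that result to a scalar.  Replicates whose fit fails
    (degenerate resample, non-convergence) are dropped and counted; more
    than ``max_failure_fraction`` failures aborts with diagnostics.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if not statistics:
        raise ValueError("no statistics requested")

    full = pipeline(cohort)
    estimates = {name: float(fn(full)) for name, fn in statistics.items()}

    rng = np.random.default_rng(seed)
    n = len(cohort)
    draws: dict[str, list[float]] = {name: [] for name in statistics}
    failures: list[str] = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub = cohort.take(idx, reassign_ids=True)
        try:
            res = pipeline(sub)
            for name, fn in statistics.items():
                draws[name].append(float(fn(res)))
        except (ValueError, RuntimeError, ZeroDivisionError,
                np.linalg.LinAlgError, CoxConvergenceError) as exc:
            failures.append(f"{type(exc).__name__}: {exc}")
    n_failed = len(failures)
    if n_failed > max_failure_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed; first failures: "
            + "; ".join(failures[:3])
        )

    alpha = (1.0 - level) / 2.0
    out: dict[str, BootstrapResult] = {}
    for name in statistics:
        reps = np.asarray(draws[name], dtype=float)
        lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
        out[name] = BootstrapResult(
            estimate=estimates[name], replicates=reps,
            ci_low=float(lo), ci_high=float(hi),
            B=B, seed=seed, level=level, n_failed=n_failed,
        )
    return out
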