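"""Randomisation inference for group-dependent measures.

Individual measures taken within a group are not independent, so classical
two-sample tests are off the table.  Two procedures are provided:

* a paired-swap randomisation test for per-individual measures observed in
  two treatments: each individual's pair of values is swapped between
  treatments with probability 1/2, and the absolute difference of treatment
  means is the test statistic;
* a Monte-Carlo percentile test for group-polygon reductions: the null
  distribution of 12-to-6 reductions is built from paired random-walk
  simulations and the observed reduction is compared against its upper 2.5%
  quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .random_walk import WalkConfig, iter_replicate_frames
from .group_geometry import polygon_reduction

__all__ = [
    "RandTestResult",
    "PercentileTestResult",
    "paired_swap_test",
    "exhaustive_swap_test",
    "null_polygon_reductions",
    "polygon_percentile_test",
]


@dataclass
class RandTestResult:
    """Observed statistic and Monte-Carlo (or exact) p-value."""

    observed_stat: float
    p_value: float
    repetitions: int
    seed: int | None = None
    exact: bool = False


@dataclass
class PercentileTestResult:
    """Observed reduction versus the null 0.025-percentile critical value."""

    observed_reduction: float
    critical_value: float
    significant: bool
    repetitions: int
    metric: str
    seed: int | None = None


def _check_pairs(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 matched individuals")
    return a, b


def paired_swap_test(
    a, b, reps: int = 100_000, seed: int = 0
) -> RandTestResult:
    """Monte-Carlo paired-swap randomisation test.

    The statistic is |mean(a) - mean(b)|.  Each repetition independently
    swaps each individual's (a_i, b_i) pair with probability 1/2.  The
    p-value uses the add-one convention (k+1)/(reps+1), which keeps it in
    (0, 1] and counts ties as extreme.
    """
    a, b = _check_pairs(a, b)
    observed = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    diff = a - b  # swapping a pair flips the sign of its contribution
    signs = rng.integers(0, 2, size=(reps, len(a))) * 2 - 1
    null = np.abs(signs @ diff) / len(a)
    k = int(np.sum(null >= observed - 1e-12))
    return RandTestResult(
        observed_stat=float(observed),
        p_value=(k + 1) / (reps + 1),
        repetitions=reps,
        seed=seed,
    )


def exhaustive_swap_test(a, b) -> RandTestResult:
    """Exact version of the paired-swap test over all 2^n swap patterns."""
    a, b = _check_pairs(a, b)
    n = len(a)
    if n > 20:
        raise ValueError("exhaustive enumeration is limited to n <= 20")
    observed = abs(a.mean() - b.mean())
    diff = a - b
    codes = np.arange(2**n, dtype=np.int64)
    signs = ((codes[:, None] >> np.arange(n)) & 1) * 2 - 1
    null = np.abs(signs @ diff) / n
    k = int(np.sum(null >= observed - 1e-12))
    return RandTestResult(
        observed_stat=float(observed),
        p_value=k / 2**n,
        repetitions=2**n,
        exact=True,
    )


def null_polygon_reductions(
    config_high: WalkConfig,
    n_low: int = 6,
    reps: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of paired high-to-low polygon reductions.

    Each repetition simulates one recording at the high group size and one at
    the low size (identical parameters otherwise) and returns the percent
    reduction of the per-run mean hull metric; column 0 is the perimeter
    reduction, column 1 the area reduction.
    """
    config_low = config_high.with_agents(n_low)
    out = np.empty((reps, 2))
    high_frames = iter_replicate_frames(config_high, reps, seed)
    low_frames = iter_replicate_frames(config_low, reps, seed + 1)
    for i, (fh, fl) in enumerate(zip(high_frames, low_frames)):
        mh = _kernels.hull_metrics_frames(fh).mean(axis=0)
        ml = _kernels.hull_metrics_frames(fl).mean(axis=0)
        out[i, 0] = polygon_reduction(mh[0], ml[0])
        out[i, 1] = polygon_reduction(mh[1], ml[1])
    return out


def polygon_percentile_test(
    observed_reduction: float,
    config_high: WalkConfig,
    n_low: int = 6,
    reps: int = 10_000,
    seed: int = 0,
    metric: str = "area",
    null_reductions: np.ndarray | None = None,
) -> PercentileTestResult:
    """Compare an observed polygon reduction against the simulation null.

    The critical value is the upper 2.5% quantile of the null reduction
    distribution (larger reduction = more extreme); the observed reduction is
    significant when it exceeds that value.  A precomputed array from
    :func:`null_polygon_reductions` can be passed to test both metrics
    without re-simulating.
    """
    if metric not in ("perimeter", "area"):
        raise ValueError("metric must be 'perimeter' or 'area'")
    if null_reductions is None:
        null_reductions = null_polygon_reductions(config_high, n_low, reps, seed)
    col = 0 if metric == "perimeter" else 1
    critical = float(np.quantile(null_reductions[:, col], 0.975))
    return PercentileTestResult(
        observed_reduction=float(observed_reduction),
        critical_value=critical,
        significant=bool(observed_reduction > critical),
        repetitions=len(null_reductions),
        metric=metric,
        seed=seed,
    )
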