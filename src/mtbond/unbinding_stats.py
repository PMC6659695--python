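"""Comparison statistics for rupture-force samples.

The experimental workflow pools primary unbinding forces per condition
and direction, then compares conditions with: normalized 1-pN histograms
(approximating the rupture-force pdf), percentile-bootstrap 95% CIs of
the mean (4,000 resamples), empirical CDFs, a two-sample
Kolmogorov-Smirnov test (p_ks), and a bootstrap difference-of-means test
(p_m, 1e5 resampled means per sample, centred under the null, two-tailed,
floored at 1e-5 when no resample exceeds the observed difference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

__all__ = [
    "ForceHistogram",
    "MeanCI",
    "TestResult",
    "normalized_histogram",
    "bootstrap_ci_mean",
    "ecdf",
    "ks_two_sample",
    "bootstrap_mean_diff_p",
]

P_FLOOR = 1e-5  # reporting floor for the bootstrap mean-difference p-value


class StatsError(ValueError):
    """Invalid input to a statistics operation."""


@dataclass(frozen=True)
class ForceHistogram:
    """Normalized rupture-force histogram with 1-pN bins anchored at 0."""

    bin_edges: np.ndarray  # pN, integer edges
    counts: np.ndarray
    heights: np.ndarray  # counts / N
    N: int


@dataclass(frozen=True)
class MeanCI:
    """Bootstrap percentile CI of a sample mean."""

    mean: float
    lo: float
    hi: float
    level: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class TestResult:
    """Two-sample test outcome; ``floor_flag`` marks a floored p_m."""

    statistic: float
    p_value: float
    kind: str  # "ks" | "boot_mean_diff"
    floor_flag: bool = False

    def __str__(self) -> str:
        p = f"<{self.p_value:g}" if self.floor_flag else f"{self.p_value:.4g}"
        return f"{self.kind}: statistic={self.statistic:.4g}, p={p}"


def normalized_histogram(forces: np.ndarray) -> ForceHistogram:
    """1-pN-bin histogram of force magnitudes, heights normalized by N."""
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        raise StatsError("cannot histogram an empty force sample")
    if np.any(forces < 0):
        raise StatsError("histogram expects force magnitudes (all >= 0)")
    hi = int(np.floor(forces.max())) + 1
    edges = np.arange(0, hi + 1, dtype=float)
    counts, _ = np.histogram(forces, bins=edges)
    return ForceHistogram(
        bin_edges=edges,
        counts=counts,
        heights=counts / forces.size,
        N=int(forces.size),
    )


def bootstrap_ci_mean(
    values: np.ndarray,
    n_boot: int = 4000,
    level: float = 0.95,
    seed: int = 0,
) -> MeanCI:
    """Percentile-bootstrap CI of the mean (default 4,000 resamples, 95%)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise StatsError("bootstrap CI needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot_means = values[idx].mean(axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(boot_means, [alpha / 2, 1 - alpha / 2])
    return MeanCI(
        mean=float(values.mean()),
        lo=float(lo),
        hi=float(hi),
        level=level,
        n_boot=n_boot,
        seed=seed,
    )


def ecdf(values: np.ndarray) -> Callable[[np.ndarray | float], np.ndarray]:
    """Right-continuous empirical CDF with 1/n jumps (ties stack)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise StatsError("ECDF needs at least one value")
    srt = np.sort(values)
    n = srt.size

    def F(x: np.ndarray | float) -> np.ndarray:
        x_arr = np.asarray(x, dtype=float)
        out = np.searchsorted(srt, x_arr, side="right") / n
        return out if x_arr.ndim else float(out)

    return F


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise StatsError("KS test needs non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), kind="ks")


def bootstrap_mean_diff_p(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Bootstrap difference-of-means p-value (two-tailed, null-centred).

    Resamples ``n_boot`` means from each sample, differences them
    pairwise, shifts the difference distribution to zero mean (the null),
    and reports the proportion at least as extreme as the observed mean
    difference.  When no resampled difference qualifies, the p-value is
    floored at 1/n_boot and flagged (reported as "<1e-05" downstream).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("bootstrap mean-difference test needs n >= 2 per sample")
    rng = np.random.default_rng(seed)
    # chunked to bound peak memory at large n_boot
    diffs = np.empty(n_boot)
    chunk = max(1, int(5e6 // max(a.size, b.size)))
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        ia = rng.integers(0, a.size, size=(stop - start, a.size))
        ib = rng.integers(0, b.size, size=(stop - start, b.size))
        diffs[start:stop] = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    diffs -= diffs.mean()
    observed = abs(a.mean() - b.mean())
    n_exceed = int(np.count_nonzero(np.abs(diffs) >= observed))
    if n_exceed == 0:
        return TestResult(
            statistic=float(a.mean() - b.mean()),
            p_value=1.0 / n_boot,
            kind="boot_mean_diff",
            floor_flag=True,
        )
    return TestResult(
        statistic=float(a.mean() - b.mean()),
        p_value=n_exceed / n_boot,
        kind="boot_mean_diff",
    )
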