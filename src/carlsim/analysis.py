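"""Derived statistics: performance, Q-value gaps, behavior profiles, KDE
peak/regime detection, polarization, crossing points, and optimal bias."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .environment import ARM_BEST, ARM_WORST, BanditTask, expected_random_performance
from .simulation import SimulationResult

__all__ = [
    "PerformanceSummary",
    "PolarizationSummary",
    "RegimeSummary",
    "behavior_profile",
    "intersection_group_size",
    "kde_peaks",
    "mean_behavior_profile",
    "optimal_bias",
    "performance",
    "polarization",
    "qgap",
]

#: Minimum sample count for a meaningful KDE.
MIN_KDE_SAMPLES = 50

#: Histogram bin count used for distribution outputs.
DEFAULT_BINS = 50


@dataclass(frozen=True)
class PerformanceSummary:
    """Mean collected payoff per agent per trial plus derived quantities."""

    mean_payoff: float
    ci95: float
    focal_mean: float
    improvement: float
    n_sims: int


@dataclass(frozen=True)
class RegimeSummary:
    """KDE local maxima of a final-gap distribution, sorted by location."""

    peak_locations: np.ndarray
    peak_heights: np.ndarray
    relative_heights: np.ndarray
    bandwidth: float

    @property
    def n_peaks(self) -> int:
        return len(self.peak_locations)


@dataclass(frozen=True)
class PolarizationSummary:
    """Per-replicate differences between two agents' final Q-value gaps."""

    gap_differences: np.ndarray
    pair: tuple[int, int]


def performance(
    results: list[SimulationResult],
    task: BanditTask,
    window: tuple[int, int] | None = None,
) -> PerformanceSummary:
    """Average payoffs over agents, trials in ``window``, and replicates.

    ``window`` is a 1-based inclusive trial range, e.g. ``(101, 200)`` for
    the last 100 of 200 trials; ``None`` means all trials. The 95% CI is a
    normal approximation over the distribution of replicate means.
    """
    if not results:
        raise ValueError("results batch is empty")
    trials = results[0].payoffs.shape[0]
    if window is None:
        lo, hi = 1, trials
    else:
        lo, hi = window
    if not 1 <= lo <= hi <= trials:
        raise ValueError(f"window {window!r} invalid for {trials} trials")
    sl = slice(lo - 1, hi)
    rep_means = np.array([r.payoffs[sl].mean() for r in results])
    focal_means = np.array([r.payoffs[sl, 0].mean() for r in results])
    mean = float(rep_means.mean())
    se = rep_means.std(ddof=1) / np.sqrt(len(results)) if len(results) > 1 else 0.0
    return PerformanceSummary(
        mean_payoff=mean,
        ci95=float(1.96 * se),
        focal_mean=float(focal_means.mean()),
        improvement=mean - expected_random_performance(task),
        n_sims=len(results),
    )


def qgap(final_q: np.ndarray, agent: int = 0) -> float:
    """Final Q-value gap ``Q(best arm) − Q(worst arm)`` for one agent.

    Negative values mean the agent values the objectively worse arm higher.
    """
    final_q = np.asarray(final_q)
    if not 0 <= agent < final_q.shape[0]:
        raise ValueError(f"agent index {agent} out of range")
    return float(final_q[agent, ARM_BEST] - final_q[agent, ARM_WORST])


def behavior_profile(gap: float | np.ndarray, beta: float) -> float | np.ndarray:
    """Probability of choosing the best arm given a Q-value gap: logistic(β·ΔQ)."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    z = np.clip(beta * np.asarray(gap, dtype=float), -500.0, 500.0)
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def mean_behavior_profile(gaps: np.ndarray, beta: float) -> float:
    """Mean of the per-replicate behavior profiles (softmax applied per
    data point, *then* averaged — not softmax of the mean gap)."""
    return float(np.mean(behavior_profile(np.asarray(gaps), beta)))


def kde_peaks(
    samples: np.ndarray,
    bw_method: str | float = "scott",
    grid_size: int = 1024,
    min_relative_height: float = 0.05,
    support: tuple[float, float] = (-2.0, 2.0),
) -> RegimeSummary:
    """Locate the local maxima of a Gaussian KDE of ``samples``.

    The KDE is evaluated on a fixed grid over ``[support[0]−3h,
    support[1]+3h]`` (h = Scott's-rule bandwidth by default). The default
    support spans [−2, 2], the full range of a Q-value gap or of a
    difference of gaps. Maxima are grid points strictly above both
    neighbors; those below ``min_relative_height`` of the global maximum
    are discarded — with ~10³ samples, tail bumps a few percent of the
    main mode's density are sampling noise, not regimes.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < MIN_KDE_SAMPLES:
        raise ValueError(
            f"need at least {MIN_KDE_SAMPLES} samples for KDE, got {samples.size}"
        )
    if np.ptp(samples) == 0.0:
        # degenerate point mass (e.g. unbiased agents never diverge): one peak
        return RegimeSummary(
            peak_locations=np.array([samples[0]]),
            peak_heights=np.array([np.inf]),
            relative_heights=np.array([1.0]),
            bandwidth=0.0,
        )
    kde = gaussian_kde(samples, bw_method=bw_method)
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(support[0] - 3 * h, support[1] + 3 * h, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    idx = np.flatnonzero(interior) + 1
    if idx.size:
        keep = dens[idx] >= min_relative_height * dens[idx].max()
        idx = idx[keep]
    locs = grid[idx]
    heights = dens[idx]
    order = np.argsort(locs)
    locs, heights = locs[order], heights[order]
    rel = heights / heights.max() if heights.size else heights
    return RegimeSummary(
        peak_locations=locs,
        peak_heights=heights,
        relative_heights=rel,
        bandwidth=h,
    )


def polarization(
    results: list[SimulationResult], focal: int = 0, other: int = 1
) -> PolarizationSummary:
    """Per-replicate difference between two agents' final Q-value gaps.

    Consensus shows as a single mode at 0; polarization as off-zero modes
    (probe with :func:`kde_peaks` on ``gap_differences`` with support
    ``(-2, 2)``).
    """
    if not results:
        raise ValueError("results batch is empty")
    n = results[0].final_q.shape[0]
    if n < 2:
        raise ValueError("polarization needs a group of at least 2 agents")
    for idx in (focal, other):
        if not 0 <= idx < n:
            raise ValueError(f"agent index {idx} out of range for group of {n}")
    diffs = np.array([qgap(r.final_q, focal) - qgap(r.final_q, other) for r in results])
    return PolarizationSummary(gap_differences=diffs, pair=(focal, other))


def intersection_group_size(
    curve_biased: np.ndarray,
    curve_unbiased: np.ndarray,
    group_sizes: np.ndarray,
) -> int | None:
    """Smallest group size at which the biased curve meets or exceeds the
    unbiased one; ``None`` if it never does on the grid."""
    curve_biased = np.asarray(curve_biased, dtype=float)
    curve_unbiased = np.asarray(curve_unbiased, dtype=float)
    group_sizes = np.asarray(group_sizes)
    if not curve_biased.shape == curve_unbiased.shape == group_sizes.shape:
        raise ValueError("curves and group-size grid must have equal shape")
    hits = np.flatnonzero(curve_biased >= curve_unbiased)
    return int(group_sizes[hits[0]]) if hits.size else None


def optimal_bias(bias_grid: np.ndarray, mean_profiles: np.ndarray) -> float:
    """Grid bias strength maximizing the mean behavior profile."""
    bias_grid = np.asarray(bias_grid, dtype=float)
    mean_profiles = np.asarray(mean_profiles, dtype=float)
    if bias_grid.shape != mean_profiles.shape or bias_grid.size < 3:
        raise ValueError("need matching grids with at least 3 bias values")
    return float(bias_grid[np.argmax(mean_profiles)])
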