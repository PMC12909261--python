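"""Penalized change-point detection on short 1-D series.

Detects shifts in the root-mean-square level of a signal by exact penalized
optimal partitioning: the series is split into contiguous segments, each
segment pays a goodness-of-fit cost, and every additional change point pays a
fixed penalty ``min_threshold``.  A split is accepted only when it *strictly*
lowers the penalized objective, so ``min_threshold`` acts as the minimum cost
improvement a change point must buy.

Two segment statistics are supported:

``rms``
    ``L * log(max(eps, mean(x^2)))`` for a segment of length ``L`` — the
    log-likelihood cost for a change in scale about zero, the standard
    formulation for detecting shifts in RMS level.
``mean``
    Sum of squared residuals about the segment mean.

The series here are longitudinal tumor volumes (typically 4–30 scans), so the
solver is a plain O(n^2) dynamic program with no pruning, and an exhaustive
enumeration oracle (:func:`oracle_detect`) is provided for verification on
short inputs.

The online wrapper :func:`detect_online` reruns the offline detector on each
growing prefix of the series and reports the first prefix at which a change
point appears — mimicking real-time accrual of scans, where only measurements
taken before the current date are available.

Indices are 1-based throughout; a change point is the index of the FIRST
sample of the new segment (``[1,1,1,1,8,8,8,8]`` -> change point 5).

The minimum spacing ``min_distance`` applies to every segment that is closed
on the right by a change point — the initial segment and any segment between
two change points must contain at least ``min_distance`` samples.  The final
segment is exempt: in online use it is still accruing samples, so a change
may be declared at the newest scan before ``min_distance`` post-change
samples exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChangePointConfig",
    "ChangePointResult",
    "OnlineDetection",
    "segment_cost",
    "detect_offline",
    "detect_online",
    "oracle_detect",
]

#: relative tolerance under which two penalized costs are considered tied
_COST_RTOL = 1e-9

_STATISTICS = ("rms", "mean")

#: exhaustive enumeration cap for :func:`oracle_detect`
_ORACLE_MAX_N = 16


@dataclass(frozen=True)
class ChangePointConfig:
    """Detector parameters.

    Parameters
    ----------
    statistic:
        Segment cost statistic, ``"rms"`` (default) or ``"mean"``.
    min_threshold:
        Penalty added to the objective per change point; a split must improve
        the total segment cost by more than this amount to be reported.
    min_distance:
        Minimum number of samples per segment (equivalently, minimum spacing
        between consecutive change points and the series boundaries).
        Default 2.
    epsilon:
        Floor applied to the mean square inside the log for the ``rms``
        statistic, guarding all-zero segments.
    """

    statistic: str = "rms"
    min_threshold: float = 0.05
    min_distance: int = 2
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}; expected one of {_STATISTICS}")
        if not self.min_threshold > 0:
            raise ValueError("min_threshold (change-point penalty) must be > 0")
        if int(self.min_distance) != self.min_distance or self.min_distance < 1:
            raise ValueError("min_distance must be an integer >= 1")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class ChangePointResult:
    """Outcome of an offline detection run.

    ``changepoints`` are sorted 1-based indices, each the first sample of a
    new segment.  ``total_cost`` is the penalized objective of the returned
    partition: ``sum(segment_costs) + min_threshold * len(changepoints)``.
    """

    changepoints: list[int]
    total_cost: float
    segment_costs: list[float]
    n: int

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Inclusive 1-based (start, end) bounds of each segment."""
        bounds = [1, *self.changepoints, self.n + 1]
        return [(bounds[k], bounds[k + 1] - 1) for k in range(len(bounds) - 1)]


@dataclass
class OnlineDetection:
    """Outcome of the prefix-by-prefix online wrapper.

    ``trigger_index`` is the length of the shortest prefix at which the
    offline detector first reports a change point (the "current scan" when
    the alarm fires); ``onset_index`` is the first change point of that
    prefix's partition.  ``prefix_results`` traces every evaluated prefix.
    """

    fired: bool
    trigger_index: int | None = None
    onset_index: int | None = None
    insufficient_data: bool = False
    prefix_results: dict[int, ChangePointResult] = field(default_factory=dict)


def segment_cost(
    x: np.ndarray | list[float],
    i: int,
    j: int,
    statistic: str = "rms",
    epsilon: float = 1e-12,
) -> float:
    """Cost of fitting ``x[i..j]`` (1-based, inclusive) as one segment."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if not (1 <= i <= j <= n):
        raise ValueError(f"empty or out-of-range segment [{i}, {j}] for series of length {n}")
    seg = x[i - 1 : j]
    L = seg.size
    if statistic == "rms":
        return L * math.log(max(epsilon, float(np.mean(seg**2))))
    if statistic == "mean":
        return float(np.sum((seg - seg.mean()) ** 2))
    raise ValueError(f"unknown statistic {statistic!r}")


def _cost_matrix(x: np.ndarray, statistic: str, epsilon: float) -> np.ndarray:
    """C[i, j] = cost of segment x[i..j] (1-based), via prefix sums."""
    n = x.size
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x**2)])
    C = np.full((n + 2, n + 2), np.nan)
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            L = j - i + 1
            ss = s2[j] - s2[i - 1]
            if statistic == "rms":
                C[i, j] = L * math.log(max(epsilon, ss / L))
            else:
                C[i, j] = ss - (s1[j] - s1[i - 1]) ** 2 / L
    return C


def _better(cost_a: float, cps_a: tuple[int, ...], cost_b: float, cps_b: tuple[int, ...]) -> bool:
    """True if partition a beats b: strictly lower cost, then fewer change
    points, then the lexicographically earlier change-point vector."""
    tol = _COST_RTOL * max(1.0, abs(cost_a), abs(cost_b))
    if cost_a < cost_b - tol:
        return True
    if cost_b < cost_a - tol:
        return False
    if len(cps_a) != len(cps_b):
        return len(cps_a) < len(cps_b)
    return cps_a < cps_b


def _result_from(
    x: np.ndarray, cps: tuple[int, ...], C: np.ndarray, penalty: float
) -> ChangePointResult:
    n = x.size
    bounds = [1, *cps, n + 1]
    seg_costs = [float(C[bounds[k], bounds[k + 1] - 1]) for k in range(len(bounds) - 1)]
    return ChangePointResult(
        changepoints=list(cps),
        total_cost=float(sum(seg_costs) + penalty * len(cps)),
        segment_costs=seg_costs,
        n=n,
    )


def detect_offline(x: np.ndarray | list[float], config: ChangePointConfig) -> ChangePointResult:
    """Exact penalized optimal partitioning of ``x``.

    Minimizes ``sum(segment costs) + min_threshold * (#change points)``
    subject to the spacing rule: the initial segment and every segment
    between consecutive change points contain at least ``min_distance``
    samples (the final, still-accruing segment is exempt).  Ties resolve
    toward fewer change points, then toward the earliest change-point
    vector; a change point is therefore reported only when it strictly
    improves the objective.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 1:
        raise ValueError("series must contain at least one sample")
    L = config.min_distance
    beta = config.min_threshold
    C = _cost_matrix(x, config.statistic, config.epsilon)

    # closed[j]: optimal penalized partition of x[1..j] given that a change
    # point sits at j+1, so the segment ending at j is closed and must
    # contain >= L samples; defined for j >= L.
    closed_cost: dict[int, float] = {}
    closed_cps: dict[int, tuple[int, ...]] = {}
    for j in range(L, n + 1):
        bc, bv = float(C[1, j]), ()
        for t in range(L, j - L + 1):
            cand_cost = closed_cost[t] + beta + float(C[t + 1, j])
            cand_cps = closed_cps[t] + (t + 1,)
            if _better(cand_cost, cand_cps, bc, bv):
                bc, bv = cand_cost, cand_cps
        closed_cost[j], closed_cps[j] = bc, bv

    # final segment: any length >= 1
    best_cost, best_cps = float(C[1, n]), ()
    for t in range(L, n):
        cand_cost = closed_cost[t] + beta + float(C[t + 1, n])
        cand_cps = closed_cps[t] + (t + 1,)
        if _better(cand_cost, cand_cps, best_cost, best_cps):
            best_cost, best_cps = cand_cost, cand_cps

    return _result_from(x, best_cps, C, beta)


def _admissible_vectors(n: int, min_distance: int) -> list[tuple[int, ...]]:
    """Every change-point vector satisfying the spacing rule: each change
    point lies at least ``min_distance`` past the start of the segment it
    terminates; the final segment may be arbitrarily short."""
    out: list[tuple[int, ...]] = [()]

    def extend(prefix: tuple[int, ...], seg_start: int) -> None:
        for c in range(seg_start + min_distance, n + 1):
            v = prefix + (c,)
            out.append(v)
            extend(v, c)

    extend((), 1)
    return out


def oracle_detect(x: np.ndarray | list[float], config: ChangePointConfig) -> ChangePointResult:
    """Brute-force reference detector: exhaustively enumerates every
    admissible partition and applies the identical tie-breaking rule.

    Independent of the dynamic program in :func:`detect_offline`; intended
    for verification on short series (n <= 16).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 1:
        raise ValueError("series must contain at least one sample")
    if n > _ORACLE_MAX_N:
        raise ValueError(f"oracle_detect enumerates exhaustively; n={n} exceeds cap {_ORACLE_MAX_N}")
    C = _cost_matrix(x, config.statistic, config.epsilon)
    beta = config.min_threshold

    best_cost: float | None = None
    best_cps: tuple[int, ...] = ()
    for cps in _admissible_vectors(n, config.min_distance):
        bounds = [1, *cps, n + 1]
        cost = sum(float(C[bounds[k], bounds[k + 1] - 1]) for k in range(len(bounds) - 1))
        cost += beta * len(cps)
        if best_cost is None or _better(cost, cps, best_cost, best_cps):
            best_cost, best_cps = cost, cps
    return _result_from(x, best_cps, C, beta)


def _first_upward_changepoint(x: np.ndarray, res: ChangePointResult) -> int | None:
    """First change point whose segment level rises above the preceding
    segment's (levels compared as root mean square)."""
    segs = res.segments
    for k, c in enumerate(res.changepoints):
        i0, j0 = segs[k]
        i1, j1 = segs[k + 1]
        prev_level = float(np.mean(x[i0 - 1 : j0] ** 2))
        new_level = float(np.mean(x[i1 - 1 : j1] ** 2))
        if new_level > prev_level:
            return c
    return None


def detect_online(
    x: np.ndarray | list[float],
    config: ChangePointConfig,
    start_prefix: int | None = None,
    require_increase: bool = False,
) -> OnlineDetection:
    """Run :func:`detect_offline` on each growing prefix of ``x``.

    Prefixes of length ``start_prefix`` (default ``2 * min_distance``)
    through ``n`` are evaluated in order; the alarm fires at the first prefix
    whose partition contains a change point.  A series shorter than
    ``start_prefix`` yields ``fired=False`` with ``insufficient_data=True``
    rather than an exception.

    With ``require_increase=True`` the alarm only fires on an upward level
    shift — the first change point in a prefix whose new segment has a
    higher RMS level than the segment before it.  Downward shifts (for
    tumor volumes: shrinkage, not growth) are ignored and scanning
    continues with the next prefix.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if start_prefix is None:
        start_prefix = 2 * config.min_distance
    if start_prefix < 2 * config.min_distance:
        raise ValueError(
            f"start_prefix={start_prefix} below the shortest splittable prefix "
            f"2*min_distance={2 * config.min_distance}"
        )
    if n < start_prefix:
        return OnlineDetection(fired=False, insufficient_data=True)

    trace: dict[int, ChangePointResult] = {}
    for k in range(start_prefix, n + 1):
        res = detect_offline(x[:k], config)
        trace[k] = res
        if res.changepoints:
            if require_increase:
                onset = _first_upward_changepoint(x[:k], res)
                if onset is None:
                    continue
            else:
                onset = res.changepoints[0]
            return OnlineDetection(
                fired=True,
                trigger_index=k,
                onset_index=onset,
                prefix_results=trace,
            )
    return OnlineDetection(fired=False, prefix_results=trace)
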