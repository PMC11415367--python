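"""The core enrichment statistic: threshold split, rank-sum test, sweep, knee.

For a candidate VAF threshold the cohort's distinct genomic positions
are partitioned into an upper group (max VAF at or above the threshold
in at least one patient) and a lower group (the rest).  Repository
recurrence counts of the two groups are compared with a two-sided
Wilcoxon rank-sum test; sweeping the threshold over a grid yields a
p-value curve whose knee is proposed as the limit of detection.

The rank test uses midranks throughout.  For small combined sample
sizes the null is enumerated exactly — including ties — by dynamic
programming over half-integer ranks; larger samples use the
tie-corrected normal approximation (no continuity correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_calls import CohortPositionTable
from .resources import FrequencyMap, PositionSet

P_FLOOR = 1e-300  #: reported p-values are floored here; treat as "p < floor"
DEFAULT_EXACT_CAP = 20


@dataclass(frozen=True)
class ThresholdSplit:
    """Partition of cohort positions at one VAF threshold."""

    threshold: float
    above: PositionSet
    below: PositionSet


def split_at_threshold(
    table: CohortPositionTable, threshold: float, boundary: str = "closed"
) -> ThresholdSplit:
    """Split cohort positions by per-position max VAF.

    ``boundary="closed"`` (default) puts max_vaf == threshold in the
    upper group (max_vaf >= t); ``"open"`` uses a strict inequality.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if boundary not in ("closed", "open"):
        raise ValueError("boundary must be 'closed' or 'open'")
    df = table.df
    if boundary == "closed":
        mask = df["max_vaf"].to_numpy() >= threshold
    else:
        mask = df["max_vaf"].to_numpy() > threshold
    pairs = np.array(list(zip(df["chrom"], df["pos"])), dtype=object)
    above = frozenset((c, int(p)) for c, p in pairs[mask])
    below = frozenset((c, int(p)) for c, p in pairs[~mask])
    return ThresholdSplit(
        threshold=threshold,
        above=PositionSet(above, name=f"above_{threshold:g}"),
        below=PositionSet(below, name=f"below_{threshold:g}"),
    )


def _exact_ranksum_p(ranks2: np.ndarray, nx: int, w2_obs: int) -> float:
    """Exact two-sided p for the rank-sum statistic under the permutation null.

    ``ranks2`` are midranks doubled (integers); ``w2_obs`` the doubled
    observed rank sum of the first group.  Counts, via subset-sum DP,
    the number of size-``nx`` subsets whose doubled rank sum is at
    least as far from the null mean as observed.
    """
    n = len(ranks2)
    total2 = int(ranks2.sum())
    # dp[k, s]: number of size-k subsets with doubled-rank sum s
    dp = np.zeros((nx + 1, total2 + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        # iterate k downwards so each rank is used once
        for k in range(min(nx, 1_000_000), 0, -1):
            if k > nx:
                continue
            dp[k, r:] += dp[k - 1, : total2 + 1 - r]
    dist = dp[nx]
    n_subsets = dist.sum()
    mean2 = nx * total2 / n  # doubled null mean of the rank sum
    d_obs = abs(w2_obs - mean2) - 1e-9  # guard float fuzz on equality
    sums = np.arange(total2 + 1, dtype=float)
    extreme = dist[np.abs(sums - mean2) >= d_obs].sum()
    return float(extreme / n_subsets)


def rank_sum_test(
    scores_above: Sequence[float],
    scores_below: Sequence[float],
    exact_cap: int = DEFAULT_EXACT_CAP,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the midrank sum of the first group.
    Combined sizes up to ``exact_cap`` are handled by exact tie-aware
    enumeration; beyond that the tie-corrected normal approximation is
    used.  All-tied inputs give p = 1.
    """
    x = np.asarray(scores_above, dtype=float)
    y = np.asarray(scores_below, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = len(x), len(y)
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks
    w = float(ranks[:nx].sum())

    if np.all(combined == combined[0]):
        return w, 1.0

    if n <= exact_cap:
        ranks2 = np.rint(ranks * 2).astype(int)
        p = _exact_ranksum_p(ranks2, nx, int(round(w * 2)))
        return w, min(max(p, P_FLOOR), 1.0)

    # tie-corrected normal approximation
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    z = (w - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return w, float(min(max(p, P_FLOOR), 1.0))


@dataclass
class SweepResult:
    """Per-threshold group sizes and test results.

    ``df`` columns: threshold, n_above, n_below, statistic, p_value,
    tested.  Thresholds where one group is empty are kept with
    ``tested=False`` and NaN statistics.
    """

    df: pd.DataFrame = field(repr=False)
    boundary: str = "closed"
    source_name: str = "repository"

    def tested(self) -> pd.DataFrame:
        return self.df[self.df["tested"]].reset_index(drop=True)


def threshold_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid, rounded to avoid float drift."""
    if not (hi > lo and step > 0):
        raise ValueError("need hi > lo and step > 0")
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


DEFAULT_GRID = threshold_grid(0.002, 0.008, 0.0005)


def sweep(
    table: CohortPositionTable,
    fmap: FrequencyMap,
    thresholds: Sequence[float] | None = None,
    boundary: str = "closed",
    exact_cap: int = DEFAULT_EXACT_CAP,
) -> SweepResult:
    """Run the rank-sum comparison at every threshold of the grid.

    The scores entering the test are raw repository counts; the rank
    test is invariant to the monotone log2(x+1) display transform.
    """
    grid = DEFAULT_GRID if thresholds is None else np.asarray(thresholds, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    df = table.df
    max_vaf = df["max_vaf"].to_numpy()
    counts = fmap.counts_for(zip(df["chrom"], df["pos"]))
    rows = []
    for t in grid:
        mask = max_vaf >= t if boundary == "closed" else max_vaf > t
        n_above = int(mask.sum())
        n_below = int(len(df) - n_above)
        if n_above == 0 or n_below == 0:
            rows.append((t, n_above, n_below, np.nan, np.nan, False))
            continue
        w, p = rank_sum_test(counts[mask], counts[~mask], exact_cap=exact_cap)
        rows.append((t, n_above, n_below, w, p, True))
    out = pd.DataFrame(
        rows, columns=["threshold", "n_above", "n_below", "statistic", "p_value", "tested"]
    )
    return SweepResult(df=out, boundary=boundary, source_name=fmap.source_name)


@dataclass
class KneeEstimate:
    """Proposed limit of detection from the p-value curve."""

    knee_threshold: float
    method: str
    curve: pd.DataFrame = field(repr=False)
    low_confidence: bool = False
    max_distance: float = 0.0


def detect_knee(
    sweep_result: SweepResult,
    method: str = "chord",
    min_distance: float = 0.05,
) -> KneeEstimate:
    """Locate the knee of the -log10(p) vs threshold curve.

    ``"chord"`` (Kneedle-style, default): both axes are normalised to
    [0, 1] and the knee is the point of maximum perpendicular distance
    from the chord joining the curve's endpoints.  ``"second-diff"``
    picks the maximum discrete second difference instead.  A nearly
    straight curve (max distance below ``min_distance`` in normalised
    units) is flagged low-confidence.
    """
    if method not in ("chord", "second-diff"):
        raise ValueError("method must be 'chord' or 'second-diff'")
    curve = sweep_result.tested()[["threshold", "p_value"]].copy()
    if len(curve) < 4:
        raise ValueError(f"knee detection needs >= 4 tested points, got {len(curve)}")
    t = curve["threshold"].to_numpy()
    y = -np.log10(np.clip(curve["p_value"].to_numpy(), P_FLOOR, 1.0))
    curve["neg_log10_p"] = y

    t_span = t[-1] - t[0]
    y_span = y.max() - y.min()
    tn = (t - t[0]) / t_span
    if y_span == 0:
        return KneeEstimate(
            knee_threshold=float(t[0]),
            method=method,
            curve=curve,
            low_confidence=True,
            max_distance=0.0,
        )
    yn = (y - y.min()) / y_span

    if method == "chord":
        # perpendicular distance from chord (tn[0],yn[0]) -> (tn[-1],yn[-1])
        dx, dy = tn[-1] - tn[0], yn[-1] - yn[0]
        norm = math.hypot(dx, dy)
        dist = np.abs(dy * (tn - tn[0]) - dx * (yn - yn[0])) / norm
        idx = int(np.argmax(dist))
        score = float(dist[idx])
    else:
        d2 = np.abs(np.diff(yn, 2))
        idx = int(np.argmax(d2)) + 1
        score = float(d2.max())
    return KneeEstimate(
        knee_threshold=float(t[idx]),
        method=method,
        curve=curve,
        low_confidence=score < min_distance,
        max_distance=score,
    )
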