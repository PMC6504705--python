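"""Growth analysis for serial re-plating experiments.

Each re-plating interval starts from a known inoculum (~1,000 cells) and
ends at an OD750 harvest reading; an OD-per-cell calibration converts the
reading to a cell count, giving a per-interval doubling time

    Td = dt * ln(2) / ln(N_end / N_start).

Condition differences are tested with the Wilcoxon rank-sum test and
temporal trends with the Jonckheere–Terpstra test (not available in
scipy/statsmodels, implemented here with a normal approximation, a
tie-corrected variance, and exhaustive or Monte-Carlo permutation for
small samples). Growth "rate" is reported in two conventions, doublings
per day (1/Td) and the exponential rate ln(2)/Td per day, because the two
are easy to conflate.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Doubling time
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSeries:
    """Ordered re-plating events of one condition."""

    condition: str
    days: tuple[float, ...]          # harvest day of each event, from day 0
    od750: tuple[float, ...]
    inoculum: tuple[float, ...]      # cells streaked at the start of each interval

    def __post_init__(self) -> None:
        n = len(self.days)
        if not (n == len(self.od750) == len(self.inoculum)):
            raise ValueError("days, od750 and inoculum must have equal length")
        if n == 0:
            raise ValueError("growth series needs at least one interval")
        if any(b <= a for a, b in zip(self.days, self.days[1:])) or self.days[0] <= 0:
            raise ValueError("days must be strictly increasing and positive")
        if any(od <= 0 for od in self.od750):
            raise ValueError("OD750 must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str) -> "GrowthSeries":
        sub = df[df["condition"] == condition].sort_values("day")
        return cls(condition, tuple(map(float, sub["day"])),
                   tuple(map(float, sub["od750"])),
                   tuple(map(float, sub["inoculum"])))


@dataclass
class DoublingTimeResult:
    condition: str
    interval_days: list[float]
    td: list[float]                      # per retained interval
    excluded: list[int] = field(default_factory=list)  # interval indices dropped
    mean_td: float = float("nan")
    mean_rate_doublings_per_day: float = float("nan")  # mean of 1/Td
    mean_rate_per_day: float = float("nan")            # mean of ln2/Td


def doubling_time(series: GrowthSeries, od_per_cell: float) -> DoublingTimeResult:
    """Per-interval and mean doubling times from OD calibration.

    Intervals where the harvested count does not exceed the inoculum are
    flagged, excluded and logged rather than producing negative times.
    """
    if od_per_cell <= 0:
        raise ValueError("od_per_cell must be positive")
    prev_day = 0.0
    dts, tds, excluded = [], [], []
    for i, (day, od, n0) in enumerate(zip(series.days, series.od750, series.inoculum)):
        dt = day - prev_day
        prev_day = day
        n_end = od / od_per_cell
        if n_end <= n0:
            log.warning("interval %d of %s: no net growth (N_end <= N_start), excluded",
                        i, series.condition)
            excluded.append(i)
            continue
        dts.append(dt)
        tds.append(dt * math.log(2) / math.log(n_end / n0))
    result = DoublingTimeResult(series.condition, dts, tds, excluded)
    if tds:
        arr = np.asarray(tds)
        result.mean_td = float(arr.mean())
        result.mean_rate_doublings_per_day = float((1.0 / arr).mean())
        result.mean_rate_per_day = float((math.log(2) / arr).mean())
    return result


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    method: str


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided") -> RankSumResult:
    """Mann–Whitney/Wilcoxon rank-sum: exact enumeration for combined
    n <= 20 without ties, otherwise a tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        # complete ties: the tie-corrected variance vanishes
        return RankSumResult(x.size * y.size / 2.0, 1.0, "degenerate")
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and combined.size <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue),
                         "normal-approx" if method == "asymptotic" else "exact")


# ---------------------------------------------------------------------------
# Jonckheere–Terpstra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendTestResult:
    statistic: float
    p_value: float
    method: str                     # 'normal-approx' | 'permutation'
    group_sizes: tuple[int, ...]


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    j = 0.0
    for gi, gj in itertools.combinations(groups, 2):
        diff = gj[None, :] - gi[:, None]
        j += np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(j)


def _jt_null_moments(group_sizes: Sequence[int],
                     pooled: np.ndarray) -> tuple[float, float]:
    n = int(sum(group_sizes))
    ni = np.asarray(group_sizes, dtype=float)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    mean = (n * n - np.sum(ni ** 2)) / 4.0
    term1 = (n * (n - 1) * (2 * n + 5)
             - np.sum(ni * (ni - 1) * (2 * ni + 5))
             - np.sum(t * (t - 1) * (2 * t + 5))) / 72.0
    term2 = (np.sum(ni * (ni - 1) * (ni - 2)) * np.sum(t * (t - 1) * (t - 2))
             / (36.0 * n * (n - 1) * (n - 2))) if n > 2 else 0.0
    term3 = (np.sum(ni * (ni - 1)) * np.sum(t * (t - 1))
             / (8.0 * n * (n - 1))) if n > 1 else 0.0
    return mean, term1 + term2 + term3


def _iter_group_assignments(pooled: np.ndarray, sizes: Sequence[int]):
    """Yield every distinct split of pooled indices into ordered groups."""
    idx = tuple(range(pooled.size))

    def rec(remaining: tuple[int, ...], sizes_left: Sequence[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo,) + tail

    yield from rec(idx, sizes)


def jonckheere_terpstra(groups: Sequence[Sequence[float]],
                        alternative: str = "increasing",
                        method: str = "auto",
                        n_permutations: int = 10_000,
                        seed: Optional[int] = None) -> TrendTestResult:
    """Test for a monotone trend across ordered groups.

    With two groups the statistic reduces to the Mann–Whitney U of the
    pair. ``method='auto'`` enumerates every permutation when the pooled
    sample size is <= 12, otherwise uses the tie-corrected normal
    approximation; ``method='permutation'`` forces a (seeded) Monte-Carlo
    permutation when exhaustive enumeration is infeasible.
    """
    if alternative not in {"increasing", "decreasing", "two-sided"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two ordered groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    sizes = tuple(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    n = pooled.size
    j_obs = _jt_statistic(arrays)

    if method == "auto":
        method = "permutation" if n <= 12 else "normal-approx"

    if method == "normal-approx":
        mean, var = _jt_null_moments(sizes, pooled)
        if var <= 0:
            return TrendTestResult(j_obs, 1.0, "normal-approx", sizes)
        z = (j_obs - mean) / math.sqrt(var)
        if alternative == "increasing":
            p = stats.norm.sf(z)
        elif alternative == "decreasing":
            p = stats.norm.cdf(z)
        else:
            p = 2 * stats.norm.sf(abs(z))
        return TrendTestResult(j_obs, float(min(p, 1.0)), "normal-approx", sizes)

    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    n_distinct = math.factorial(n)
    for s in sizes:
        n_distinct //= math.factorial(s)
    eps = 1e-9
    if n_distinct <= 200_000:
        count_ge = count_le = total = 0
        for assignment in _iter_group_assignments(pooled, sizes):
            perm_groups = [pooled[list(ix)] for ix in assignment]
            j = _jt_statistic(perm_groups)
            total += 1
            count_ge += j >= j_obs - eps
            count_le += j <= j_obs + eps
        p_inc = count_ge / total
        p_dec = count_le / total
    else:
        rng = np.random.default_rng(seed)
        count_ge = count_le = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            out = np.split(perm, np.cumsum(sizes)[:-1])
            j = _jt_statistic(out)
            count_ge += j >= j_obs - eps
            count_le += j <= j_obs + eps
        p_inc = (1 + count_ge) / (1 + n_permutations)
        p_dec = (1 + count_le) / (1 + n_permutations)
    if alternative == "increasing":
        p = p_inc
    elif alternative == "decreasing":
        p = p_dec
    else:
        p = min(1.0, 2 * min(p_inc, p_dec))
    return TrendTestResult(j_obs, float(p), "permutation", sizes)


# ---------------------------------------------------------------------------
# OLS trend
# ---------------------------------------------------------------------------

def ols_trend(t: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Least-squares slope and intercept of y on t."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need >= 2 paired observations")
    if np.ptp(t) == 0:
        raise ValueError("all time values equal; slope undefined")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept)


def read_growth_table(path) -> pd.DataFrame:
    """TSV with columns condition, day, od750, inoculum."""
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "day", "od750", "inoculum"}
    if not required <= set(df.columns):
        raise ValueError(f"growth table must have columns {sorted(required)}")
    return df
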