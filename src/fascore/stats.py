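"""Evaluation statistics: score-error summaries and the Jonckheere-Terpstra
ordered-alternative trend test.

The trend test asks whether Growth rates increase across clinician-ordered
severity groups (rank 1 "approximately the same" < rank 2 "slightly worse" <
rank 3 "much worse").  The statistic is the sum over ordered group pairs
(i < j) of Mann-Whitney counts

    JT = sum_{i<j} [ #(x_i < x_j) + 0.5 #(x_i = x_j) ].

For small samples the one-sided p-value is computed by exhaustive enumeration
of group-label arrangements; otherwise by normal approximation with
tie-corrected variance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Largest pooled sample size for which the exact permutation null is used.
EXACT_N = 10

#: Safety cap on the number of enumerated arrangements.
_MAX_ARRANGEMENTS = 300_000

#: Cache of exact null distributions keyed by (group sizes, pooled tie pattern).
_NULL_CACHE: Dict[Tuple, np.ndarray] = {}


class StatisticsError(ValueError):
    pass


class ErrorSummary(NamedTuple):
    mean: float
    sd: float
    n: int


class JTResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str  # "exact" | "normal"
    null_mean: float
    null_sd: float


@dataclass
class RankedGrowth:
    """One pair's Growth rate with its clinician severity rank (1, 2 or 3)."""

    growth_rate: float
    rank: int
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.rank not in (1, 2, 3):
            raise StatisticsError(f"rank must be 1, 2 or 3, got {self.rank}")


def error_summary(growth_rates: Sequence[float]) -> ErrorSummary:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    With fewer than two values the standard deviation is undefined (NaN).
    """
    arr = np.asarray(list(growth_rates), dtype=np.float64)
    if arr.size == 0:
        raise StatisticsError("error_summary needs at least one growth rate")
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    return ErrorSummary(mean=float(arr.mean()), sd=sd, n=int(arr.size))


def _jt_statistic(groups: List[np.ndarray]) -> float:
    jt = 0.0
    for i, j in itertools.combinations(range(len(groups)), 2):
        a, b = groups[i][:, None], groups[j][None, :]
        jt += float((a < b).sum()) + 0.5 * float((a == b).sum())
    return jt


def _null_moments(sizes: np.ndarray, pooled: np.ndarray) -> Tuple[float, float]:
    """Mean and tie-corrected variance of JT under the permutation null."""
    n = int(sizes.sum())
    mean = (n * n - (sizes**2).sum()) / 4.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(np.float64)
    s = sizes.astype(np.float64)
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - (s * (s - 1) * (2 * s + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    if n > 2:
        term2 = (
            (s * (s - 1) * (s - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
            / (36.0 * n * (n - 1) * (n - 2))
        )
    else:
        term2 = 0.0
    term3 = (s * (s - 1)).sum() * (t * (t - 1)).sum() / (8.0 * n * (n - 1))
    return float(mean), float(term1 + term2 + term3)


def _n_arrangements(sizes: Sequence[int]) -> int:
    total = int(sum(sizes))
    count = 1
    remaining = total
    for s in sizes:
        count *= math.comb(remaining, s)
        remaining -= s
    return count


from functools import lru_cache


@lru_cache(maxsize=None)
def _mw_counts(m: int, n: int) -> Tuple[int, ...]:
    """Number of arrangements of m A's and n B's with #(A < B) = u, u = 0..m*n."""
    if m == 0 or n == 0:
        return (1,)
    shifted = _mw_counts(m - 1, n)  # the largest observation is an A: adds n
    plain = _mw_counts(m, n - 1)  # the largest observation is a B: adds 0
    out = [0] * (m * n + 1)
    for u, c in enumerate(shifted):
        out[u + n] += c
    for u, c in enumerate(plain):
        out[u] += c
    return tuple(out)


def _exact_null(sizes: Tuple[int, ...], pooled_sorted: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(support, probabilities) of JT over every distinct assignment.

    Without ties JT decomposes into independent Mann-Whitney statistics
    U(n_1 + .. + n_{j-1}, n_j), so the null pmf is their convolution.  With
    ties the assignments are enumerated explicitly.  The distribution depends
    only on the group sizes and the tie pattern of the pooled sample, so it
    is cached on those.
    """
    _, tie_counts = np.unique(pooled_sorted, return_counts=True)
    key = (sizes, tuple(tie_counts.tolist()))
    hit = _NULL_CACHE.get(key)
    if hit is not None:
        return hit

    n = int(sum(sizes))
    if len(tie_counts) == n:  # all values distinct: convolve MW counts
        pmf = np.array([1.0])
        before = 0
        for size in sizes:
            if before:
                pmf = np.convolve(pmf, np.asarray(_mw_counts(before, size), dtype=np.float64))
            before += size
        support = np.arange(pmf.size, dtype=np.float64)
        probs = pmf / pmf.sum()
    else:
        if _n_arrangements(sizes) > _MAX_ARRANGEMENTS:
            raise StatisticsError("exact enumeration too large; use method='normal'")
        from scipy.stats import rankdata

        x = rankdata(pooled_sorted)
        less = (x[:, None] < x[None, :]).astype(np.float64)
        less += 0.5 * ((x[:, None] == x[None, :]) & ~np.eye(n, dtype=bool))

        def assignments(pool: Tuple[int, ...], remaining: Tuple[int, ...]):
            if not remaining:
                yield ()
                return
            for combo in itertools.combinations(pool, remaining[0]):
                rest = tuple(i for i in pool if i not in combo)
                for tail in assignments(rest, remaining[1:]):
                    yield (combo,) + tail

        values = []
        for groups_idx in assignments(tuple(range(n)), sizes):
            jt = 0.0
            for gi, gj in itertools.combinations(range(len(sizes)), 2):
                jt += less[np.ix_(groups_idx[gi], groups_idx[gj])].sum()
            values.append(jt)
        support, counts = np.unique(np.asarray(values), return_counts=True)
        probs = counts / counts.sum()
    _NULL_CACHE[key] = (support, probs)
    return support, probs


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]],
    alternative: str = "increasing",
    method: str = "auto",
    continuity_correction: bool = False,
) -> JTResult:
    """Jonckheere-Terpstra trend test over ordered groups.

    Parameters
    ----------
    groups : samples in their hypothesised order (e.g. rank 1, 2, 3).
    alternative : ``"increasing"`` (one-sided, values rise with group order)
        or ``"decreasing"``.
    method : ``"exact"`` (exhaustive permutation), ``"normal"``
        (tie-corrected normal approximation), or ``"auto"`` (exact when the
        pooled n <= 10).
    continuity_correction : subtract 0.5 from the statistic in the normal
        approximation; off by default, useful at small n where the null is
        coarsely discrete.
    """
    arrs = [np.asarray(list(g), dtype=np.float64) for g in groups]
    if len(arrs) < 2 or any(a.size == 0 for a in arrs):
        raise StatisticsError("need >= 2 non-empty ordered groups")
    if alternative not in ("increasing", "decreasing"):
        raise StatisticsError(f"unknown alternative {alternative!r}")
    if alternative == "decreasing":
        arrs = list(reversed(arrs))

    sizes = np.array([a.size for a in arrs])
    pooled = np.concatenate(arrs)
    jt = _jt_statistic(arrs)
    mean, var = _null_moments(sizes, pooled)
    sd = math.sqrt(var) if var > 0 else 0.0

    use_exact = method == "exact" or (method == "auto" and pooled.size <= EXACT_N)
    if use_exact:
        support, probs = _exact_null(tuple(int(s) for s in sizes), np.sort(pooled))
        # one-sided: P(JT >= observed); guard rounding with a half-step slack
        p = float(probs[support >= jt - 1e-9].sum())
        return JTResult(jt, p, "exact", mean, sd)

    if sd == 0.0:
        return JTResult(jt, 1.0 if jt <= mean else 0.0, "normal", mean, sd)
    from scipy.stats import norm

    z = (jt - (0.5 if continuity_correction else 0.0) - mean) / sd
    return JTResult(jt, float(norm.sf(z)), "normal", mean, sd)


def groups_from_ranked(ranked: Sequence[RankedGrowth]) -> List[List[float]]:
    """Split RankedGrowth records into ordered rank-1/2/3 samples."""
    out: List[List[float]] = [[], [], []]
    for r in ranked:
        out[r.rank - 1].append(r.growth_rate)
    return [g for g in out if g]


def jt_from_table(df: pd.DataFrame, alternative: str = "increasing",
                  method: str = "auto") -> dict:
    """Run the trend test on a table with ``growth_rate`` and ``rank`` columns.

    Returns a JSON-ready dict with the statistic, p-value and per-group
    summaries, matching the CSV/JSON surface of the command-line tool.
    """
    if not {"growth_rate", "rank"} <= set(df.columns):
        raise StatisticsError("table needs 'growth_rate' and 'rank' columns")
    ranks = sorted(df["rank"].unique())
    groups = [df.loc[df["rank"] == r, "growth_rate"].to_numpy() for r in ranks]
    res = jonckheere_terpstra(groups, alternative=alternative, method=method)
    return {
        "JT": res.statistic,
        "p": res.pvalue,
        "method": res.method,
        "alternative": alternative,
        "group_ranks": [int(r) for r in ranks],
        "group_ns": [int(len(g)) for g in groups],
        "group_means": [float(np.mean(g)) for g in groups],
        "group_sds": [float(np.std(g, ddof=1)) if len(g) > 1 else None for g in groups],
    }


def plot_rank_growth(df: pd.DataFrame, path) -> None:
    """Box + scatter plot of Growth rate by clinician rank."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranks = sorted(df["rank"].unique())
    data = [df.loc[df["rank"] == r, "growth_rate"].to_numpy() for r in ranks]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(data, positions=range(1, len(ranks) + 1), showfliers=False)
    rng = np.random.default_rng(0)
    for i, vals in enumerate(data, start=1):
        ax.scatter(i + rng.uniform(-0.08, 0.08, len(vals)), vals, s=12, alpha=0.7)
    ax.set_xticks(range(1, len(ranks) + 1))
    ax.set_xticklabels([f"Rank {r}" for r in ranks])
    ax.set_ylabel("Growth rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
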