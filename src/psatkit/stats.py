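"""Statistical layer: normality screening, rank-based multi-group
comparison with post hoc tests, rank correlation, and 1 deg binned median
maps.

Environmental properties and dive metrics from tag records are heavily
non-Gaussian, so the comparisons are rank-based throughout: a Lilliefors
test documents the non-normality, Kruskal-Wallis tests compare groups
(hotspots, seasons), and a Tukey-Kramer procedure on rank-transformed data
provides the pairwise post hocs. Groups with five or fewer observations
are dropped before testing. Spearman's rank correlation relates bin-level
medians of environmental properties to dive metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "lilliefors_test",
    "kruskal_wallis",
    "posthoc_tukey_ranks",
    "spearman",
    "binned_median_map",
    "apply_group_omission",
    "MIN_GROUP_N",
]

MIN_GROUP_N = 5  # groups with n <= 5 are omitted from tests


@dataclass
class TestResult:
    """Outcome of one statistical test: the statistic (chi-square-scale H
    for Kruskal-Wallis, rho for Spearman, D for Lilliefors), its p-value,
    and pairwise post hoc p-values where applicable."""

    name: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.pvalue) and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _lilliefors_stat(x: np.ndarray) -> float:
    """KS distance between the sample ECDF and a normal with estimated
    mean/sd (the Lilliefors statistic)."""
    x = np.sort(x)
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))


def lilliefors_test(
    x: np.ndarray, *, reps: int = 10_000, seed: int = 0
) -> TestResult:
    """Lilliefors normality test with a Monte-Carlo null.

    The null distribution of the statistic (KS with estimated parameters)
    is simulated with ``reps`` standard-normal samples of the same size,
    which reproduces identically across platforms for a fixed seed. The
    p-value uses the add-one estimator (never exactly 0).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("Lilliefors test needs n >= 5")
    if x.std(ddof=1) == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    d = _lilliefors_stat(x)
    rng = np.random.default_rng(seed)
    # vectorized null: all replicate samples at once
    sims = rng.standard_normal((reps, n))
    sims.sort(axis=1)
    z = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_null = np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n), axis=1)
    p = (1 + int(np.sum(d_null >= d))) / (reps + 1)
    return TestResult(name="lilliefors", statistic=d, pvalue=float(p))


def apply_group_omission(
    groups: dict[str, np.ndarray], *, min_n: int = MIN_GROUP_N
) -> dict[str, np.ndarray]:
    """Drop groups with ``min_n`` or fewer observations (n <= 5 by
    default), the omission rule applied before every multi-group test."""
    return {
        k: np.asarray(v, dtype=float)
        for k, v in groups.items()
        if len(v) > min_n
    }


def kruskal_wallis(
    groups: dict[str, np.ndarray], *, min_n: int = MIN_GROUP_N
) -> TestResult:
    """Kruskal-Wallis rank test across groups (tie-corrected H,
    chi-square p-value), after dropping small groups."""
    kept = apply_group_omission(groups, min_n=min_n)
    if len(kept) < 2:
        raise ValueError(
            f"need >= 2 groups with more than {min_n} observations, have {len(kept)}"
        )
    h, p = sps.kruskal(*kept.values())
    return TestResult(
        name="kruskal-wallis",
        statistic=float(h),
        pvalue=float(p),
        note=f"groups: {', '.join(kept)}",
    )


def posthoc_tukey_ranks(
    groups: dict[str, np.ndarray],
    *,
    min_n: int = MIN_GROUP_N,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise post hoc comparisons: Tukey-Kramer HSD on rank-transformed
    observations.

    The pooled data are replaced by their ranks (ties averaged) and the
    unequal-n Tukey HSD procedure is applied to the rank means — the usual
    companion to a Kruskal-Wallis test when an honestly-significant-
    difference family correction is wanted. Applies the same small-group
    omission rule as the omnibus test. Returns a tidy frame (group1,
    group2, p_adj, reject).
    """
    from itertools import combinations

    kept = apply_group_omission(groups, min_n=min_n)
    if len(kept) < 2:
        raise ValueError("need >= 2 groups after the omission rule")
    if any(len(v) < 2 for v in kept.values()):
        raise ValueError("every group needs n >= 2 for the post hoc")
    names = sorted(kept)
    sizes = np.array([len(kept[k]) for k in names])
    ranks = sps.rankdata(np.concatenate([kept[k] for k in names]))
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    means = np.array([r.mean() for r in split])
    k, big_n = len(names), int(sizes.sum())
    df_err = big_n - k
    mse = sum(((r - r.mean()) ** 2).sum() for r in split) / df_err
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(mse / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        q = abs(means[i] - means[j]) / se if se > 0 else 0.0
        p = float(sps.studentized_range.sf(q, k, df_err)) if se > 0 else 1.0
        p = min(max(p, 0.0), 1.0)
        rows.append(
            {"group1": names[i], "group2": names[j], "p_adj": p, "reject": p < alpha}
        )
    return pd.DataFrame(rows)


def spearman(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Spearman rank correlation with tie handling; p by the t
    approximation. Inputs are paired (typically 1-deg-bin medians of an
    environmental property and a dive metric)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 4:
        raise ValueError("Spearman correlation needs n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            name="spearman", statistic=np.nan, pvalue=np.nan,
            note="undefined: constant input",
        )
    rho, p = sps.spearmanr(x, y)
    return TestResult(name="spearman", statistic=float(rho), pvalue=float(p))


def binned_median_map(
    df: pd.DataFrame,
    value_col: str,
    *,
    lon_col: str = "lon",
    lat_col: str = "lat",
    bin_deg: float = 1.0,
) -> pd.DataFrame:
    """Median of ``value_col`` within 1 deg x 1 deg bins.

    Each observation must carry a daily position. Returns one row per
    occupied bin (lon_bin, lat_bin = lower edges, median, n); empty bins
    are absent.
    """
    d = df.dropna(subset=[value_col, lon_col, lat_col]).copy()
    d["lon_bin"] = np.floor(d[lon_col] / bin_deg) * bin_deg
    d["lat_bin"] = np.floor(d[lat_col] / bin_deg) * bin_deg
    out = (
        d.groupby(["lon_bin", "lat_bin"])[value_col]
        .agg(median="median", n="size")
        .reset_index()
    )
    return out
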