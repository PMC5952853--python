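"""WT-vs-KO summary statistics for equilibrium expression and decay rates.

Two orientations are fixed package-wide:

* equilibrium change  = KO/WT - 1  (de-repression raises KO expression);
* degradation change  = WT/KO - 1  (the miRNA raises the WT decay rate).

Two aggregation schemes mirror the difference between whole-cohort and
per-group analyses: ``change_of_medians`` compares the two group medians
(one number per cohort), while ``median_of_changes`` computes each
transcript's paired WT/KO change first and then takes the median (robust to
unpaired skew, used for the binary-group contrasts).  On skewed data the
two deliberately disagree.

Also here: empirical CDFs, the Wilcoxon rank-sum test (exact enumeration
for small groups), the densest point of an axis-aligned 2D Gaussian KDE,
and the rank selections (top expressed at t = 0; most/least stable).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decay_model import DecayFit, mode_1d
from .io_formats import ExpressionMatrix

ORIENTATIONS = ("equilibrium", "degradation")


@dataclass(frozen=True)
class ComparisonResult:
    """A named WT-vs-KO statistic."""

    statistic_name: str
    wt_value: float
    ko_value: float
    percent_change: float      # fraction, orientation in statistic_name
    p_value: float | None = None
    group_labels: tuple[str, str] | None = None
    n_per_group: tuple[int, int] | None = None


@dataclass(frozen=True)
class ModePoint2D:
    """Densest grid point of the 2D KDE (x = WT axis, y = KO axis)."""

    x: float
    y: float
    grid_n: int
    bandwidths: tuple[float, float]


def percent_change(numerator: float, denominator: float) -> float:
    """numerator/denominator - 1 (a fraction; multiply by 100 to print %)."""
    if denominator <= 0:
        raise ValueError("denominator must be strictly positive")
    return numerator / denominator - 1.0


def _oriented_change(wt: float, ko: float, orientation: str) -> float:
    if orientation == "equilibrium":
        return percent_change(ko, wt)
    if orientation == "degradation":
        return percent_change(wt, ko)
    raise ValueError(f"orientation must be one of {ORIENTATIONS}")


def change_of_medians(
    wt_values: Sequence[float],
    ko_values: Sequence[float],
    orientation: str,
    name: str = "change_of_medians",
) -> ComparisonResult:
    """Percent change between the two group medians (midpoint convention)."""
    wt = np.asarray(wt_values, dtype=float)
    ko = np.asarray(ko_values, dtype=float)
    if wt.size == 0 or ko.size == 0:
        raise ValueError("both samples must be non-empty")
    med_wt = float(np.median(wt))
    med_ko = float(np.median(ko))
    return ComparisonResult(
        statistic_name=f"{name}:{orientation}",
        wt_value=med_wt,
        ko_value=med_ko,
        percent_change=_oriented_change(med_wt, med_ko, orientation),
        n_per_group=(wt.size, ko.size),
    )


def per_pair_changes(
    wt_values: Sequence[float],
    ko_values: Sequence[float],
    orientation: str,
) -> np.ndarray:
    wt = np.asarray(wt_values, dtype=float)
    ko = np.asarray(ko_values, dtype=float)
    if wt.shape != ko.shape:
        raise ValueError("paired samples must have equal length")
    return np.array([_oriented_change(w, k, orientation)
                     for w, k in zip(wt, ko)])


def median_of_changes(
    wt_values: Sequence[float],
    ko_values: Sequence[float],
    orientation: str,
    name: str = "median_of_changes",
) -> ComparisonResult:
    """Median of the per-transcript paired changes."""
    changes = per_pair_changes(wt_values, ko_values, orientation)
    if changes.size == 0:
        raise ValueError("need at least one pair")
    wt = np.asarray(wt_values, dtype=float)
    ko = np.asarray(ko_values, dtype=float)
    return ComparisonResult(
        statistic_name=f"{name}:{orientation}",
        wt_value=float(np.median(wt)),
        ko_value=float(np.median(ko)),
        percent_change=float(np.median(changes)),
        n_per_group=(wt.size, ko.size),
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_n: int = 8,
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration (all C(n_a+n_b, n_a) rank assignments, midranks
    for ties) when both groups have <= ``exact_max_n`` observations;
    otherwise the tie- and continuity-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size <= exact_max_n and b.size <= exact_max_n:
        return _exact_rank_sum(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def _exact_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks under ties
    n_a = a.size
    n = pooled.size
    w_obs = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(n), n_a):
        total += 1
        w = float(ranks[list(idx)].sum())
        if abs(w - mu) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------
# empirical CDF
# ---------------------------------------------------------------------------

def ecdf(values: Sequence[float]) -> list[tuple[float, float]]:
    """Right-continuous step points (sorted unique value, cumulative
    fraction); the last fraction is 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ecdf of an empty sample")
    uniq, counts = np.unique(v, return_counts=True)
    frac = np.cumsum(counts) / v.size
    return list(zip(uniq.tolist(), frac.tolist()))


# ---------------------------------------------------------------------------
# 2D KDE mode
# ---------------------------------------------------------------------------

def kde2d_mode(
    points: Sequence[tuple[float, float]] | np.ndarray,
    grid_n: int = 100,
) -> ModePoint2D:
    """Densest point of an axis-aligned bivariate normal KDE.

    Density is evaluated on a ``grid_n`` x ``grid_n`` grid spanning the data
    extent with per-axis normal-reference bandwidths h_i = sigma_i n^(-1/6).
    Ties break to the lowest x, then lowest y.  Degenerate inputs (zero
    extent on an axis) fall back to the per-axis 1D mode.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("kde2d_mode needs >= 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if x.min() == x.max() or y.min() == y.max():
        mx = float(x[0]) if x.min() == x.max() else mode_1d(x)
        my = float(y[0]) if y.min() == y.max() else mode_1d(y)
        return ModePoint2D(mx, my, grid_n, (0.0, 0.0))
    hx = float(np.std(x, ddof=1)) * n ** (-1.0 / 6.0)
    hy = float(np.std(y, ddof=1)) * n ** (-1.0 / 6.0)
    gx = np.linspace(x.min(), x.max(), grid_n)
    gy = np.linspace(y.min(), y.max(), grid_n)
    # separable kernel: density(i,j) = sum_k Kx[i,k] * Ky[j,k]
    kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2)
    dens = kx @ ky.T  # (grid_n, grid_n): [ix, iy]
    ix, iy = np.unravel_index(np.argmax(dens), dens.shape)  # first = lowest x,y
    return ModePoint2D(float(gx[ix]), float(gy[iy]), grid_n, (hx, hy))


# ---------------------------------------------------------------------------
# rank selections
# ---------------------------------------------------------------------------

def top_expressed(matrix: ExpressionMatrix, n: int = 4500) -> set[str]:
    """Top n transcripts by mean normalized FPKM at t = 0 in the WT
    background; ties break lexicographically."""
    if n > len(matrix.transcript_ids):
        raise ValueError(f"n={n} exceeds {len(matrix.transcript_ids)} transcripts")
    cols = matrix.sample_ids(genotype="WT", time_h=0.0)
    if not cols:
        raise ValueError("no WT t=0 samples")
    means = matrix.values[cols].mean(axis=1)
    order = sorted(means.index, key=lambda t: (-means[t], t))
    return set(order[:n])


def extremes_by_stability(
    fits: Iterable[DecayFit] | dict[str, DecayFit],
    n: int = 200,
) -> tuple[set[str], set[str]]:
    """(most_stable, least_stable): the n smallest-D and n largest-D
    transcripts, typically from the WT background."""
    fit_list = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if 2 * n > len(fit_list):
        raise ValueError(f"2n={2*n} exceeds {len(fit_list)} fits")
    order = sorted(fit_list, key=lambda f: (f.D, f.transcript_id))
    most_stable = {f.transcript_id for f in order[:n]}
    least_stable = {f.transcript_id for f in order[-n:]}
    return most_stable, least_stable


def comparison_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "statistic": r.statistic_name,
                "wt_value": r.wt_value,
                "ko_value": r.ko_value,
                "percent_change": r.percent_change,
                "p_value": r.p_value if r.p_value is not None else np.nan,
                "group_a": r.group_labels[0] if r.group_labels else "",
                "group_b": r.group_labels[1] if r.group_labels else "",
                "n_a": r.n_per_group[0] if r.n_per_group else np.nan,
                "n_b": r.n_per_group[1] if r.n_per_group else np.nan,
            }
        )
    return pd.DataFrame(rows)
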