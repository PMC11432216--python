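"""Descriptive statistics and hypothesis tests for peptide features.

Class-conditional binning (bar-plot data), QQ-plot points, the
Shapiro–Wilk normality test, and the two-sided Wilcoxon rank-sum
comparison between the two diabetes-type classes.  None of the features is
expected to be normal, which is exactly what the Shapiro–Wilk stage
establishes before the non-parametric rank-sum test is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

#: p-values below this floor are displayed as "<2.2e-16" in table output,
#: matching the conventional R print floor.
P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def bin_by_class(values, labels, breaks) -> pd.DataFrame:
    """Per-bin class counts with left-open/right-closed intervals.

    Values outside every interval are collected in ``underflow``/
    ``overflow`` rows with a warning.  Returns a DataFrame indexed by
    interval label with one count column per class.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    breaks = np.asarray(breaks, dtype=float)
    if values.shape != labels.shape:
        raise ValueError("values and labels differ in length")
    if len(breaks) < 2 or (np.diff(breaks) <= 0).any():
        raise ValueError("breaks must be strictly increasing, length >= 2")
    interval_names = [f"({breaks[i]:g}, {breaks[i+1]:g}]"
                      for i in range(len(breaks) - 1)]
    classes = sorted(np.unique(labels))
    rows = {name: {c: 0 for c in classes} for name in interval_names}
    under = {c: 0 for c in classes}
    over = {c: 0 for c in classes}
    # right-closed: value v falls in bin i iff breaks[i] < v <= breaks[i+1]
    idx = np.searchsorted(breaks, values, side="left") - 1
    for v, lab, i in zip(values, labels, idx):
        if v <= breaks[0]:
            under[lab] += 1
        elif v > breaks[-1]:
            over[lab] += 1
        else:
            rows[interval_names[min(i, len(interval_names) - 1)]][lab] += 1
    n_out = sum(under.values()) + sum(over.values())
    if n_out:
        warnings.warn(f"{n_out} value(s) outside the bin range; counted in "
                      "underflow/overflow rows", RuntimeWarning, stacklevel=2)
        rows = {"underflow": under, **rows, "overflow": over}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = [f"class_{c}" for c in out.columns]
    out.index.name = "interval"
    return out


def shapiro_wilk(values) -> TestResult:
    """Shapiro–Wilk normality test (Royston's approximation via scipy)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not 3 <= n <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    stat, p = sps.shapiro(values)
    return TestResult(statistic=float(stat), p_value=float(p),
                      method="shapiro-wilk", n=(n,))


def _exact_rank_sum_p(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for the rank-sum statistic.

    Enumerates every assignment of the pooled midranks to group 0 and
    counts assignments whose rank sum is at least as extreme (two-sided, by
    distance from the null mean) as the observed one.  Midranks make this
    valid under ties.
    """
    pooled = np.concatenate([x0, x1])
    ranks = sps.rankdata(pooled)
    n0 = len(x0)
    observed = ranks[:n0].sum()
    mu = n0 * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - mu)
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n0):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs_dev - 1e-9:
            count += 1
    return float(observed), count / total


def wilcoxon_rank_sum(x0, x1, exact_max_n: int = 10) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the normal approximation with midranks, tie correction and
    continuity correction; switches to an exact permutation enumeration
    when the smaller sample has at most ``exact_max_n`` observations.
    The statistic reported is the rank sum of the first sample.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("both samples must be non-empty")
    n0, n1 = len(x0), len(x1)
    from math import comb
    feasible = comb(n0 + n1, min(n0, n1)) <= 500_000
    if min(n0, n1) <= exact_max_n and not feasible:
        warnings.warn("exact mode requested by sample size but the "
                      "enumeration is too large; using the normal "
                      "approximation", RuntimeWarning, stacklevel=2)
    if min(n0, n1) <= exact_max_n and feasible:
        stat, p = _exact_rank_sum_p(x0, x1)
        method = "wilcoxon-rank-sum-exact"
    else:
        res = sps.mannwhitneyu(x0, x1, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        # convert U to the rank sum of sample 0
        stat = float(res.statistic + n0 * (n0 + 1) / 2.0)
        p = float(res.pvalue)
        method = "wilcoxon-rank-sum-normal"
    return TestResult(statistic=stat, p_value=min(p, 1.0), method=method,
                      n=(n0, n1))


def qq_points(values) -> pd.DataFrame:
    """Normal QQ data: sample order statistics vs standard-normal quantiles
    at plotting positions (i - 0.5)/n."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("QQ plot needs at least 2 values")
    theoretical = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"theoretical": theoretical,
                         "sample": np.sort(values)})


def format_p(p: float) -> str:
    """Display convention: floor very small p-values at 2.2e-16."""
    if p < P_FLOOR:
        return "<2.200e-16"
    return f"{p:.3e}"


def feature_tests(features: pd.DataFrame, labels,
                  columns: list[str] | None = None) -> pd.DataFrame:
    """Per-feature normality and class-difference tests.

    For each column: Shapiro–Wilk on all values pooled (subsampled to 5000
    if larger) and the rank-sum test between the two label classes.
    Returns the table-shaped frame (feature x p-values) with both raw and
    display-floored p-values.
    """
    labels = np.asarray(labels).astype(int)
    if columns is None:
        columns = list(features.columns)
    rows = []
    for col in columns:
        v = features[col].to_numpy(dtype=float)
        sw_values = v if len(v) <= 5000 else v[:5000]
        sw = shapiro_wilk(sw_values)
        w = wilcoxon_rank_sum(v[labels == 0], v[labels == 1])
        rows.append({
            "feature": col,
            "shapiro_p": sw.p_value,
            "wilcoxon_p": w.p_value,
            "shapiro_p_display": format_p(sw.p_value),
            "wilcoxon_p_display": format_p(w.p_value),
        })
    return pd.DataFrame(rows).set_index("feature")
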