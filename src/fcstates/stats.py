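"""Nonparametric group comparisons for brain-state features.

Two independent groups are compared per dependent variable with the
Mann-Whitney U test.  The module provides the U statistic itself, an
exact two-sided p-value from the full null distribution of U (computed
by the standard counting recurrence), the large-sample normal
approximation with continuity and tie corrections, the rank-biserial
effect size r = 2U/(n1*n2) - 1, Benjamini-Hochberg FDR adjustment
within declared families of tests, and the usual assumption checks
(Shapiro-Wilk, Levene, z-score/IQR outlier flags) that accompany a
nonparametric analysis.

Published tables of this kind typically report the continuity-corrected
normal-approximation p-value even at n = 15 per group, so
:func:`compare_groups` defaults to ``method="asymptotic"``; the exact
enumeration is available as ``method="exact"`` and is validated against
brute-force arrangement enumeration in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "mannwhitney_u",
    "exact_p",
    "asymptotic_p",
    "p_value",
    "rank_biserial",
    "bh_fdr",
    "assumption_checks",
    "flag_outliers",
    "compare_groups",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "feature",
    "family",
    "median1",
    "median2",
    "median_diff",
    "U",
    "p",
    "p_fdr",
    "r_rb",
    "n1",
    "n2",
    "method",
]


@dataclass
class TestResult:
    """One dependent variable's two-group comparison."""

    feature: str
    family: str
    median1: float
    median2: float
    median_diff: float
    U: float
    p: float
    p_fdr: float
    r_rb: float
    n1: int
    n2: int
    method: str


def mannwhitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, bool]:
    """Mann-Whitney U statistic for the first sample.

    U counts, over all (x_i, y_j) pairs, 1 for x_i > y_j and 1/2 for a
    tie.  Returns ``(U, has_ties)``; ties make U possibly half-integral
    and invalidate the exact no-tie null distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    diff = x[:, None] - y[None, :]
    u = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    return u, has_ties


@lru_cache(maxsize=64)
def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of rank arrangements giving each U value (no ties).

    Uses the recurrence f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u)
    implemented iteratively as a polynomial product (the Gaussian
    binomial coefficient), which is equivalent and fast.
    """
    umax = n1 * n2
    # rows[b][u] = f(a, b, u) for the current a; start at a = 0
    rows = np.zeros((n2 + 1, umax + 1), dtype=float)
    rows[:, 0] = 1.0
    for a in range(1, n1 + 1):
        prev_a = rows
        rows = np.zeros_like(prev_a)
        rows[0, 0] = 1.0
        for b in range(1, n2 + 1):
            shifted = np.zeros(umax + 1)
            shifted[b:] = prev_a[b, : umax + 1 - b]
            rows[b] = rows[b - 1] + shifted
    return rows[n2]


def exact_p(U: float, n1: int, n2: int) -> float:
    """Exact two-sided p-value of the Mann-Whitney U statistic.

    Enumerates the tie-free null distribution of U via the counting
    recurrence and returns ``min(1, 2 * P(U <= min(U, n1*n2 - U)))``.
    Requires an integer-valued U (half-integral U signals ties, for
    which the exact distribution does not apply).
    """
    if not float(U).is_integer():
        raise ValueError(
            "exact p-value requires an integer U (ties present?); "
            "use asymptotic_p with a tie term instead"
        )
    U = int(U)
    if not 0 <= U <= n1 * n2:
        raise ValueError(f"U={U} outside [0, {n1 * n2}]")
    counts = _u_counts(n1, n2)
    total = counts.sum()
    u_low = min(U, n1 * n2 - U)
    p = 2.0 * counts[: u_low + 1].sum() / total
    return min(1.0, float(p))


def _tie_term(x: Sequence[float], y: Sequence[float]) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    _, t = np.unique(pooled, return_counts=True)
    return float(np.sum(t**3 - t))


def asymptotic_p(U: float, n1: int, n2: int, tie_term: float = 0.0) -> float:
    """Two-sided normal-approximation p with continuity correction.

    The null mean is n1*n2/2 and the variance n1*n2*(n1+n2+1)/12,
    reduced by the midrank tie correction when ``tie_term`` (the sum of
    t^3 - t over tie groups) is supplied.  This is the p-value printed
    by the common Python statistical routines and hence by most applied
    reports.
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(U - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def p_value(
    U: float, n1: int, n2: int, *, method: str = "exact", tie_term: float = 0.0
) -> float:
    """Two-sided Mann-Whitney p-value by the requested method.

    ``method="exact"`` uses the enumeration (falling back to the
    tie-corrected normal approximation when U is half-integral);
    ``method="asymptotic"`` always uses the normal approximation with
    continuity correction.
    """
    if method == "asymptotic":
        return asymptotic_p(U, n1, n2, tie_term)
    if method == "exact":
        if float(U).is_integer() and tie_term == 0.0:
            return exact_p(U, n1, n2)
        return asymptotic_p(U, n1, n2, tie_term)
    raise ValueError(f"unknown method {method!r}")


def rank_biserial(U: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = 2U/(n1*n2) - 1."""
    if not 0 <= U <= n1 * n2:
        raise ValueError(f"U={U} outside [0, {n1 * n2}]")
    return 2.0 * U / (n1 * n2) - 1.0


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assumption_checks(x: Sequence[float], y: Sequence[float]) -> dict:
    """Shapiro-Wilk per group and median-centred Levene across groups.

    Informational only: the primary comparison is nonparametric.
    Constant (zero-variance) samples are flagged and skipped rather
    than raising.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    report: dict = {"degenerate": []}
    for name, v in (("group1", x), ("group2", y)):
        if v.size < 3 or np.ptp(v) == 0:
            report["degenerate"].append(name)
            report[f"shapiro_{name}"] = (np.nan, np.nan)
        else:
            w, p = sps.shapiro(v)
            report[f"shapiro_{name}"] = (float(w), float(p))
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        report["levene"] = (0.0, 1.0)
    else:
        stat, p = sps.levene(x, y, center="median")
        report["levene"] = (float(stat), float(p))
    return report


def flag_outliers(values: Sequence[float]) -> np.ndarray:
    """Boolean flags: |z| > 3 or outside the 1.5*IQR Tukey fences.

    Flags only; nothing is removed (exclusion is an analyst decision).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values to flag outliers")
    sd = v.std(ddof=1)
    z = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (np.abs(z) > 3) | (v < lo) | (v > hi)


def compare_groups(
    features: pd.DataFrame,
    pairing: tuple[str, str],
    families: Mapping[str, str] | None = None,
    *,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Compare two groups on every feature of a tidy feature table.

    ``features`` must have columns ``subject_id``, ``group``,
    ``feature``, ``value``.  ``pairing`` names (group1, group2); U is
    reported for group1, so a negative rank-biserial r means group1
    tends lower.  ``families`` maps feature name -> FDR family; BH
    adjustment is applied within each family separately.  Features
    whose family is not declared raise, unless ``families`` is None, in
    which case every feature defaults to the single family "all".

    Missing values (NaN) are dropped pairwise per feature.  Returns a
    DataFrame with one row per feature, columns ``RESULT_COLUMNS``.
    """
    required = {"subject_id", "group", "feature", "value"}
    if not required.issubset(features.columns):
        raise ValueError(f"feature table needs columns {sorted(required)}")
    g1, g2 = pairing
    rows: list[TestResult] = []
    feats = list(dict.fromkeys(features["feature"]))
    if families is None:
        families = {f: "all" for f in feats}
    missing_family = [f for f in feats if f not in families]
    if missing_family:
        raise ValueError(f"features without an FDR family: {missing_family}")
    for feat in feats:
        sub = features[features["feature"] == feat]
        x = sub.loc[sub["group"] == g1, "value"].to_numpy(dtype=float)
        y = sub.loc[sub["group"] == g2, "value"].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if x.size == 0 or y.size == 0:
            raise ValueError(f"feature {feat!r}: a group has no finite values")
        u, has_ties = mannwhitney_u(x, y)
        tie = _tie_term(x, y) if has_ties else 0.0
        p = p_value(u, x.size, y.size, method=method, tie_term=tie)
        rows.append(
            TestResult(
                feature=feat,
                family=families[feat],
                median1=float(np.median(x)),
                median2=float(np.median(y)),
                median_diff=float(np.median(x) - np.median(y)),
                U=u,
                p=p,
                p_fdr=np.nan,
                r_rb=rank_biserial(u, x.size, y.size),
                n1=int(x.size),
                n2=int(y.size),
                method=method if not (method == "exact" and has_ties) else "asymptotic",
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows])[RESULT_COLUMNS]
    for fam, idx in out.groupby("family").groups.items():
        out.loc[idx, "p_fdr"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out
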