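"""Between-group statistics: summary-table tests and edge-/node-wise
two-sample tests with Benjamini-Hochberg FDR control."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .flow import PreferredFlow, edge_features

__all__ = [
    "StatReport",
    "ttest_from_summary",
    "chisq_2x2",
    "ks_normality",
    "mannwhitney",
    "bh_fdr",
    "edgewise_test",
    "nodewise_test",
]


@dataclass
class StatReport:
    """Tabular test results for a family of units (edges, nodes, variables).

    ``table`` columns: id, t, p, q, significant, direction.  ``direction``
    is "increased"/"decreased" in group B relative to group A.
    """

    unit: str
    table: pd.DataFrame
    level: float = 0.05
    variant: str = "student"
    extra: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_ids(self) -> list:
        return list(self.table.loc[self.table["significant"], "id"])


def ttest_from_summary(m1, s1, n1, m2, s2, n2, variant: str = "welch"):
    """Two-sample t-test from per-group mean, SD and n.

    ``student`` pools the variances (df = n1 + n2 - 2); ``welch`` uses the
    Welch-Satterthwaite df.  Returns (t, df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means: t is infinite")
    if variant == "student":
        t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(t), float(df), float(p)


def chisq_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-squared test (df = 1, no continuity correction) on the
    2x2 table [[a, b], [c, d]].  Returns (chi2, p)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def ks_normality(sample):
    """One-sample Kolmogorov-Smirnov test of the standardized data against
    the standard normal (Lilliefors-style: parameters are fitted, so the
    returned p is conservative).  Returns (statistic, p)."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 5:
        raise ValueError("KS normality test needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    z = (x - x.mean()) / sd
    stat, p = stats.kstest(z, "norm")
    return float(stat), float(p)


def mannwhitney(sample_a, sample_b):
    """Two-sided Mann-Whitney U test.

    Exact for small tie-free samples; normal approximation with tie
    correction otherwise.  Returns (U, p) with U for the first sample.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = a.size <= 20 and b.size <= 20
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p_values, level: float = 0.05):
    """Benjamini-Hochberg step-up FDR.  Returns (q_values, reject_flags)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    reject = q <= level
    return q, reject


def _feature_ttests(A: np.ndarray, B: np.ndarray, variant: str):
    """Vectorized two-sample t over feature columns; zero-variance columns
    with equal means get (t=0, p=1), with unequal means p=0."""
    equal_var = variant == "student"
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        mean_diff = A.mean(axis=0) - B.mean(axis=0)
        same = degenerate & (mean_diff == 0)
        diff = degenerate & (mean_diff != 0)
        t[same], p[same] = 0.0, 1.0
        t[diff] = np.sign(mean_diff[diff]) * np.inf
        p[diff] = 0.0
    return t, p


def _build_report(ids, t, p, mean_a, mean_b, unit, level, variant) -> StatReport:
    q, reject = bh_fdr(p, level)
    direction = np.where(mean_b > mean_a, "increased",
                         np.where(mean_b < mean_a, "decreased", "unchanged"))
    table = pd.DataFrame({
        "id": ids,
        "mean_group_a": mean_a,
        "mean_group_b": mean_b,
        "t": t,
        "p": p,
        "q": q,
        "significant": reject,
        "direction": direction,
    })
    return StatReport(unit=unit, table=table, level=level, variant=variant)


def _stack_flows(flows: list, extractor):
    rows = [extractor(f) for f in flows]
    return np.vstack([np.asarray(r, dtype=float) for r in rows])


def edgewise_test(flows_a: list, flows_b: list, level: float = 0.05,
                  variant: str = "student") -> StatReport:
    """Per-edge two-sample t-test of the preferred direction between groups,
    BH-FDR corrected jointly over all upper-triangle edges."""
    if len(flows_a) < 2 or len(flows_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    _, names = edge_features(flows_a[0])
    A = _stack_flows(flows_a, lambda f: edge_features(f)[0])
    B = _stack_flows(flows_b, lambda f: edge_features(f)[0])
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups have different edge counts")
    t, p = _feature_ttests(A, B, variant)
    return _build_report(names, t, p, A.mean(axis=0), B.mean(axis=0),
                         "edge", level, variant)


def nodewise_test(flows_a: list, flows_b: list, level: float = 0.05,
                  variant: str = "student") -> StatReport:
    """Per-node two-sample t-test of the preferred-flow index between
    groups, BH-FDR corrected over the N nodes."""
    if len(flows_a) < 2 or len(flows_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    ids = [f"region_{r}" for r in flows_a[0].region_ids]
    A = _stack_flows(flows_a, lambda f: f.index)
    B = _stack_flows(flows_b, lambda f: f.index)
    t, p = _feature_ttests(A, B, variant)
    return _build_report(ids, t, p, A.mean(axis=0), B.mean(axis=0),
                         "node", level, variant)
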