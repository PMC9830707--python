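"""Per-group feature summaries and two-group comparison.

Groups are summarized as per-feature means with sample standard deviations
(n-1 denominator), and each of the eight morphometrics is compared between
the two groups with a two-sided pooled-variance Student's t-test at
alpha = 0.05 by default.  No multiple-testing correction is applied by
default (Holm correction and Welch's test are available behind flags).
Undefined feature values are excluded pairwise and the per-feature n is
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from collafiber.features import FEATURE_NAMES, FeatureVector

__all__ = [
    "GroupSummary",
    "ComparisonRow",
    "summarize_group",
    "students_t_test",
    "welch_t_test",
    "compare_groups",
    "comparison_table",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Per-feature mean, sample SD and n for one group of samples."""

    group_label: str
    n: int
    mean: dict[str, float]
    sd: dict[str, float]
    n_defined: dict[str, int]


@dataclass(frozen=True)
class ComparisonRow:
    feature_name: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    t_statistic: float
    df: float
    p_value: float
    significant: bool


def _feature_matrix(vectors: list[FeatureVector]) -> np.ndarray:
    return np.asarray([fv.as_tuple() for fv in vectors], dtype=float)


def summarize_group(vectors: list[FeatureVector], label: str) -> GroupSummary:
    """Mean and sample SD per feature over defined (non-NaN) values.

    With a single defined value the mean is that value and the SD is NaN
    (the n-1 denominator is undefined).
    """
    if len(vectors) == 0:
        raise ValueError("cannot summarize an empty group")
    X = _feature_matrix(vectors)
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    n_defined: dict[str, int] = {}
    for j, name in enumerate(FEATURE_NAMES):
        col = X[:, j]
        col = col[~np.isnan(col)]
        n_defined[name] = int(col.size)
        mean[name] = float(col.mean()) if col.size else float("nan")
        sd[name] = float(col.std(ddof=1)) if col.size >= 2 else float("nan")
    return GroupSummary(label, len(vectors), mean, sd, n_defined)


def students_t_test(a, b) -> tuple[float, float, float]:
    """Two-sided two-sample pooled-variance Student's t-test.

    Returns ``(t, df, p)`` with ``s2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2)``,
    ``t = (m1-m2)/sqrt(s2 (1/n1 + 1/n2))`` and ``df = n1+n2-2``.  When both
    groups are constant and equal the statistic is undefined; t is NaN and
    p is reported as 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 defined values")
    df = float(n1 + n2 - 2)
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    se = math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    diff = a.mean() - b.mean()
    if se == 0:
        if diff == 0:
            return float("nan"), df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), df, p


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Two-sided Welch's unequal-variance t-test (optional alternative)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 defined values")
    v1, v2 = a.var(ddof=1) / n1, b.var(ddof=1) / n2
    se = math.sqrt(v1 + v2)
    if se == 0:
        diff = a.mean() - b.mean()
        if diff == 0:
            return float("nan"), float(n1 + n2 - 2), 1.0
        return math.copysign(math.inf, diff), float(n1 + n2 - 2), 0.0
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = (a.mean() - b.mean()) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


def compare_groups(
    g1: list[FeatureVector],
    g2: list[FeatureVector],
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
    correction: str = "none",
) -> list[ComparisonRow]:
    """Compare the eight morphometrics between two groups of samples.

    One row per feature, pairwise-complete values only.  A feature with
    fewer than two defined values in either group yields a row with the
    test fields missing (NaN, not significant).  ``correction="holm"``
    applies a Holm step-down adjustment to the p-values before flagging.
    """
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    X1, X2 = _feature_matrix(g1), _feature_matrix(g2)
    test = welch_t_test if welch else students_t_test

    raw: list[dict] = []
    for j, name in enumerate(FEATURE_NAMES):
        a = X1[:, j]
        b = X2[:, j]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        row = {
            "feature_name": name,
            "n1": int(a.size), "mean1": float(a.mean()) if a.size else float("nan"),
            "sd1": float(a.std(ddof=1)) if a.size >= 2 else float("nan"),
            "n2": int(b.size), "mean2": float(b.mean()) if b.size else float("nan"),
            "sd2": float(b.std(ddof=1)) if b.size >= 2 else float("nan"),
        }
        if a.size >= 2 and b.size >= 2:
            t, df, p = test(a, b)
            row.update(t=t, df=df, p=p)
        else:
            row.update(t=float("nan"), df=float("nan"), p=float("nan"))
        raw.append(row)

    pvals = np.asarray([r["p"] for r in raw])
    adj = pvals.copy()
    if correction == "holm":
        order = np.argsort(np.where(np.isnan(pvals), np.inf, pvals))
        m = int(np.sum(~np.isnan(pvals)))
        running = 0.0
        for rank, idx in enumerate(order):
            if np.isnan(pvals[idx]):
                continue
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    return [
        ComparisonRow(
            feature_name=r["feature_name"],
            n1=r["n1"], mean1=r["mean1"], sd1=r["sd1"],
            n2=r["n2"], mean2=r["mean2"], sd2=r["sd2"],
            t_statistic=r["t"], df=r["df"], p_value=r["p"],
            significant=bool(adj[j] < alpha) if not np.isnan(adj[j]) else False,
        )
        for j, r in enumerate(raw)
    ]


def comparison_table(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a DataFrame in export column order."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature_name,
                "n1": r.n1, "mean1": r.mean1, "sd1": r.sd1,
                "n2": r.n2, "mean2": r.mean2, "sd2": r.sd2,
                "t": r.t_statistic, "df": r.df, "p": r.p_value,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
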