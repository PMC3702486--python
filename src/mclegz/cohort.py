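"""Two-group cohort statistics: pooled t-tests, Fisher exact tests, reports.

Continuous measures are compared with the pooled-variance two-sample
Student t-test (two-sided), either from raw per-subject values or directly
from printed ``mean ± SD (n)`` summaries — the two routes agree exactly by
construction.  Binary characteristics use Fisher's exact test with the
probability-mass two-sided rule (the sum of hypergeometric probabilities of
all tables, at fixed margins, no more probable than the observed one).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "FisherResult",
    "t_test_summary",
    "t_test_subjects",
    "fisher_2x2",
    "build_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    """Sample mean, sample SD (ddof=1) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


@dataclass(frozen=True)
class TTestResult:
    """Pooled two-sample t statistic, degrees of freedom, two-sided p."""

    t: float
    df: int
    p: float
    degenerate: bool = False  # pooled sd was 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be in [0, 1]")


@dataclass(frozen=True)
class FisherResult:
    two_sided_p: float
    table: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        if not (0.0 < self.two_sided_p <= 1.0):
            raise ValueError("p must be in (0, 1]")


def t_test_summary(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Pooled two-sample t-test from per-group summaries.

    sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2);
    t = (m1 - m2) / (sp sqrt(1/n1 + 1/n2)), two-sided p on n1+n2-2 df.
    A zero pooled SD is degenerate: p=1 for equal means, p=0 otherwise.
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    # treat spread at floating-point roundoff of the means as exactly zero
    scale = max(abs(g1.mean), abs(g2.mean), 1.0)
    if sp2 <= (1e-12 * scale) ** 2:
        if abs(g1.mean - g2.mean) <= 1e-12 * scale:
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        t = math.inf if g1.mean > g2.mean else -math.inf
        return TTestResult(t=t, df=df, p=0.0, degenerate=True)
    t, p = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    return TTestResult(t=float(t), df=df, p=float(p))


def t_test_subjects(values1, values2) -> TTestResult:
    """Pooled t-test from raw per-subject values.

    Computed via the groups' sample summaries, so it is algebraically
    identical to :func:`t_test_summary` on those summaries.
    """
    x1 = np.asarray(values1, dtype=float)
    x2 = np.asarray(values2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need >= 2 values per group")
    g1 = GroupSummary(float(x1.mean()), float(x1.std(ddof=1)), x1.size)
    g2 = GroupSummary(float(x2.mean()), float(x2.std(ddof=1)), x2.size)
    return t_test_summary(g1, g2)


def fisher_2x2(table) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    Uses the probability-mass rule (sum over tables with hypergeometric
    probability <= the observed one, fixed margins).  A zero row or column
    margin makes every table certain: p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return FisherResult(two_sided_p=1.0, table=tuple(map(tuple, t.tolist())))
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])
    return FisherResult(two_sided_p=min(p, 1.0), table=tuple(map(tuple, t.tolist())))


def build_report(
    cohort: pd.DataFrame,
    group_col: str = "therapy",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group summary table: mean ± SD with pooled-t p for continuous
    variables, n (%) with Fisher p for binary variables.

    Missing values are dropped per variable (counts logged).  Rows keep the
    order of the configured variable lists.
    """
    groups = sorted(cohort[group_col].unique(), reverse=True)
    if len(groups) != 2:
        raise ValueError(f"{group_col} must define exactly two groups")
    g1 = cohort[cohort[group_col] == groups[0]]
    g2 = cohort[cohort[group_col] == groups[1]]
    if continuous is None:
        continuous = [
            c
            for c in cohort.columns
            if c not in (group_col, "subject_id")
            and pd.api.types.is_numeric_dtype(cohort[c])
            and not set(cohort[c].dropna().unique()) <= {0, 1}  # binary -> Fisher
        ]
    categorical = categorical or []

    rows = []
    for var in continuous:
        x1 = g1[var].dropna().to_numpy(dtype=float)
        x2 = g2[var].dropna().to_numpy(dtype=float)
        n_missing = len(g1) + len(g2) - x1.size - x2.size
        if n_missing:
            log.info("report: %s dropped %d missing values", var, n_missing)
        res = t_test_subjects(x1, x2)
        rows.append(
            {
                "variable": var,
                f"group_{groups[0]}": f"{x1.mean():.1f} ± {x1.std(ddof=1):.1f}",
                f"group_{groups[1]}": f"{x2.mean():.1f} ± {x2.std(ddof=1):.1f}",
                "test": "pooled t",
                "p": res.p,
            }
        )
    for var in categorical:
        x1 = g1[var].dropna().astype(bool)
        x2 = g2[var].dropna().astype(bool)
        table = [[int(x1.sum()), int((~x1).sum())], [int(x2.sum()), int((~x2).sum())]]
        res_f = fisher_2x2(table)
        rows.append(
            {
                "variable": var,
                f"group_{groups[0]}": f"{table[0][0]} ({100 * x1.mean():.0f}%)",
                f"group_{groups[1]}": f"{table[1][0]} ({100 * x2.mean():.0f}%)",
                "test": "Fisher exact",
                "p": res_f.two_sided_p,
            }
        )
    return pd.DataFrame(rows)
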