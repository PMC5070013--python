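"""Classical hypothesis tests used by the volume, distance and expression analyses.

All three tests are implemented from their textbook definitions (and
cross-checked against scipy / brute-force enumeration in the test suite):

* ``students_t`` — unpaired equal-variance two-sample Student's t, two-sided.
* ``rank_sum_test`` — one- or two-sided Wilcoxon rank-sum / Mann-Whitney.
  Small samples (both groups <= 8) use exact enumeration over all label
  assignments, which is also correct under ties; larger samples use the
  normal approximation with tie and continuity corrections.
* ``chisq_proportions`` — Pearson chi-square on a 2x2 table, df=1, no Yates
  correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

EXACT_RANKSUM_MAX_N = 8


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float
    alternative: str
    n1: int
    n2: int
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or math.isnan(self.pvalue)):
            raise ValueError(f"p-value out of range: {self.pvalue}")


def students_t(group_a, group_b) -> TestResult:
    """Unpaired two-sample Student's t-test (equal variances), two-sided.

    Degenerate inputs: zero pooled variance gives p=1 when the means agree and
    p=0 when they differ.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if sp2 == 0.0:
        stat = 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
        p = 1.0 if m1 == m2 else 0.0
    else:
        stat = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * sps.t.sf(abs(stat), df)
    return TestResult(
        name="students_t", statistic=float(stat), pvalue=float(p),
        alternative="two-sided", n1=n1, n2=n2, details={"df": df},
    )


def _exact_rank_sum(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact permutation distribution of the rank sum of x (handles ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, total = len(x), len(pooled)
    w_obs = ranks[:n].sum()
    sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(total), n)])
    eps = 1e-9
    p_greater = np.mean(sums >= w_obs - eps)
    p_less = np.mean(sums <= w_obs + eps)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return float(w_obs), float(p)


def rank_sum_test(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum test of x against y.

    ``alternative='greater'`` tests whether x is stochastically larger than y.
    Both groups <= 8 -> exact enumeration; otherwise normal approximation with
    tie correction and continuity correction.  If every pooled value is tied
    the test is uninformative: p = 0.5 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        log.warning("rank_sum_test: all values tied across both groups; p = 0.5")
        return TestResult(
            name="rank_sum", statistic=float("nan"), pvalue=0.5,
            alternative=alternative, n1=len(x), n2=len(y), details={"degenerate": True},
        )
    if max(len(x), len(y)) <= EXACT_RANKSUM_MAX_N:
        stat, p = _exact_rank_sum(x, y, alternative)
        method = "exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic", use_continuity=True)
        stat, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    return TestResult(
        name="rank_sum", statistic=stat, pvalue=min(p, 1.0),
        alternative=alternative, n1=len(x), n2=len(y), details={"method": method},
    )


def chisq_proportions(table) -> TestResult:
    """Pearson chi-square (no continuity correction) on a 2x2 count table.

    Rows are groups, columns are outcomes.  Also reports the two observed
    first-column proportions.  Zero margins are an error (expected counts
    must all be positive).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin: every row and column must have counts")
    expected = np.outer(rows, cols) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    props = (t[:, 0] / rows).tolist()
    return TestResult(
        name="chi_square", statistic=stat, pvalue=p, alternative="two-sided",
        n1=int(rows[0]), n2=int(rows[1]),
        details={"df": 1, "proportions": props},
    )
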