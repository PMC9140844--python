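"""Exact small-sample statistical battery for paired diagnostic-positivity analysis.

A 40-nodule cohort is far below the comfort zone of asymptotic tests, so
every categorical comparison here is exact:

* :func:`fisher_exact` — Fisher's exact test, generalized to r x c tables
  by full enumeration over fixed margins (Freeman-Halton), with the
  probability-ordering two-sided definition;
* :func:`mcnemar_exact` — exact binomial McNemar test on discordant pairs,
  doubling the smaller tail;
* :func:`wilcoxon_signed_rank` — exact sign-flip distribution (with ties)
  up to ``EXACT_WILCOXON_N`` pairs, tie- and continuity-corrected normal
  approximation above;
* :func:`mann_whitney_u` — exact rank-split enumeration when both samples
  are small, tie-corrected normal approximation otherwise.

Kruskal-Wallis uses the standard tie-corrected H with a chi-square
reference (delegated to scipy).  Quantiles everywhere use the
weighted-average percentile definition (positions at (n + 1)p), the
convention of mainstream clinical statistics software.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "PairedBinary",
    "TestResult",
    "fisher_exact",
    "mcnemar_exact",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "bonferroni_posthoc",
    "median_quartiles",
    "EXACT_MCNEMAR_MAX_DISCORDANT",
    "EXACT_WILCOXON_N",
    "EXACT_MANN_WHITNEY_N",
]

# Exact-vs-approximation switch points, explicit for reproducibility.
EXACT_MCNEMAR_MAX_DISCORDANT = 25
EXACT_WILCOXON_N = 20
EXACT_MANN_WHITNEY_N = 10

_FISHER_MAX_DIM = 4
_FISHER_MAX_TOTAL = 200
#: relative tolerance when comparing table probabilities for the
#: probability-ordering two-sided rule (guards against float round-off).
_PROB_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: Optional[Sequence[str]] = None
    col_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() < 1:
            raise ValueError("table must contain at least one observation")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class PairedBinary:
    """Discordant and concordant counts of a paired binary outcome.

    ``b``: positive before / negative after; ``c``: negative before /
    positive after; ``n_concordant``: pairs with no change.
    """

    b: int
    c: int
    n_concordant: int = 0

    def __post_init__(self) -> None:
        if min(self.b, self.c, self.n_concordant) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: Optional[float]
    p_value: float
    method: str
    exact: bool
    df: Optional[int] = None
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> Dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "exact": self.exact,
        }
        if self.df is not None:
            d["df"] = self.df
        if self.note is not None:
            d["note"] = self.note
        return d


# ---------------------------------------------------------------------------
# Fisher / Freeman-Halton


def _iter_tables_with_margins(
    row_margins: Sequence[int], col_margins: Sequence[int]
) -> Iterator[np.ndarray]:
    """Yield every non-negative integer table with the given margins."""
    r, c = len(row_margins), len(col_margins)
    table = np.zeros((r, c), dtype=np.int64)
    col_left = np.array(col_margins, dtype=np.int64)

    def fill_row(i: int) -> Iterator[np.ndarray]:
        if i == r - 1:
            # last row forced by column remainders
            if (col_left >= 0).all() and col_left.sum() == row_margins[i]:
                if (col_left <= row_margins[i]).all():
                    table[i] = col_left
                    yield table
            return
        yield from fill_cell(i, 0, row_margins[i])

    def fill_cell(i: int, j: int, row_left: int) -> Iterator[np.ndarray]:
        if j == c - 1:
            if row_left <= col_left[j]:
                table[i, j] = row_left
                col_left[j] -= row_left
                yield from fill_row(i + 1)
                col_left[j] += row_left
            return
        for v in range(min(row_left, col_left[j]) + 1):
            table[i, j] = v
            col_left[j] -= v
            yield from fill_cell(i, j + 1, row_left - v)
            col_left[j] += v

    yield from fill_row(0)


def _log_table_prob(counts: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a table given its margins."""
    rm = counts.sum(axis=1)
    cm = counts.sum(axis=0)
    n = counts.sum()
    return float(
        gammaln(rm + 1).sum()
        + gammaln(cm + 1).sum()
        - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


def fisher_exact(t: ContingencyTable) -> TestResult:
    """Exact conditional test of independence on an r x c table.

    Two-sided p is the probability-ordering (Freeman-Halton) definition:
    the sum of probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed that of the observed table.
    On 2 x 2 tables this reduces to the classic two-sided Fisher test.
    """
    counts = t.counts
    r, c = counts.shape
    n = int(counts.sum())
    if r > _FISHER_MAX_DIM or c > _FISHER_MAX_DIM or n > _FISHER_MAX_TOTAL:
        raise ValueError(
            f"table {r}x{c} with total {n} exceeds the exact-enumeration bound "
            f"({_FISHER_MAX_DIM}x{_FISHER_MAX_DIM}, total {_FISHER_MAX_TOTAL}); "
            "use a chi-square approximation instead"
        )
    log_p_obs = _log_table_prob(counts)
    threshold = log_p_obs + _PROB_TIE_RTOL
    p = 0.0
    for table in _iter_tables_with_margins(counts.sum(axis=1), counts.sum(axis=0)):
        lp = _log_table_prob(table)
        if lp <= threshold:
            p += math.exp(lp)
    return TestResult(
        statistic=math.exp(log_p_obs),
        p_value=min(p, 1.0),
        method=f"Fisher exact ({r}x{c}, Freeman-Halton enumeration)",
        exact=True,
    )


# ---------------------------------------------------------------------------
# McNemar


def mcnemar_exact(p: PairedBinary) -> TestResult:
    """Change in a paired binary outcome, using only discordant pairs.

    Exact binomial (doubling the smaller tail, capped at 1) while the
    discordant count is at most ``EXACT_MCNEMAR_MAX_DISCORDANT``;
    continuity-corrected chi-square above.
    """
    nd = p.b + p.c
    if nd == 0:
        return TestResult(
            statistic=0.0, p_value=1.0, method="McNemar exact", exact=True,
            note="degenerate: no discordant pairs",
        )
    if nd <= EXACT_MCNEMAR_MAX_DISCORDANT:
        k = min(p.b, p.c)
        p_value = min(1.0, 2.0 * float(sps.binom.cdf(k, nd, 0.5)))
        return TestResult(
            statistic=float(k), p_value=p_value, method="McNemar exact", exact=True,
        )
    chi2 = (abs(p.b - p.c) - 1.0) ** 2 / nd
    return TestResult(
        statistic=chi2,
        p_value=float(sps.chi2.sf(chi2, 1)),
        method="McNemar chi-square (continuity corrected)",
        exact=False,
        df=1,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square reference."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=0.0, p_value=1.0, method="Kruskal-Wallis", exact=False,
            df=df, note="degenerate: all pooled values identical",
        )
    h, p = sps.kruskal(*arrays)
    return TestResult(
        statistic=float(h), p_value=float(p), method="Kruskal-Wallis",
        exact=False, df=df,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_setup(before: Sequence[float], after: Sequence[float]):
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be 1-D sequences of equal length")
    diffs = after - before
    diffs = diffs[diffs != 0.0]  # zero differences dropped
    return diffs


def wilcoxon_signed_rank(
    before: Sequence[float], after: Sequence[float]
) -> TestResult:
    """Paired-sample test on the signed ranks of after - before.

    Zero differences are dropped.  Up to ``EXACT_WILCOXON_N`` non-zero
    pairs, the two-sided p doubles the smaller tail of the exact sign-flip
    distribution of the positive-rank sum (ties handled via average ranks);
    above, a normal approximation with tie and continuity corrections.
    """
    diffs = _signed_rank_setup(before, after)
    n = diffs.size
    if n == 0:
        return TestResult(
            statistic=0.0, p_value=1.0, method="Wilcoxon signed-rank", exact=True,
            note="degenerate: all differences zero",
        )
    ranks = sps.rankdata(np.abs(diffs))
    w_pos = float(ranks[diffs > 0].sum())
    if n <= EXACT_WILCOXON_N:
        # DP over the sign-flip distribution of 2*W+ (doubled ranks are integers)
        doubled = np.rint(2 * ranks).astype(int)
        total = int(doubled.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in doubled:
            counts[r:] += counts[: total + 1 - r].copy()
        counts /= 2.0**n
        w2 = int(round(2 * w_pos))
        p_le = counts[: w2 + 1].sum()
        p_ge = counts[w2:].sum()
        p_value = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(
            statistic=w_pos, p_value=float(p_value),
            method="Wilcoxon signed-rank (exact)", exact=True,
        )
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var == 0:
        return TestResult(
            statistic=w_pos, p_value=1.0, method="Wilcoxon signed-rank", exact=False,
            note="degenerate: zero variance",
        )
    shift = w_pos - mean
    z = (shift - 0.5 * np.sign(shift)) / math.sqrt(var)
    return TestResult(
        statistic=w_pos,
        p_value=min(1.0, 2.0 * float(sps.norm.sf(abs(z)))),
        method="Wilcoxon signed-rank (normal approximation)",
        exact=False,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample rank test; exact by rank-split enumeration for small samples.

    Exact when both samples have at most ``EXACT_MANN_WHITNEY_N``
    observations (enumerating every assignment of the pooled values, which
    handles ties); tie-corrected normal approximation otherwise.  Two-sided
    p doubles the smaller tail.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = a.size, b.size
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = float(ranks[:m].sum())
    u_a = r_a - m * (m + 1) / 2.0
    if m <= EXACT_MANN_WHITNEY_N and n <= EXACT_MANN_WHITNEY_N:
        u_values = []
        for idx in itertools.combinations(range(m + n), m):
            u_values.append(sum(ranks[i] for i in idx) - m * (m + 1) / 2.0)
        u_values = np.asarray(u_values)
        p_le = float((u_values <= u_a + 1e-9).mean())
        p_ge = float((u_values >= u_a - 1e-9).mean())
        return TestResult(
            statistic=u_a, p_value=min(1.0, 2.0 * min(p_le, p_ge)),
            method="Mann-Whitney U (exact enumeration)", exact=True,
        )
    big_n = m + n
    mean = m * n / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (big_n * (big_n - 1))
    var = m * n / 12.0 * ((big_n + 1) - tie_term)
    if var == 0:
        return TestResult(
            statistic=u_a, p_value=1.0, method="Mann-Whitney U", exact=False,
            note="degenerate: zero variance",
        )
    z = (u_a - mean) / math.sqrt(var)
    return TestResult(
        statistic=u_a,
        p_value=min(1.0, 2.0 * float(sps.norm.sf(abs(z)))),
        method="Mann-Whitney U (normal approximation, tie corrected)",
        exact=False,
    )


# ---------------------------------------------------------------------------
# Multiple testing, summaries


def bonferroni_posthoc(pairwise_p: Sequence[float]) -> List[float]:
    """Bonferroni adjustment: each p times the number of comparisons, capped at 1."""
    ps = list(pairwise_p)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(ps)
    return [min(1.0, k * p) for p in ps]


def median_quartiles(values: Sequence[float]) -> Tuple[float, float, float]:
    """(median, Q1, Q3) by the weighted-average percentile rule ((n + 1)p positions)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    med, q1, q3 = np.quantile(arr, [0.5, 0.25, 0.75], method="weibull")
    return float(med), float(q1), float(q3)
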