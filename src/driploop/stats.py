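"""Small-sample statistical tests used throughout the break and qPCR analyses.

Three tests cover every inferential step of the pipeline: a directional
unpaired Wilcoxon (Mann-Whitney) rank-sum test for group contrasts, a
Pearson correlation test for the pre-existing-hybrid analysis, and a paired
t-test for qPCR fold changes. They are implemented here directly so that
the small-sample behaviour is exact and auditable: the rank-sum test
enumerates the full null distribution whenever the pooled sample is small
and tie-free, and falls back to a tie-corrected, continuity-corrected
normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import special

__all__ = ["TestResult", "wilcoxon_one_sided", "pearson_test", "paired_t"]

#: pooled-sample size at or below which the tie-free rank-sum null is enumerated
EXACT_CUTOFF = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    statistic : U (rank-sum), r (Pearson) or t (paired t).
    p         : p-value in [0, 1] for the stated alternative.
    sidedness : "less", "greater" or "two-sided".
    n         : per-group sample sizes.
    method    : "exact" or "approximate".
    extra     : test-specific values (e.g. the t behind a Pearson p).
    """

    statistic: float
    p: float
    sidedness: str
    n: tuple[int, ...]
    method: str
    extra: dict | None = None

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by the mean rank of the tied block."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x against y with midranks for ties."""
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    rx = ranks[:nx].sum()
    return rx - nx * (nx + 1) / 2.0


def _exact_p(u: float, nx: int, ny: int, direction: str) -> float:
    """Full enumeration of the tie-free null: every assignment of ranks to x."""
    n = nx + ny
    ranks = range(1, n + 1)
    offset = nx * (nx + 1) / 2.0
    count = 0
    for combo in combinations(ranks, nx):
        u_perm = sum(combo) - offset
        if direction == "less":
            count += u_perm <= u + 1e-9
        else:
            count += u_perm >= u - 1e-9
    return count / comb(n, nx)


def _approx_p(u: float, x: np.ndarray, y: np.ndarray, direction: str) -> float:
    nx, ny = len(x), len(y)
    n = nx + ny
    mu = nx * ny / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # every pooled value identical
        return 1.0
    sd = sqrt(var)
    if direction == "less":
        z = (u + 0.5 - mu) / sd
        return float(special.ndtr(z))
    z = (u - 0.5 - mu) / sd
    return float(special.ndtr(-z))


def wilcoxon_one_sided(x, y, direction: str = "less") -> TestResult:
    """Directional unpaired Wilcoxon (Mann-Whitney) rank-sum test.

    Tests whether ``x`` is stochastically smaller (``direction="less"``) or
    larger (``"greater"``) than ``y``. The p-value is exact (full
    enumeration of rank assignments) when the pooled sample has at most
    ``EXACT_CUTOFF`` observations and no ties, otherwise a tie-corrected
    normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if direction not in ("less", "greater"):
        raise ValueError(f"direction must be 'less' or 'greater', got {direction!r}")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_CUTOFF and not has_ties:
        p = _exact_p(u, len(x), len(y), direction)
        method = "exact"
    else:
        p = _approx_p(u, x, y, direction)
        method = "approximate"
    return TestResult(u, min(p, 1.0), direction, (len(x), len(y)), method)


def pearson_test(x, y) -> TestResult:
    """Pearson correlation with the two-sided t-test on r.

    r = sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) sum((y-ybar)^2));
    t = r sqrt((n-2)/(1-r^2)) is referred to Student's t with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Pearson test needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    ssx = float(xc @ xc)
    ssy = float(yc @ yc)
    if ssx == 0.0 or ssy == 0.0:
        raise ValueError("zero variance in one of the variables: correlation undefined")
    r = float(xc @ yc) / sqrt(ssx * ssy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
        t = float("inf") if r > 0 else float("-inf")
    else:
        t = r * sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(special.stdtr(n - 2, -abs(t)))
    return TestResult(r, min(p, 1.0), "two-sided", (n,), "approximate", extra={"t": t})


def paired_t(a, b, sidedness: str = "two-sided") -> TestResult:
    """Paired t-test on matched observations a_i vs b_i.

    t = dbar / (s_d / sqrt(n)) on differences d = a - b, df = n - 1.
    ``sidedness`` may be "two-sided", "greater" (a > b) or "less".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D with equal length")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    dbar = d.mean()
    if sd == 0.0:
        if dbar == 0.0:
            # all pairs identical: no evidence of a shift
            return TestResult(0.0, 1.0, sidedness, (n,), "exact")
        raise ValueError("zero variance of non-zero differences: t undefined")
    t = dbar / (sd / sqrt(n))
    df = n - 1
    if sidedness == "two-sided":
        p = 2.0 * float(special.stdtr(df, -abs(t)))
    elif sidedness == "greater":
        p = float(special.stdtr(df, -t))
    elif sidedness == "less":
        p = float(special.stdtr(df, t))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return TestResult(float(t), min(p, 1.0), sidedness, (n,), "approximate")
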