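"""Correlation and group-comparison machinery.

Plain Pearson and Spearman correlations wrap scipy; the partial Spearman
correlation is computed by rank residualization: x, y and every control
are converted to mid-ranks, the ranked x and y are residualized on the
ranked controls by least squares (with intercept), and the coefficient
is the Pearson correlation of the residuals, with a t-approximate
p-value on n - 2 - k degrees of freedom.  This is equivalent to the
recursive partial-correlation formula on the rank scale and generalizes
cleanly to several simultaneous controls.

The two-sample location test is the Wilcoxon rank-sum test with the
tie-corrected, continuity-corrected normal approximation; an exact
enumeration of the rank-sum distribution (valid with ties) is available
for small samples.

Missing values are removed pairwise for simple correlations and
casewise for partial correlations; the n actually used is reported in
every result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # pearson | spearman | partial_spearman
    coefficient: float
    p_value: float
    n: int
    controls: tuple[str, ...] = ()
    dropped_controls: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupComparison:
    labels: tuple[str, str]
    statistic: float  # rank sum of the first group
    p_value: float
    medians: tuple[float, float]


@dataclass(frozen=True)
class LengthStratification:
    subgroup: int  # 1 (shortest) .. k (longest)
    indices: np.ndarray = field(compare=False)
    length_range: tuple[float, float] = (math.nan, math.nan)


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation; two-sided t-based p on n - 2 df."""
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult("pearson", math.nan, math.nan, n)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult("pearson", float(r), float(p), n)


def spearman(x, y) -> CorrelationResult:
    """Rank correlation (mid-ranks for ties); t-transform p-value."""
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult("spearman", math.nan, math.nan, n)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult("spearman", float(rho), float(p), n)


def _drop_collinear(matrix: np.ndarray, names: list[str]):
    """Greedily drop columns that add no rank to the control matrix."""
    kept_idx: list[int] = []
    dropped: list[str] = []
    current = np.ones((matrix.shape[0], 1))  # intercept
    for j in range(matrix.shape[1]):
        candidate = np.column_stack([current, matrix[:, j]])
        if np.linalg.matrix_rank(candidate) > np.linalg.matrix_rank(current):
            kept_idx.append(j)
            current = candidate
        else:
            dropped.append(names[j])
    return kept_idx, dropped


def partial_spearman(x, y, controls, control_names=None) -> CorrelationResult:
    """Partial rank correlation of x and y given the control covariates.

    Complete cases only; collinear control columns are dropped and
    recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if controls.ndim == 1:
        controls = controls[:, None]
    if controls.size == 0:
        controls = np.empty((x.size, 0))
    if control_names is None:
        control_names = [f"c{j}" for j in range(controls.shape[1])]
    control_names = list(control_names)

    keep = np.isfinite(x) & np.isfinite(y)
    if controls.shape[1]:
        keep &= np.all(np.isfinite(controls), axis=1)
    x, y, controls = x[keep], y[keep], controls[keep]
    n = x.size

    if controls.shape[1] == 0:
        base = spearman(x, y)
        return CorrelationResult(
            "partial_spearman", base.coefficient, base.p_value, n
        )

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rz = np.column_stack([sps.rankdata(controls[:, j]) for j in range(controls.shape[1])])

    kept_idx, dropped = _drop_collinear(rz, control_names)
    rz = rz[:, kept_idx]
    kept_names = tuple(control_names[j] for j in kept_idx)
    k = rz.shape[1]

    if n <= k + 2:
        return CorrelationResult(
            "partial_spearman", math.nan, math.nan, n, kept_names, tuple(dropped)
        )

    design = np.column_stack([np.ones(n), rz])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    # residual variance numerically nil: the controls explain the variable
    # completely, so nothing remains to correlate
    tol = 1e-8 * n
    if np.std(ex) <= tol or np.std(ey) <= tol:
        return CorrelationResult(
            "partial_spearman", 0.0, 1.0, n, kept_names, tuple(dropped)
        )
    rho = float(np.corrcoef(ex, ey)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    df = n - 2 - k
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(
        "partial_spearman", rho, p, n, kept_names, tuple(dropped)
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------


def _rank_sum_exact_p(pooled_ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Exact two-sided p by dynamic programming over rank-sum values.

    Enumerates the distribution of the sum of ``n1`` ranks drawn without
    replacement from ``pooled_ranks`` (ties allowed: mid-ranks are
    rescaled to integers).  p = P(|W - E[W]| >= |w_obs - E[W]|).
    """
    # mid-ranks are multiples of 0.5; double to work in integers
    r2 = np.round(pooled_ranks * 2).astype(int)
    total = int(r2.sum())
    # dp[j] = dict mapping achievable doubled rank-sum -> count, choosing j items
    dp = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in r2:
        for j in range(min(n1, len(dp) - 1) - 1, -1, -1):
            for s, c in list(dp[j].items()):
                dp[j + 1][s + r] = dp[j + 1].get(s + r, 0) + c
    dist = dp[n1]
    n_total = sum(dist.values())
    mean2 = n1 * total / len(r2)
    obs_dev = abs(2 * w_obs - mean2)
    hits = sum(c for s, c in dist.items() if abs(s - mean2) >= obs_dev - 1e-9)
    return min(1.0, hits / n_total)


def wilcoxon_rank_sum(
    a, b, labels: tuple[str, str] = ("a", "b"), exact: bool | None = None
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test.

    Default is the tie-corrected normal approximation with continuity
    correction (matching R's large-sample ``wilcox.test``); ``exact=True``
    (default for n1, n2 <= 10) enumerates the rank-sum distribution.
    When all pooled values are identical, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    medians = (float(np.median(a)), float(np.median(b)))

    if np.unique(pooled).size == 1:
        return GroupComparison(labels, w, 1.0, medians)

    if exact is None:
        exact = n1 <= 10 and n2 <= 10
    if exact:
        p = _rank_sum_exact_p(ranks, n1, w)
        return GroupComparison(labels, w, p, medians)

    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return GroupComparison(labels, w, 1.0, medians)
    dev = w - mean_w
    # continuity correction toward the mean
    dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev)
    z = dev / math.sqrt(var_w)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return GroupComparison(labels, w, p, medians)


def length_quintiles(lengths, k: int = 5) -> list[LengthStratification]:
    """Split observations into k contiguous length subgroups.

    Observations are stably sorted by length (ties keep input order) and
    split into k blocks with sizes as equal as possible, any remainder
    going to the lowest-index (shortest) subgroups.  Subgroup 1 holds
    the shortest lengths.
    """
    lengths = np.asarray(lengths, dtype=float)
    n = lengths.size
    if n < k:
        raise ValueError(f"need at least {k} observations, got {n}")
    order = np.argsort(lengths, kind="stable")
    blocks = np.array_split(order, k)
    out = []
    for i, idx in enumerate(blocks, start=1):
        vals = lengths[idx]
        out.append(
            LengthStratification(i, idx, (float(vals.min()), float(vals.max())))
        )
    return out
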