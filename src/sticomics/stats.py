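"""Statistical primitives shared by every analysis stage.

These are the building blocks of the comparative analysis: Benjamini–Hochberg
FDR adjustment, the exact (Clopper–Pearson) binomial confidence interval,
Fisher's exact test for r×c contingency tables by full margin-fixed
enumeration (Freeman–Halton), Spearman rank correlation, and the two-sample
t test in pooled and Welch variants.

All functions are deterministic, operate on plain numpy arrays, and raise
``ValueError`` on degenerate input rather than guessing.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from scipy import special
from scipy import stats as _scipy_stats

__all__ = [
    "bh_adjust",
    "clopper_pearson_ci",
    "fisher_exact",
    "spearman_rho",
    "two_sample_t",
    "two_sample_t_matrix",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    For sorted p-values p_(1) <= ... <= p_(m),

        q_(i) = min_{j >= i} min(m * p_(j) / j, 1),

    returned in the original order of ``p``.

    Parameters
    ----------
    p : array-like of float in [0, 1]
        Raw p-values, one per feature; no missing values allowed.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1] with no missing entries")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def clopper_pearson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval from beta quantiles.

    lower = Beta(alpha/2; s, n-s+1) quantile, upper = Beta(1-alpha/2; s+1, n-s),
    with lower = 0 when s = 0 and upper = 1 when s = n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    s = int(successes)
    lower = 0.0 if s == 0 else float(special.betaincinv(s, n - s + 1, alpha / 2))
    upper = 1.0 if s == n else float(special.betaincinv(s + 1, n - s, 1 - alpha / 2))
    return lower, upper


def _log_table_prob(table: np.ndarray, lgam_margins: float) -> float:
    # log multivariate hypergeometric probability given fixed margins;
    # lgam_margins = sum(lgamma(r_i+1)) + sum(lgamma(c_j+1)) - lgamma(N+1)
    return lgam_margins - float(np.sum(special.gammaln(table + 1.0)))


def fisher_exact(table, enumeration_cap: int = 500) -> float:
    """Two-sided Fisher's exact p-value for an r×c table (Freeman–Halton).

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the observed
    table.  All-zero rows and columns are dropped first (they carry no mass).
    Tables whose total exceeds ``enumeration_cap`` are refused outright: there
    is no asymptotic fallback, so the result is exact whenever it is returned.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(t < 0):
        raise ValueError("cell counts must be non-negative")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        # after reduction the table is degenerate: only one outcome possible
        return 1.0
    n_total = int(t.sum())
    if n_total > enumeration_cap:
        raise ValueError(
            f"table total {n_total} exceeds the exact-enumeration cap "
            f"({enumeration_cap}); no asymptotic fallback is provided"
        )
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    lgam_margins = float(
        np.sum(special.gammaln(rows + 1.0))
        + np.sum(special.gammaln(cols + 1.0))
        - special.gammaln(n_total + 1.0)
    )
    log_p_obs = _log_table_prob(t, lgam_margins)
    # enumerate tables row by row; the last row and last column are implied
    r, c = t.shape
    total_log = []

    def recurse(row_idx: int, remaining_cols: np.ndarray, partial: list[np.ndarray]) -> None:
        if row_idx == r - 1:
            last = remaining_cols
            if np.all(last >= 0):
                full = np.vstack(partial + [last])
                total_log.append(_log_table_prob(full, lgam_margins))
            return
        target = rows[row_idx]
        # all ways to split `target` over c cells bounded by remaining margins
        for combo in _bounded_compositions(int(target), remaining_cols):
            recurse(row_idx + 1, remaining_cols - combo, partial + [combo])

    recurse(0, cols.copy(), [])
    logs = np.array(total_log)
    # tolerance guards against float jitter in "<= observed probability"
    keep = logs <= log_p_obs + 1e-9
    p = float(np.exp(special.logsumexp(logs[keep])))
    return min(p, 1.0)


def _bounded_compositions(total: int, bounds: np.ndarray):
    """Yield integer vectors summing to `total` with 0 <= v_j <= bounds_j."""
    c = len(bounds)
    if c == 1:
        if 0 <= total <= bounds[0]:
            yield np.array([total], dtype=np.int64)
        return
    lo = max(0, total - int(bounds[1:].sum()))
    hi = min(int(bounds[0]), total)
    for v in range(lo, hi + 1):
        for rest in _bounded_compositions(total - v, bounds[1:]):
            yield np.concatenate(([v], rest))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive their mean rank.  Raises if either vector is constant
    after ranking (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d vectors of length >= 3")
    rx = _scipy_stats.rankdata(x, method="average")
    ry = _scipy_stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant vector: Spearman correlation is undefined")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


TTestVariant = Literal["pooled", "welch"]


def two_sample_t(x, y, variant: TTestVariant = "welch") -> tuple[float, float]:
    """Two-sided two-sample t test; returns (t, p).

    ``variant="pooled"`` assumes equal variances (df = n1+n2-2);
    ``variant="welch"`` uses the Satterthwaite df.  When the standard-error
    denominator is zero (no within-group variance) the convention t = 0,
    p = 1 applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = two_sample_t_matrix(x[None, :], y[None, :], variant=variant)
    return float(t[0]), float(p[0])


def two_sample_t_matrix(
    x: np.ndarray, y: np.ndarray, variant: TTestVariant = "welch"
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t test for gene-by-sample matrices.

    ``x`` is genes × n1 (group 1), ``y`` genes × n2 (group 2).  The statistic
    is (mean(x) - mean(y)) / se.  Rows with a zero denominator get t = 0,
    p = 1 by convention, so constant genes stay in the table.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    m1 = x.mean(axis=1)
    m2 = y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, float(n1 + n2 - 2))
    elif variant == "welch":
        a, b = v1 / n1, v2 / n2
        se2 = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    else:
        raise ValueError(f"unknown t-test variant: {variant!r}")
    se = np.sqrt(se2)
    zero = se == 0
    t = np.zeros_like(se)
    np.divide(m1 - m2, se, out=t, where=~zero)
    p = np.ones_like(t)
    nz = ~zero
    p[nz] = 2.0 * _scipy_stats.t.sf(np.abs(t[nz]), df[nz])
    return t, p
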