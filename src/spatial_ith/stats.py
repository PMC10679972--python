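"""Exact statistical primitives shared across the pipeline.

The Fisher exact tests are computed by direct enumeration of the
hypergeometric (2x2) or multivariate-hypergeometric (Rx2) table space with
fixed margins, and the Benjamini-Hochberg adjustment is the standard
step-up with enforced monotonicity.  These are implemented here rather
than delegated so that they can be verified against independent library
oracles, and so the Rx2 exact test (which scipy does not provide) shares
one code path with the 2x2 case.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "fisher_exact_2x2",
    "fisher_exact_rx2",
    "bh_adjust",
    "paired_t_test",
]

# relative tolerance when comparing table probabilities to the observed
# probability; guards against floating-point noise in the tail sum
_REL_EPS = 1e-7


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    The p-value is the sum of probabilities of all tables with the same
    margins whose hypergeometric probability does not exceed that of the
    observed table.  Degenerate tables (an empty row or column margin)
    return p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    if n == 0 or 0 in row or 0 in col:
        warnings.warn("degenerate 2x2 table (empty margin); p = 1")
        return 1.0
    rv = _sps.hypergeom(n, int(row[0]), int(col[0]))
    a_obs = int(t[0, 0])
    p_obs = rv.pmf(a_obs)
    lo = max(0, int(col[0]) - int(row[1]))
    hi = min(int(row[0]), int(col[0]))
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_EPS)].sum())
    return min(1.0, p)


def _rx2_enumerate(row_sums: np.ndarray, col1: int) -> np.ndarray:
    """All first-column count vectors compatible with the margins."""
    out: list[list[int]] = []

    def rec(i: int, remaining: int, acc: list[int]) -> None:
        if i == len(row_sums) - 1:
            if 0 <= remaining <= row_sums[i]:
                out.append(acc + [remaining])
            return
        tail_cap = int(row_sums[i + 1 :].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(int(row_sums[i]), remaining)
        for a in range(lo, hi + 1):
            rec(i + 1, remaining - a, acc + [a])

    rec(0, col1, [])
    return np.asarray(out, dtype=np.int64)


def fisher_exact_rx2(table: Sequence[Sequence[int]]) -> float:
    """Exact Fisher test for an R x 2 table by full enumeration.

    Generalises the 2x2 case: the null distribution over tables with fixed
    margins is multivariate hypergeometric, and the two-sided p-value sums
    the probabilities of tables no more probable than the observed one.
    Feasible for the cohort sizes this pipeline sees (tens of samples).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2 or (t < 0).any():
        raise ValueError("table must be R x 2 with nonnegative integer counts")
    if t.shape[0] == 2:
        return fisher_exact_2x2(t)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if t.sum() == 0 or (row == 0).any() or (col == 0).any():
        warnings.warn("degenerate R x 2 table (empty margin); p = 1")
        return 1.0

    # log-probability of a table given its first-column vector a:
    # sum_i log C(row_i, a_i) - log C(N, col1)
    def logp(a: np.ndarray) -> float:
        s = -math.lgamma(int(t.sum()) + 1) + math.lgamma(int(col[0]) + 1) + math.lgamma(
            int(col[1]) + 1
        )
        for ri, ai in zip(row, a):
            s += (
                math.lgamma(int(ri) + 1)
                - math.lgamma(int(ai) + 1)
                - math.lgamma(int(ri - ai) + 1)
            )
        return s

    obs = t[:, 0]
    lp_obs = logp(obs)
    tables = _rx2_enumerate(row, int(col[0]))
    lps = np.array([logp(a) for a in tables])
    # normalise in log space for numerical safety
    m = lps.max()
    probs = np.exp(lps - m)
    probs /= probs.sum()
    p_obs = math.exp(lp_obs - m) / np.exp(lps - m).sum()
    p = float(probs[probs <= p_obs * (1.0 + _REL_EPS)].sum())
    return min(1.0, p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the
    original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided paired Student t-test p-value.

    t = mean(d) / (sd(d) / sqrt(n)) with n - 1 degrees of freedom, where
    d = x - y.  Zero-variance differences are degenerate: p = 1 with a
    warning (identical inputs are the canonical case).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    n = xa.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = xa - ya
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance differences; p = 1")
        return 1.0
    tstat = d.mean() / (sd / math.sqrt(n))
    return float(2.0 * _sps.t.sf(abs(tstat), df=n - 1))
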