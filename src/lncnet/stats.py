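"""Shared statistical primitives: hypergeometric tail, correlations, BH FDR."""
from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .models import ValidationError


def hypergeom_tail(M: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in a draw of ``n`` from a universe of ``M`` items of
    which ``K`` are successes: p = sum_{i=k}^{min(K,n)} C(K,i) C(M-K,n-i) / C(M,n).

    This single engine backs both the shared-miRNA sponge test and
    over-representation analysis.
    """
    for name, v in (("M", M), ("K", K), ("n", n), ("k", k)):
        if not isinstance(v, (int, np.integer)):
            raise ValidationError(f"{name} must be an integer, got {v!r}")
    if not (0 <= K <= M and 0 <= n <= M):
        raise ValidationError(f"need 0 <= K,n <= M; got M={M}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    # sf(k-1) is the exact upper tail; scipy evaluates it stably in log space.
    return float(_sps.hypergeom.sf(k - 1, M, K, n))


def spearman_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks; ties get average rank).

    Returns NaN when either profile has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("profiles must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = _sps.spearmanr(x, y).statistic
    return float(rho)


def pearson_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation; NaN for zero-variance profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("profiles must be equal-length 1-D vectors")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q(i) = min_{j >= i} m * p(j) / j on the sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of ``a`` and every row of ``b``.

    Rows with zero variance yield NaN in the corresponding entries.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValidationError("matrices must share the sample axis")
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(asd, bsd)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)
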