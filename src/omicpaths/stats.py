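"""Shared statistical kernels.

All enrichment-style questions in this package reduce to three pieces:
a one-sided hypergeometric over-representation tail, a one-sided exact
binomial upper tail, and Fisher's method for combining independent
P-values (−2 Σ ln pᵢ against χ² with 2m degrees of freedom). Multiple
testing is controlled with Benjamini–Hochberg step-up FDR.

P-values are never reported as exactly zero: they are floored at the
smallest positive normal float, with a warning.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedTestError, ValidationError

P_FLOOR = sys.float_info.min  # smallest positive normal double


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts feeding the over-representation test.

    k: significant features in the set; n: measured features in the set;
    K: significant features in the background; N: measured background.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n <= self.N):
            raise ValidationError(f"invalid counts: need 0 <= k <= n <= N, got {self}")
        if not (self.k <= self.K <= self.N):
            raise ValidationError(f"invalid counts: need k <= K <= N, got {self}")
        if self.n - self.k > self.N - self.K:
            raise ValidationError(
                f"invalid counts: non-significant in set exceeds background, {self}"
            )


def floor_pvalue(p: float, context: str = "") -> float:
    """Clamp a P-value into (0, 1], warning when an exact zero is floored."""
    if p <= 0.0:
        warnings.warn(
            f"P-value underflowed to {p!r}{' in ' + context if context else ''}; "
            f"floored at {P_FLOOR:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
        return P_FLOOR
    return min(float(p), 1.0)


def fisher_exact_enrichment(c: ContingencyCounts) -> float:
    """One-sided (over-representation) hypergeometric tail P(X >= k).

    X ~ Hypergeometric(N, K, n): k significant among n drawn from a
    background of N containing K significant.
    """
    if c.n == 0:
        raise UndefinedTestError("enrichment test undefined for n = 0")
    p = sps.hypergeom.sf(c.k - 1, c.N, c.K, c.n)
    return floor_pvalue(p, "hypergeometric tail")


def binomial_tail(k: int, n: int, p0: float) -> float:
    """One-sided exact binomial upper tail P(X >= k), X ~ Binomial(n, p0)."""
    if n < 1:
        raise UndefinedTestError("binomial test undefined for n = 0")
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"null proportion must be in (0, 1), got {p0}")
    p = sps.binom.sf(k - 1, n, p0)
    return floor_pvalue(p, "binomial tail")


def combine_pvalues_fisher(ps: Sequence[float]) -> float:
    """Fisher's combined probability: χ²(2m) upper tail of −2 Σ ln pᵢ."""
    if len(ps) == 0:
        raise ValidationError("cannot combine an empty list of P-values")
    arr = np.asarray(ps, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValidationError(
            "P-values must lie in (0, 1]; floor zeros before combining"
        )
    x = -2.0 * float(np.log(arr).sum())
    return floor_pvalue(sps.chi2.sf(x, 2 * len(arr)), "Fisher combination")


def adjust_bh(ps: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P-values, input order preserved."""
    arr = np.asarray(ps, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValidationError("P-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def midrank_percentile(value: float, values: Sequence[float]) -> float:
    """Midrank percentile of ``value`` within ``values`` (which contains it).

    (count strictly below + half the tied count) / total × 100, so a full
    tie yields 50.0 and a unique maximum among m values yields
    100 · (m − 0.5) / m.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty reference distribution")
    below = int(np.sum(arr < value))
    ties = int(np.sum(arr == value))
    if ties == 0:
        raise ValidationError("queried value absent from reference distribution")
    return 100.0 * (below + 0.5 * ties) / arr.size
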