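"""Shared statistical tests (Fisher exact, two-sample KS).

Thin wrappers over scipy with the exact conventions the pipeline relies
on: the two-sided Fisher p sums hypergeometric probability mass <= that of
the observed table (ties included), and the KS p-value uses exact
small-sample computation when n*m <= 10^4, the asymptotic Kolmogorov
distribution otherwise.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Uses probability-mass ordering (the conventional exact definition;
    other tie-breaking conventions can differ on degenerate tables).
    An all-zero table has p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns (D, p) where D = sup |ECDF_x - ECDF_y|.  The p-value is exact
    for small samples (n*m <= 10^4) and asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if x.size * y.size <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)
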