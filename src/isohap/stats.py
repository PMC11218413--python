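"""Shared statistical core: exact Fisher test and multiple-testing adjustment.

Every contingency-table test in this package (haplotype bias, differential
editing, editing coordination) routes through :func:`fisher_exact_2x2`.

The two-sided p-value is computed by exact enumeration of the conditional
hypergeometric distribution using integer arithmetic: a table in the support
contributes to the p-value iff its probability is <= the observed table's
probability, where the comparison is made on the exact integer numerators
``C(r1, k) * C(r2, c1-k)`` (the denominator ``C(n, c1)`` is shared).  This
avoids any floating-point tie ambiguity; the only rounding is the final
conversion of an exact rational to a float.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["fisher_exact_2x2", "bh_adjust"]

# Above this total the exact big-integer enumeration is wasteful and the
# classic floating implementation is indistinguishable in practice.
_EXACT_LIMIT = 2000


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact test p-value for a 2x2 count table.

    Parameters
    ----------
    table : 2x2 sequence of non-negative ints, ``[[a, b], [c, d]]``.

    Returns
    -------
    float p-value in (0, 1].  Degenerate tables (any zero margin) carry no
    information about association and return 1.0.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    if n > _EXACT_LIMIT:
        from scipy.stats import fisher_exact as _sp_fisher

        return float(_sp_fisher([[a, b], [c, d]], alternative="two-sided")[1])
    obs = comb(r1, a) * comb(r2, c)
    total = comb(n, c1)
    acc = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        term = comb(r1, k) * comb(r2, c1 - k)
        if term <= obs:
            acc += term
    return float(Fraction(acc, total))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
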