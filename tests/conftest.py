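"""Shared independent oracles and fixtures for the test suite.

The oracles here deliberately re-derive results by brute force (per-base
walks, exhaustive window enumeration, naive clustering) so the package's
optimized implementations are checked against an independent route.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial
from typing import Dict, List, Sequence, Tuple

import pytest

from isohap.alignment import DELETION, INSERTION, INTRON, MATCH, MISMATCH

_FACT = [factorial(i) for i in range(201)]


def _choose(n: int, k: int) -> int:
    if k < 0 or k > n:
        return 0
    return _FACT[n] // (_FACT[k] * _FACT[n - k])


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration with exact factorial rationals."""
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    p_obs = Fraction(_choose(r1, a) * _choose(r2, c), _choose(n, c1))
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(_choose(r1, k) * _choose(r2, c1 - k), _choose(n, c1))
        if p_k <= p_obs:
            total += p_k
    return float(total)


def flank_oracle(
    ops: Sequence[Tuple[str, int]],
    target_start: int,
    junction_positions: Sequence[int],
    flank: int = 3,
):
    """Base-by-base walk computing per-junction flank matches and max indel."""
    kinds: Dict[int, str] = {}
    insertions: List[Tuple[int, int]] = []  # (target point, length)
    tpos = target_start
    for kind, length in ops:
        if kind == INSERTION:
            insertions.append((tpos, length))
            continue
        for i in range(length):
            kinds[tpos + i] = kind
        tpos += length
    target_end = tpos
    flank_counts, max_indels = [], []
    for p in junction_positions:
        lo, hi = p - flank, p + flank
        if lo < target_start or hi > target_end:
            flank_counts.append(None)
            max_indels.append(0)
            continue
        flank_counts.append(
            sum(1 for q in range(lo, hi) if kinds.get(q) == MATCH)
        )
        indel = 0
        runs: List[Tuple[int, int]] = []
        run_start = None
        for q in sorted(kinds):
            if kinds[q] == DELETION:
                if run_start is None:
                    run_start = q
            elif run_start is not None:
                runs.append((run_start, q))
                run_start = None
        if run_start is not None:
            runs.append((run_start, target_end))
        for s, e in runs:
            if s < hi and e > lo:
                indel = max(indel, e - s)
        for point, length in insertions:
            if lo <= point <= hi:
                indel = max(indel, length)
        max_indels.append(indel)
    return flank_counts, max_indels


def type2_oracle(
    positions: Sequence[int], window: int = 150, min_sites: int = 3
) -> List[Tuple[int, int, Tuple[int, ...]]]:
    """All-window enumeration of hyperediting regions on one chromosome."""
    pos = sorted(set(positions))
    if len(pos) < min_sites:
        return []
    qualifying = [
        s
        for s in range(pos[0] - window, pos[-1] + 1)
        if sum(1 for p in pos if s <= p < s + window) >= min_sites
    ]
    if not qualifying:
        return []
    merged: List[List[int]] = []
    for s in qualifying:
        lo, hi = s, s + window
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    out = []
    for lo, hi in merged:
        members = tuple(p for p in pos if lo <= p < hi)
        out.append((members[0], members[-1], members))
    return out


def naive_single_linkage(positions: Sequence[int], window: int) -> List[List[int]]:
    """O(n^2) single-linkage clustering used as the end-calling oracle."""
    remaining = sorted(positions)
    clusters: List[List[int]] = []
    while remaining:
        cluster = [remaining.pop(0)]
        changed = True
        while changed:
            changed = False
            for p in list(remaining):
                if any(abs(p - q) <= window for q in cluster):
                    cluster.append(p)
                    remaining.remove(p)
                    changed = True
        clusters.append(sorted(cluster))
    return clusters
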