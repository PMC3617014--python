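"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by a different route than the package:
naive alignment against a linearized repeat pattern, exhaustive candidate
enumeration over every (start, end, unit class), full pmf/permutation
enumeration for the exact tests, and hypergeometric tail sums for Fisher.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from numba import njit

_BASES = "ACGT"


def naive_wraparound_score(seq: str, unit: str, match=2, mismatch=7, indel=7) -> int:
    """Needleman-Wunsch of seq against a long linear repetition of unit.

    Start and end positions in the pattern are free; all of seq is consumed.
    Equivalent to the wraparound formulation but computed over an explicit
    linear pattern, so it cannot share bugs with the ring DP.
    """
    n = len(seq)
    if n == 0:
        return 0
    p = len(unit)
    pattern = unit * (((n + 1) * p + n) // p + 2)
    L = len(pattern)
    prev = [0] * (L + 1)  # free start anywhere in the pattern
    for i in range(1, n + 1):
        cur = [prev[0] - indel * i] * (L + 1)
        c = seq[i - 1]
        for j in range(1, L + 1):
            s = match if (c == pattern[j - 1] and c != "N") else -mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] - indel, cur[j - 1] - indel)
        prev = cur
    return max(prev)  # free end anywhere in the pattern


@njit(cache=False)
def _scores_for_unit(codes, unit, match, mismatch, indel):  # pragma: no cover
    n = codes.shape[0]
    p = unit.shape[0]
    S = np.full((n, n + 1), -30000, dtype=np.int16)
    row = np.zeros(p, dtype=np.int64)
    new = np.zeros(p, dtype=np.int64)
    for i in range(n):
        for k in range(p):
            row[k] = 0
        for j in range(i + 1, n + 1):
            c = codes[j - 1]
            for k in range(p):
                pk = (k - 1) % p
                s = match if c == unit[pk] else -mismatch
                a = row[pk] + s
                b = row[k] - indel
                new[k] = a if a >= b else b
            for _ in range(2):
                for k in range(p):
                    d = new[(k - 1) % p] - indel
                    if d > new[k]:
                        new[k] = d
            best = new[0]
            for k in range(1, p):
                if new[k] > best:
                    best = new[k]
            S[i, j] = best
            tmp = row
            row = new
            new = tmp
    return S


def _canon(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _oracle_unit_classes(max_period: int) -> list[str]:
    units = list(_BASES)
    if max_period >= 2:
        units += sorted({_canon(a + b) for a in _BASES for b in _BASES}
                        - {a + a for a in _BASES})
    if max_period >= 3:
        units += sorted({_canon(a + b + c) for a in _BASES for b in _BASES for c in _BASES}
                        - {a * 3 for a in _BASES})
    return units


def exhaustive_scan(seq: str, match=2, mismatch=7, indel=7, min_score=40,
                    max_period=3) -> list[tuple[int, int, int, str]]:
    """Score every (substring, unit class) candidate; greedy non-overlap pick.

    Selection order: higher score, then longer, then smaller start, then
    lexicographically smaller canonical unit.  Returns (start, end, score,
    canonical_unit) sorted by start.
    """
    code = {b: i for i, b in enumerate(_BASES)}
    codes = np.array([code.get(b, -1) for b in seq], dtype=np.int64)
    cands: list[tuple[int, int, int, str]] = []
    for cu in _oracle_unit_classes(max_period):
        unit = np.array([code[b] for b in cu], dtype=np.int64)
        S = _scores_for_unit(codes, unit, match, mismatch, indel)
        ii, jj = np.nonzero(S >= min_score)
        for i, j in zip(ii, jj):
            cands.append((int(S[i, j]), int(i), int(j), cu))
    cands.sort(key=lambda c: (-c[0], -(c[2] - c[1]), c[1], c[3]))
    chosen: list[tuple[int, int, int, str]] = []
    for sc, i, j, cu in cands:
        if all(j <= s or i >= e for _, s, e, _ in chosen):
            chosen.append((sc, i, j, cu))
    return sorted((i, j, sc, cu) for sc, i, j, cu in chosen)


def binomial_two_tailed(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-tailed binomial p by full pmf enumeration."""
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    cutoff = pmf[k] * (1 + 1e-7)
    return min(1.0, sum(q for q in pmf if q <= cutoff))


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """U and two-sided p by enumerating every labeling of the pooled sample."""
    pooled = list(x) + list(y)
    n1 = len(x)
    idx = range(len(pooled))

    def u_of(subset) -> float:
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in idx if i not in subset]
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_of(set(range(n1)))
    us = [u_of(set(c)) for c in combinations(idx, n1)]
    lower = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    upper = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return u_obs, min(1.0, 2 * min(lower, upper))


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher p by hypergeometric tail sum."""
    N = a + b + c + d
    K = a + c  # items with the property
    n = a + b  # study size
    denom = math.comb(N, n)
    hi = min(K, n)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k) for k in range(a, hi + 1)
    ) / denom
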