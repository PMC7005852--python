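"""Numba-compiled inner loops for read merging and global alignment.

Kept separate from the public modules so the compiled surface stays small
and the pure-Python wrappers remain easy to test against brute-force
oracles.
"""

import numpy as np
from numba import njit

_N = 78  # ord('N'): never matches anything, including another N


@njit(cache=True)
def best_ungapped_overlap(s1, s2rc, min_overlap, max_mismatch_frac):
    """Scan all ungapped overlaps between the 3' end of mate 1 and the 5'
    end of reverse-complemented mate 2.

    Returns (overlap_len, score) of the highest-scoring valid overlap with
    score = matches - mismatches; ties go to the longer overlap.  Returns
    (0, 0.0) when no overlap of length >= min_overlap keeps its mismatch
    fraction <= max_mismatch_frac.
    """
    n1 = s1.size
    n2 = s2rc.size
    omax = min(n1, n2)
    best_o = 0
    best_score = -1.0e18
    for o in range(omax, min_overlap - 1, -1):
        limit = int(max_mismatch_frac * o)
        mm = 0
        ok = True
        off = n1 - o
        for k in range(o):
            a = s1[off + k]
            b = s2rc[k]
            if a == _N or b == _N or a != b:
                mm += 1
                if mm > limit:
                    ok = False
                    break
        if ok:
            score = float(o - 2 * mm)
            if score > best_score:
                best_score = score
                best_o = o
    if best_o == 0:
        return 0, 0.0
    return best_o, best_score


@njit(cache=True)
def gotoh_global(a, b, match, mismatch, gap_open, gap_ext):
    """Affine-gap global alignment (Gotoh) of query `a` against reference
    `b`; a gap of length L costs gap_open + (L-1)*gap_ext.

    Tie-breaking prefers match/mismatch over deletion over insertion, which
    makes the traceback deterministic.  Returns (score, ops) where ops is a
    uint8 array over alignment columns: 0 = M (consumes both), 1 = D
    (consumes reference), 2 = I (consumes query).
    """
    n = a.size
    m = b.size
    NEG = -1.0e30
    M = np.full((n + 1, m + 1), NEG)
    D = np.full((n + 1, m + 1), NEG)
    I = np.full((n + 1, m + 1), NEG)
    pm = np.zeros((n + 1, m + 1), np.int8)
    pd = np.zeros((n + 1, m + 1), np.int8)
    pi = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        D[0, j] = -(gap_open + (j - 1) * gap_ext)
        pd[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        I[i, 0] = -(gap_open + (i - 1) * gap_ext)
        pi[i, 0] = 2 if i > 1 else 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            s = match if (ai == bj and ai != _N and bj != _N) else mismatch
            # M: diagonal from any state, prefer M > D > I
            best = M[i - 1, j - 1]
            p = 0
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
                p = 1
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pm[i, j] = p
            # D: gap in query (reference base skipped)
            best = M[i, j - 1] - gap_open
            p = 0
            if D[i, j - 1] - gap_ext > best:
                best = D[i, j - 1] - gap_ext
                p = 1
            if I[i, j - 1] - gap_open > best:
                best = I[i, j - 1] - gap_open
                p = 2
            D[i, j] = best
            pd[i, j] = p
            # I: gap in reference (query base inserted)
            best = M[i - 1, j] - gap_open
            p = 0
            if D[i - 1, j] - gap_open > best:
                best = D[i - 1, j] - gap_open
                p = 1
            if I[i - 1, j] - gap_ext > best:
                best = I[i - 1, j] - gap_ext
                p = 2
            I[i, j] = best
            pi[i, j] = p
    state = 0
    score = M[n, m]
    if D[n, m] > score:
        score = D[n, m]
        state = 1
    if I[n, m] > score:
        score = I[n, m]
        state = 2
    ops = np.empty(n + m, np.uint8)
    k = n + m
    i = n
    j = m
    while i > 0 or j > 0:
        k -= 1
        ops[k] = state
        if state == 0:
            state = pm[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pd[i, j]
            j -= 1
        else:
            state = pi[i, j]
            i -= 1
    return score, ops[k:]
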