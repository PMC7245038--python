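"""Affine-gap dynamic-programming kernels (Gotoh), numba-jitted when available.

State convention: M = diagonal (match/mismatch), X = gap in the second
sequence (consumes a), Y = gap in the first sequence (consumes b).
A gap of length k costs gap_open + (k-1) * gap_extend.

Bases with code >= 4 (N, mask) never match.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

NEG = -(2**30)


@njit(cache=False)
def gotoh_global(a, b, match, mismatch, gap_open, gap_ext):
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_ext
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_ext
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p

            bx = M[i - 1, j] + gap_open
            px = 0
            if X[i - 1, j] + gap_ext > bx:
                bx = X[i - 1, j] + gap_ext
                px = 1
            if Y[i - 1, j] + gap_open > bx:
                bx = Y[i - 1, j] + gap_open
                px = 2
            X[i, j] = bx
            pX[i, j] = px

            by = M[i, j - 1] + gap_open
            py = 0
            if X[i, j - 1] + gap_open > by:
                by = X[i, j - 1] + gap_open
                py = 1
            if Y[i, j - 1] + gap_ext > by:
                by = Y[i, j - 1] + gap_ext
                py = 2
            Y[i, j] = by
            pY[i, j] = py
    return M, X, Y, pM, pX, pY


@njit(cache=False)
def gotoh_local(a, b, match, mismatch, gap_open, gap_ext):
    """Smith-Waterman with affine gaps; returns matrices and the best cell."""
    n = a.shape[0]
    m = b.shape[0]
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    pM = np.full((n + 1, m + 1), 3, dtype=np.uint8)  # 3 = alignment start
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            # tie-break: diagonal > up > left > fresh start
            prev = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
                p = 2
            if prev < 0:
                prev = 0
                p = 3
            cand = prev + s
            if cand <= 0:
                M[i, j] = 0
                pM[i, j] = 3
            else:
                M[i, j] = cand
                pM[i, j] = p
            bx = M[i - 1, j] + gap_open
            px = 0
            if X[i - 1, j] + gap_ext > bx:
                bx = X[i - 1, j] + gap_ext
                px = 1
            X[i, j] = bx
            pX[i, j] = px
            by = M[i, j - 1] + gap_open
            py = 0
            if Y[i, j - 1] + gap_ext > by:
                by = Y[i, j - 1] + gap_ext
                py = 2
            Y[i, j] = by
            pY[i, j] = py
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    return M, X, Y, pM, pX, pY, best, bi, bj
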