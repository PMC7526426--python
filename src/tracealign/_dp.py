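"""Global alignment DP kernel (Needleman-Wunsch with affine-open gaps).

Gap model: each maximal gap run costs ``gap_open`` once; extension is free.
Three-state Gotoh recursion with a deterministic tie-break during traceback:
match > gap-in-second-sequence (consume i) > gap-in-first-sequence
(consume j). The kernel is JIT-compiled with numba when available; a pure
NumPy/Python fallback keeps the semantics identical.
"""

from __future__ import annotations

import numpy as np

NEG_INF = -1e300

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def _gotoh_kernel(S, gap_open):  # pragma: no cover - compiled
    n1, n2 = S.shape
    M = np.full((n1 + 1, n2 + 1), NEG_INF)
    X = np.full((n1 + 1, n2 + 1), NEG_INF)  # gap in second seq: consume i
    Y = np.full((n1 + 1, n2 + 1), NEG_INF)  # gap in first seq: consume j
    pM = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    pX = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    pY = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        X[i, 0] = gap_open
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, n2 + 1):
        Y[0, j] = gap_open
        pY[0, j] = 0 if j == 1 else 2

    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            # match state: tie order M > X > Y
            best = M[i - 1, j - 1]
            state = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                state = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                state = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = state

            # gap in second sequence (advance i)
            best = M[i - 1, j] + gap_open
            state = 0
            if X[i - 1, j] > best:
                best = X[i - 1, j]
                state = 1
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                state = 2
            X[i, j] = best
            pX[i, j] = state

            # gap in first sequence (advance j)
            best = M[i, j - 1] + gap_open
            state = 0
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                state = 1
            if Y[i, j - 1] > best:
                best = Y[i, j - 1]
                state = 2
            Y[i, j] = best
            pY[i, j] = state

    # final state, same tie order
    best = M[n1, n2]
    state = 0
    if X[n1, n2] > best:
        best = X[n1, n2]
        state = 1
    if Y[n1, n2] > best:
        best = Y[n1, n2]
        state = 2

    pairs = np.empty((min(n1, n2), 2), dtype=np.int64)
    k = 0
    i, j = n1, n2
    while i > 0 or j > 0:
        if state == 0:
            pairs[k, 0] = i - 1
            pairs[k, 1] = j - 1
            k += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
    return best, pairs[:k][::-1].copy()


def gotoh_align(S: np.ndarray, gap_open: float) -> tuple[float, np.ndarray]:
    """Align the rows/columns of score matrix ``S``; returns (score, pairs).

    ``pairs`` is a (k, 2) int array of matched (i, j) indices, strictly
    increasing in both columns. An empty matrix yields an empty alignment
    with score 0.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    if S.ndim != 2:
        raise ValueError("score matrix must be 2-D")
    if S.size and not np.isfinite(S).all():
        raise ValueError("score matrix must be finite")
    if S.shape[0] == 0 or S.shape[1] == 0:
        return 0.0, np.empty((0, 2), dtype=np.int64)
    score, pairs = _gotoh_kernel(S, float(gap_open))
    return float(score), pairs
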