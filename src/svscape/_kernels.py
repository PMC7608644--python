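"""Numba kernels: scaled pair-HMM forward-backward, maximum-expected-
accuracy alignment DP, and local wraparound dynamic programming for tandem
repeats.  Pure numerical code; all domain logic lives in the calling
modules."""

from __future__ import annotations

import numpy as np
from numba import njit

# states: 0 = match, 1 = insert-x (gap in y), 2 = insert-y (gap in x)


@njit(cache=True)
def pair_forward_backward(xc, yc, trans, init, em_m, em_i):
    """Posterior match probabilities P(x_i ~ y_j) for two encoded sequences
    under the 3-state pair-HMM, by scaled forward-backward.

    Returns (posterior matrix n x m, log-likelihood).
    """
    n, m = xc.size, yc.size
    alpha = np.zeros((n + 1, m + 1, 3))
    logr = np.zeros(n + 1)

    # forward, row by row (a row shares the same cumulative scale)
    for j in range(1, m + 1):
        e = em_i[yc[j - 1]]
        if j == 1:
            alpha[0, 1, 2] = init[2] * e
        else:
            alpha[0, j, 2] = alpha[0, j - 1, 2] * trans[2, 2] * e
    s = alpha[0].sum()
    inv_scale0 = 1.0
    if s > 0.0:
        alpha[0] /= s
        logr[0] = np.log(s)
        inv_scale0 = 1.0 / s
    for i in range(1, n + 1):
        exi = em_i[xc[i - 1]]
        for j in range(0, m + 1):
            if j > 0:
                emm = em_m[xc[i - 1], yc[j - 1]]
                if i == 1 and j == 1:
                    # initial term enters on row 0's scale
                    alpha[i, j, 0] = init[0] * emm * inv_scale0
                else:
                    alpha[i, j, 0] = emm * (
                        alpha[i - 1, j - 1, 0] * trans[0, 0]
                        + alpha[i - 1, j - 1, 1] * trans[1, 0]
                        + alpha[i - 1, j - 1, 2] * trans[2, 0]
                    )
            if i == 1 and j == 0:
                alpha[i, j, 1] = init[1] * exi * inv_scale0
            else:
                alpha[i, j, 1] = exi * (
                    alpha[i - 1, j, 0] * trans[0, 1] + alpha[i - 1, j, 1] * trans[1, 1]
                )
            if j > 0:
                eyj = em_i[yc[j - 1]]
                alpha[i, j, 2] = eyj * (
                    alpha[i, j - 1, 0] * trans[0, 2] + alpha[i, j - 1, 2] * trans[2, 2]
                )
        s = alpha[i].sum()
        if s > 0.0:
            alpha[i] /= s
            logr[i] = np.log(s)

    # backward
    beta = np.zeros((n + 1, m + 1, 3))
    logq = np.zeros(n + 1)
    beta[n, m, 0] = 1.0
    beta[n, m, 1] = 1.0
    beta[n, m, 2] = 1.0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            for st in range(3):
                v = 0.0
                if i < n and j < m:
                    v += trans[st, 0] * em_m[xc[i], yc[j]] * beta[i + 1, j + 1, 0]
                if i < n and st != 2:
                    v += trans[st, 1] * em_i[xc[i]] * beta[i + 1, j, 1]
                if j < m and st != 1:
                    v += trans[st, 2] * em_i[yc[j]] * beta[i, j + 1, 2]
                beta[i, j, st] = v
        s = beta[i].sum()
        if s > 0.0:
            beta[i] /= s
            logq[i] = np.log(s)

    cum_r = np.cumsum(logr)
    cum_q = np.zeros(n + 1)
    acc = 0.0
    for i in range(n, -1, -1):
        acc += logq[i]
        cum_q[i] = acc
    loglik = np.log(alpha[n, m, 0] + alpha[n, m, 1] + alpha[n, m, 2]) + cum_r[n]

    post = np.zeros((n, m))
    for i in range(1, n + 1):
        f = np.exp(cum_r[i] + cum_q[i] - loglik)
        for j in range(1, m + 1):
            p = alpha[i, j, 0] * beta[i, j, 0] * f
            if p > 1.0:
                p = 1.0
            post[i - 1, j - 1] = p
    return post, loglik


@njit(cache=True)
def mea_align(S):
    """Maximum-expected-accuracy alignment of two profiles given the summed
    posterior score matrix S; gaps score 0.  Returns the move sequence
    (0 = both, 1 = advance first, 2 = advance second) in order."""
    n, m = S.shape
    D = np.zeros((n + 1, m + 1))
    back = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        back[i, 0] = 1
        D[i, 0] = 0.0
    for j in range(1, m + 1):
        back[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = D[i - 1, j - 1] + S[i - 1, j - 1]
            move = 0
            if D[i - 1, j] > best:
                best = D[i - 1, j]
                move = 1
            if D[i, j - 1] > best:
                best = D[i, j - 1]
                move = 2
            D[i, j] = best
            back[i, j] = move
    moves = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        mv = back[i, j]
        k -= 1
        moves[k] = mv
        if mv == 0:
            i -= 1
            j -= 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    return moves[k:], D[n, m]


@njit(cache=True)
def wraparound_local(seq_codes, cons_codes, match, mismatch, indel):
    """Best local alignment of a sequence against a cyclic consensus
    (wraparound dynamic programming).  Diagonal and vertical moves may wrap
    from the last consensus column to the first; scores below zero restart.

    Returns (score, tract_start, tract_end) with the tract given in
    sequence coordinates (0-based, half-open)."""
    n, p = seq_codes.size, cons_codes.size
    H = np.zeros((n + 1, p + 1))
    start = np.zeros((n + 1, p + 1), dtype=np.int64)
    for j in range(p + 1):
        start[0, j] = 0
    best, bi, bs = 0.0, 0, 0
    for i in range(1, n + 1):
        start[i, 0] = i
        for j in range(1, p + 1):
            jm1 = j - 1 if j > 1 else p
            sub = match if seq_codes[i - 1] == cons_codes[j - 1] else -mismatch
            # diagonal (wraps past the consensus origin), vertical (gap in
            # consensus), horizontal (gap in sequence; no wrap)
            v = H[i - 1, jm1] + sub
            st = start[i - 1, jm1]
            w = H[i - 1, j] - indel
            if w > v:
                v = w
                st = start[i - 1, j]
            if j > 1:
                w = H[i, j - 1] - indel
                if w > v:
                    v = w
                    st = start[i, j - 1]
            if v < 0.0:
                v = 0.0
                st = i
            H[i, j] = v
            start[i, j] = st
            if v > best:
                best = v
                bi = i
                bs = st
    return best, bs, bi
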