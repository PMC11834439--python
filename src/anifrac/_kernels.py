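"""Numba kernels for banded affine-gap extension alignment.

Two passes per extension arm: an x-drop scan that finds the best-scoring
end cell, then a banded global alignment with traceback over the clipped
region to count matched and aligned columns.  Both work on small int8
code arrays and a dense substitution matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**8))


@njit(cache=True)
def xdrop_extend(q, t, subst, gap_open, gap_extend, band, zdrop):
    """Extend from (0,0) maximizing path score; stop on z-drop.

    Returns (best_score, q_ext, t_ext): the number of query / target
    symbols consumed by the best-scoring extension (0,0 allowed).  The
    path is anchored at the origin (no free start), scores may dip but
    a row whose maximum falls more than ``zdrop`` below the running best
    terminates the scan.
    """
    n = q.shape[0]
    m = t.shape[0]
    width = 2 * band + 1
    goe = gap_open + gap_extend

    H = np.full(width, NEG, dtype=np.int32)
    E = np.full(width, NEG, dtype=np.int32)  # gap in query (consumes target)
    F = np.full(width, NEG, dtype=np.int32)  # gap in target (consumes query)
    H[band] = 0  # cell (0, 0)

    best = np.int32(0)
    best_i = 0
    best_j = 0

    # row 0: only horizontal gaps from origin
    for o in range(band + 1, width):
        j = o - band
        if j > m:
            break
        E[o] = -(gap_open + gap_extend * j)
        H[o] = E[o]

    for i in range(1, n + 1):
        Hp = H.copy()
        Ep = E.copy()
        Fp = F.copy()
        H[:] = NEG
        E[:] = NEG
        F[:] = NEG
        row_best = NEG
        lo = band - i if i < band else 0
        for o in range(lo, width):
            j = i + o - band
            if j < 0:
                continue
            if j > m:
                break
            # F: gap in target, from (i-1, j) = previous row, offset o+1
            if o + 1 < width:
                f_open = Hp[o + 1] - goe
                f_ext = Fp[o + 1] - gap_extend
                F[o] = f_open if f_open >= f_ext else f_ext
            # E: gap in query, from (i, j-1) = same row, offset o-1
            if o - 1 >= 0:
                e_open = H[o - 1] - goe
                e_ext = E[o - 1] - gap_extend
                E[o] = e_open if e_open >= e_ext else e_ext
            # diagonal from (i-1, j-1): previous row, same offset
            h = NEG
            if j >= 1 and Hp[o] > NEG:
                h = Hp[o] + subst[q[i - 1], t[j - 1]]
            if E[o] > h:
                h = E[o]
            if F[o] > h:
                h = F[o]
            H[o] = h
            if h > row_best:
                row_best = h
            if h > best:
                best = h
                best_i = i
                best_j = j
        if row_best < best - zdrop:
            break

    return best, best_i, best_j


@njit(cache=True)
def banded_global_stats(q, t, subst, gap_open, gap_extend, band, ncode):
    """Banded global alignment of q vs t with traceback.

    Returns (score, matches, columns).  ``ncode`` is the symbol code that
    never counts as a match (N / X) even when equal on both sides.
    """
    n = q.shape[0]
    m = t.shape[0]
    width = 2 * band + 1
    goe = gap_open + gap_extend

    H = np.full((n + 1, width), NEG, dtype=np.int32)
    E = np.full((n + 1, width), NEG, dtype=np.int32)
    F = np.full((n + 1, width), NEG, dtype=np.int32)
    # traceback: bits 0-1 H came from {0 diag, 1 E, 2 F}; bit 2 E-extend; bit 3 F-extend
    tb = np.zeros((n + 1, width), dtype=np.uint8)

    H[0, band] = 0
    for o in range(band + 1, width):
        j = o - band
        if j > m:
            break
        E[0, o] = -(gap_open + gap_extend * j)
        H[0, o] = E[0, o]
        tb[0, o] = 1 | (4 if j > 1 else 0)

    for i in range(1, n + 1):
        lo = band - i if i < band else 0
        for o in range(lo, width):
            j = i + o - band
            if j < 0:
                continue
            if j > m:
                break
            code = np.uint8(0)
            f = NEG
            if o + 1 < width:
                f_open = H[i - 1, o + 1] - goe
                f_ext = F[i - 1, o + 1] - gap_extend
                if f_ext > f_open:
                    f = f_ext
                    code |= 8
                else:
                    f = f_open
            F[i, o] = f
            e = NEG
            if o - 1 >= 0:
                e_open = H[i, o - 1] - goe
                e_ext = E[i, o - 1] - gap_extend
                if e_ext > e_open:
                    e = e_ext
                    code |= 4
                else:
                    e = e_open
            E[i, o] = e
            h = NEG
            hsrc = np.uint8(0)
            if j >= 1 and H[i - 1, o] > NEG:
                h = H[i - 1, o] + subst[q[i - 1], t[j - 1]]
            if e > h:
                h = e
                hsrc = 1
            if f > h:
                h = f
                hsrc = 2
            H[i, o] = h
            tb[i, o] = code | hsrc

    o_end = m - n + band
    score = H[n, o_end]

    # traceback
    matches = 0
    columns = 0
    i = n
    j = m
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        o = j - i + band
        code = tb[i, o]
        if state == 0:
            src = code & 3
            if src == 0:
                columns += 1
                if q[i - 1] == t[j - 1] and q[i - 1] != ncode:
                    matches += 1
                i -= 1
                j -= 1
            else:
                state = src
        elif state == 1:  # gap in query: consume target
            columns += 1
            j -= 1
            state = 1 if (code & 4) else 0
            # re-read code at new cell next loop
        else:  # gap in target: consume query
            columns += 1
            i -= 1
            state = 2 if (code & 8) else 0

    return score, matches, columns


@njit(cache=True)
def seed_score(q, t, qp, tp, k, subst):
    s = np.int32(0)
    for i in range(k):
        s += subst[q[qp + i], t[tp + i]]
    return s
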