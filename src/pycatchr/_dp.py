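"""Affine-gap dynamic-programming kernels (numba-compiled).

Conventions shared by every kernel and by the brute-force oracles in the test
suite:

* a gap run of length ``k`` costs ``gap_open + (k - 1) * gap_extend``;
* a gap run may follow any state (match or the opposite gap state), paying the
  opening cost whenever the run starts;
* traceback ties are broken diagonal > up (gap in the second input) > left,
  which makes every alignment deterministic;
* local kernels accept per-position gap-cost multipliers so that gap penalties
  can be relaxed inside gap-rich profile columns.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=False)
def nw_fill(S, gap_open, gap_extend):
    """Fill Needleman-Wunsch matrices for score matrix S (m x n).

    Returns (M, Ix, Iy) where Ix consumes rows of S (gap in the column
    sequence) and Iy consumes columns.
    """
    m, n = S.shape
    M = np.full((m + 1, n + 1), NEG)
    Ix = np.full((m + 1, n + 1), NEG)
    Iy = np.full((m + 1, n + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, n + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
            M[i, j] = prev + S[i - 1, j - 1]
            a = M[i - 1, j] - gap_open
            b = Ix[i - 1, j] - gap_extend
            c = Iy[i - 1, j] - gap_open
            Ix[i, j] = max(a, max(b, c))
            a = M[i, j - 1] - gap_open
            b = Iy[i, j - 1] - gap_extend
            c = Ix[i, j - 1] - gap_open
            Iy[i, j] = max(a, max(b, c))
    return M, Ix, Iy


@njit(cache=False)
def nw_traceback(M, Ix, Iy, S, gap_open, gap_extend):
    """Deterministic global traceback.

    Returns (score, xi, yj, length): parallel index arrays over alignment
    columns, -1 marking a gap.
    """
    m, n = M.shape[0] - 1, M.shape[1] - 1
    # state 0 = M (diagonal), 1 = Ix (up), 2 = Iy (left)
    score = M[m, n]
    state = 0
    if Ix[m, n] > score:
        score = Ix[m, n]
        state = 1
    if Iy[m, n] > score:
        score = Iy[m, n]
        state = 2
    xi = np.empty(m + n, dtype=np.int64)
    yj = np.empty(m + n, dtype=np.int64)
    k = 0
    i, j = m, n
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            xi[k] = i - 1
            yj[k] = j - 1
            k += 1
            v = M[i, j] - S[i - 1, j - 1]
            i -= 1
            j -= 1
            if M[i, j] >= v - 1e-12 and M[i, j] <= v + 1e-12:
                state = 0
            elif Ix[i, j] >= v - 1e-12 and Ix[i, j] <= v + 1e-12:
                state = 1
            else:
                state = 2
        elif state == 1:
            xi[k] = i - 1
            yj[k] = -1
            k += 1
            v = Ix[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - gap_open >= v - 1e-12 and M[i, j] - gap_open <= v + 1e-12:
                state = 0
            elif Ix[i, j] - gap_extend >= v - 1e-12 and Ix[i, j] - gap_extend <= v + 1e-12:
                state = 1
            else:
                state = 2
        else:
            xi[k] = -1
            yj[k] = j - 1
            k += 1
            v = Iy[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - gap_open >= v - 1e-12 and M[i, j] - gap_open <= v + 1e-12:
                state = 0
            elif Iy[i, j] - gap_extend >= v - 1e-12 and Iy[i, j] - gap_extend <= v + 1e-12:
                state = 2
            else:
                state = 1
    # reverse
    xo = np.empty(k, dtype=np.int64)
    yo = np.empty(k, dtype=np.int64)
    for t in range(k):
        xo[t] = xi[k - 1 - t]
        yo[t] = yj[k - 1 - t]
    return score, xo, yo


@njit(cache=False)
def nw_score_only(S, gap_open, gap_extend):
    """Global affine score without traceback (two rolling rows)."""
    m, n = S.shape
    Mp = np.full(n + 1, NEG)
    Ixp = np.full(n + 1, NEG)
    Iyp = np.full(n + 1, NEG)
    Mc = np.full(n + 1, NEG)
    Ixc = np.full(n + 1, NEG)
    Iyc = np.full(n + 1, NEG)
    Mp[0] = 0.0
    for j in range(1, n + 1):
        Iyp[j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, m + 1):
        Mc[0] = NEG
        Ixc[0] = -(gap_open + (i - 1) * gap_extend)
        Iyc[0] = NEG
        for j in range(1, n + 1):
            prev = Mp[j - 1]
            if Ixp[j - 1] > prev:
                prev = Ixp[j - 1]
            if Iyp[j - 1] > prev:
                prev = Iyp[j - 1]
            Mc[j] = prev + S[i - 1, j - 1]
            a = Mp[j] - gap_open
            b = Ixp[j] - gap_extend
            c = Iyp[j] - gap_open
            Ixc[j] = max(a, max(b, c))
            a = Mc[j - 1] - gap_open
            b = Iyc[j - 1] - gap_extend
            c = Ixc[j - 1] - gap_open
            Iyc[j] = max(a, max(b, c))
        tmp = Mp
        Mp = Mc
        Mc = tmp
        tmp = Ixp
        Ixp = Ixc
        Ixc = tmp
        tmp = Iyp
        Iyp = Iyc
        Iyc = tmp
    return max(Mp[n], max(Ixp[n], Iyp[n]))


@njit(cache=False)
def sw_fill(S, gap_open, gap_extend, mul_x, mul_y):
    """Smith-Waterman fill with per-position gap-cost multipliers.

    ``mul_x[i]`` scales the cost of gap columns that consume row i of S;
    ``mul_y[j]`` scales gaps consuming column j.
    Returns (H, Ix, Iy, best_score, best_i, best_j).
    """
    m, n = S.shape
    H = np.zeros((m + 1, n + 1))
    Ix = np.full((m + 1, n + 1), NEG)
    Iy = np.full((m + 1, n + 1), NEG)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        gx_o = gap_open * mul_x[i - 1]
        gx_e = gap_extend * mul_x[i - 1]
        for j in range(1, n + 1):
            gy_o = gap_open * mul_y[j - 1]
            gy_e = gap_extend * mul_y[j - 1]
            a = H[i - 1, j] - gx_o
            b = Ix[i - 1, j] - gx_e
            Ix[i, j] = a if a > b else b
            a = H[i, j - 1] - gy_o
            b = Iy[i, j - 1] - gy_e
            Iy[i, j] = a if a > b else b
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if Ix[i, j] > h:
                h = Ix[i, j]
            if Iy[i, j] > h:
                h = Iy[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, Ix, Iy, best, bi, bj


@njit(cache=False)
def sw_traceback(H, Ix, Iy, S, gap_open, gap_extend, mul_x, mul_y, bi, bj):
    """Traceback of the best local alignment.

    Returns (q_start, q_end, t_start, t_end, aln_len, n_pairs), 0-based
    inclusive spans over S rows/columns.
    """
    i, j = bi, bj
    q_end, t_end = bi - 1, bj - 1
    aln_len = 0
    n_pairs = 0
    state = 0
    while i > 0 and j > 0:
        v = H[i, j]
        if state == 0:
            if v <= 0.0:
                break
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            if diag >= v - 1e-12 and diag <= v + 1e-12:
                aln_len += 1
                n_pairs += 1
                i -= 1
                j -= 1
                continue
            if Ix[i, j] >= v - 1e-12 and Ix[i, j] <= v + 1e-12:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            v = Ix[i, j]
            a = H[i - 1, j] - gap_open * mul_x[i - 1]
            i -= 1
            if a >= v - 1e-12 and a <= v + 1e-12:
                state = 0
            # else stay in Ix (extension)
        else:
            aln_len += 1
            v = Iy[i, j]
            a = H[i, j - 1] - gap_open * mul_y[j - 1]
            j -= 1
            if a >= v - 1e-12 and a <= v + 1e-12:
                state = 0
    return i, q_end, j, t_end, aln_len, n_pairs


@njit(cache=False)
def sw_score_only(S, gap_open, gap_extend, mul_x, mul_y):
    """Best local score only (two rolling rows); used for shuffle nulls."""
    m, n = S.shape
    Hp = np.zeros(n + 1)
    Ixp = np.full(n + 1, NEG)
    Hc = np.zeros(n + 1)
    Ixc = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, m + 1):
        gx_o = gap_open * mul_x[i - 1]
        gx_e = gap_extend * mul_x[i - 1]
        Hc[0] = 0.0
        Ixc[0] = NEG
        iy = NEG
        for j in range(1, n + 1):
            a = Hp[j] - gx_o
            b = Ixp[j] - gx_e
            ix = a if a > b else b
            a = Hc[j - 1] - gap_open * mul_y[j - 1]
            b = iy - gap_extend * mul_y[j - 1]
            iy = a if a > b else b
            h = Hp[j - 1] + S[i - 1, j - 1]
            if ix > h:
                h = ix
            if iy > h:
                h = iy
            if h < 0.0:
                h = 0.0
            Hc[j] = h
            Ixc[j] = ix
            if h > best:
                best = h
        tmp = Hp
        Hp = Hc
        Hc = tmp
        tmp = Ixp
        Ixp = Ixc
        Ixc = tmp
    return best


@njit(cache=False)
def sw_score_idx(lo, idx, gap_open, gap_extend, mul_x):
    """Best local score of a profile (log-odds rows) vs an encoded sequence.

    ``lo`` is (n_cols x 20); ``idx`` holds alphabet indices, negative values
    (masked residues) scoring zero. Avoids materializing the full n x m score
    matrix; gaps in the sequence carry unit cost multipliers.
    """
    m = lo.shape[0]
    n = idx.shape[0]
    Hp = np.zeros(n + 1)
    Ixp = np.full(n + 1, NEG)
    Hc = np.zeros(n + 1)
    Ixc = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, m + 1):
        gx_o = gap_open * mul_x[i - 1]
        gx_e = gap_extend * mul_x[i - 1]
        Hc[0] = 0.0
        Ixc[0] = NEG
        iy = NEG
        row = lo[i - 1]
        for j in range(1, n + 1):
            a = Hp[j] - gx_o
            b = Ixp[j] - gx_e
            ix = a if a > b else b
            a = Hc[j - 1] - gap_open
            b = iy - gap_extend
            iy = a if a > b else b
            aj = idx[j - 1]
            s = row[aj] if aj >= 0 else 0.0
            h = Hp[j - 1] + s
            if ix > h:
                h = ix
            if iy > h:
                h = iy
            if h < 0.0:
                h = 0.0
            Hc[j] = h
            Ixc[j] = ix
            if h > best:
                best = h
        tmp = Hp
        Hp = Hc
        Hc = tmp
        tmp = Ixp
        Ixp = Ixc
        Ixc = tmp
    return best


@njit(cache=False)
def sw_score_perm(S, gap_open, gap_extend, mul_x, mul_y, perm):
    """Best local score with columns of S taken in ``perm`` order."""
    m, n = S.shape
    Hp = np.zeros(n + 1)
    Ixp = np.full(n + 1, NEG)
    Hc = np.zeros(n + 1)
    Ixc = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, m + 1):
        gx_o = gap_open * mul_x[i - 1]
        gx_e = gap_extend * mul_x[i - 1]
        Hc[0] = 0.0
        Ixc[0] = NEG
        iy = NEG
        Srow = S[i - 1]
        for j in range(1, n + 1):
            pj = perm[j - 1]
            a = Hp[j] - gx_o
            b = Ixp[j] - gx_e
            ix = a if a > b else b
            a = Hc[j - 1] - gap_open * mul_y[pj]
            b = iy - gap_extend * mul_y[pj]
            iy = a if a > b else b
            h = Hp[j - 1] + Srow[pj]
            if ix > h:
                h = ix
            if iy > h:
                h = iy
            if h < 0.0:
                h = 0.0
            Hc[j] = h
            Ixc[j] = ix
            if h > best:
                best = h
        tmp = Hp
        Hp = Hc
        Hc = tmp
        tmp = Ixp
        Ixp = Ixc
        Ixc = tmp
    return best


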