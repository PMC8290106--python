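"""Independent brute-force oracles used by the test suite.

These enumerate alignment paths explicitly (no affine-state recurrences), so
they share nothing with the package's DP kernels beyond the cost model
definition: a gap run consuming positions p1..pk of one input costs
``open * mul[p1] + extend * (mul[p2] + ... + mul[pk])``.
"""

from __future__ import annotations

import numpy as np


def _enumerate_paths(m: int, n: int):
    """Yield all monotone move strings (D diagonal, U consumes x, L consumes y)."""
    stack = [(0, 0, "")]
    while stack:
        i, j, path = stack.pop()
        if i == m and j == n:
            yield path
            continue
        if i < m and j < n:
            stack.append((i + 1, j + 1, path + "D"))
        if i < m:
            stack.append((i + 1, j, path + "U"))
        if j < n:
            stack.append((i, j + 1, path + "L"))


def _path_score(path, S, go, ge, mul_x, mul_y, i0=0, j0=0):
    score = 0.0
    i, j = i0, j0
    prev = None
    for move in path:
        if move == "D":
            score += S[i, j]
            i += 1
            j += 1
        elif move == "U":
            score -= (ge if prev == "U" else go) * mul_x[i]
            i += 1
        else:
            score -= (ge if prev == "L" else go) * mul_y[j]
            j += 1
        prev = move
    return score


def brute_global(S, go, ge, mul_x=None, mul_y=None):
    """Max score over every global alignment of the full matrices."""
    m, n = S.shape
    mul_x = np.ones(m) if mul_x is None else mul_x
    mul_y = np.ones(n) if mul_y is None else mul_y
    return max(
        _path_score(p, S, go, ge, mul_x, mul_y) for p in _enumerate_paths(m, n)
    )


def brute_local(S, go, ge, mul_x=None, mul_y=None):
    """Max over all substring pairs of the global score, floored at 0."""
    m, n = S.shape
    mul_x = np.ones(m) if mul_x is None else mul_x
    mul_y = np.ones(n) if mul_y is None else mul_y
    best = 0.0
    for i0 in range(m):
        for i1 in range(i0, m):
            for j0 in range(n):
                for j1 in range(j0, n):
                    mm, nn = i1 - i0 + 1, j1 - j0 + 1
                    for p in _enumerate_paths(mm, nn):
                        s = _path_score(
                            p, S, go, ge, mul_x, mul_y, i0=i0, j0=j0
                        )
                        if s > best:
                            best = s
    return best
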