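"""Independent brute-force oracles used by the tests.

The alignment oracle is a straightforward pure-Python Gotoh dynamic
program, written without reference to the package's numba kernel, that
follows the same declared conventions: BLOSUM62, gap of length k costs
open + k*extend, tie preference match > gap-in-second > gap-in-first.
It is quadratic and only meant for short sequences (<= ~60 residues).
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def _sub(x: str, y: str) -> float:
    return float(_BLOSUM[x][y])


def oracle_global(a: str, b: str, gap_open: float = 10.0, gap_ext: float = 1.0):
    """Return (score, aligned_a, aligned_b) for the global alignment."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # a[i-1] vs gap
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap vs b[j-1]
    ptr = {}
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + i * gap_ext)
        ptr[("X", i, 0)] = "M" if i == 1 else "X"
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + j * gap_ext)
        ptr[("Y", 0, j)] = "M" if j == 1 else "Y"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            best, src = M[i - 1][j - 1], "M"
            if X[i - 1][j - 1] > best:
                best, src = X[i - 1][j - 1], "X"
            if Y[i - 1][j - 1] > best:
                best, src = Y[i - 1][j - 1], "Y"
            M[i][j] = best + s
            ptr[("M", i, j)] = src
            best, src = M[i - 1][j] - (gap_open + gap_ext), "M"
            if X[i - 1][j] - gap_ext > best:
                best, src = X[i - 1][j] - gap_ext, "X"
            if Y[i - 1][j] - (gap_open + gap_ext) > best:
                best, src = Y[i - 1][j] - (gap_open + gap_ext), "Y"
            X[i][j] = best
            ptr[("X", i, j)] = src
            best, src = M[i][j - 1] - (gap_open + gap_ext), "M"
            if X[i][j - 1] - (gap_open + gap_ext) > best:
                best, src = X[i][j - 1] - (gap_open + gap_ext), "X"
            if Y[i][j - 1] - gap_ext > best:
                best, src = Y[i][j - 1] - gap_ext, "Y"
            Y[i][j] = best
            ptr[("Y", i, j)] = src
    score, state = M[n][m], "M"
    if X[n][m] > score:
        score, state = X[n][m], "X"
    if Y[n][m] > score:
        score, state = Y[n][m], "Y"
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        src = ptr[(state, i, j)]
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = src
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def oracle_identity(a: str, b: str, gap_open: float = 10.0, gap_ext: float = 1.0) -> float:
    """Identical columns / alignment length for the oracle's global alignment."""
    _, sa, sb = oracle_global(a, b, gap_open, gap_ext)
    same = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return same / len(sa)


def oracle_local(a: str, b: str, gap_open: float = 11.0, gap_ext: float = 1.0):
    """Return (score, aligned_a, aligned_b) for the best local alignment.

    Restart is encoded as a fourth predecessor of the match state and is
    dispreferred on ties, matching the package's declared convention.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr = {}
    best_score, best_i, best_j = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            best, src = M[i - 1][j - 1], "M"
            if X[i - 1][j - 1] > best:
                best, src = X[i - 1][j - 1], "X"
            if Y[i - 1][j - 1] > best:
                best, src = Y[i - 1][j - 1], "Y"
            if best < 0.0:
                best, src = 0.0, "*"
            M[i][j] = best + s
            ptr[("M", i, j)] = src
            if M[i][j] > best_score:
                best_score, best_i, best_j = M[i][j], i, j
            best, src = M[i - 1][j] - (gap_open + gap_ext), "M"
            if X[i - 1][j] - gap_ext > best:
                best, src = X[i - 1][j] - gap_ext, "X"
            if Y[i - 1][j] - (gap_open + gap_ext) > best:
                best, src = Y[i - 1][j] - (gap_open + gap_ext), "Y"
            X[i][j] = best
            ptr[("X", i, j)] = src
            best, src = M[i][j - 1] - (gap_open + gap_ext), "M"
            if X[i][j - 1] - (gap_open + gap_ext) > best:
                best, src = X[i][j - 1] - (gap_open + gap_ext), "X"
            if Y[i][j - 1] - gap_ext > best:
                best, src = Y[i][j - 1] - gap_ext, "Y"
            Y[i][j] = best
            ptr[("Y", i, j)] = src
    if best_score <= 0.0:
        return 0.0, "", ""
    out_a, out_b = [], []
    i, j, state = best_i, best_j, "M"
    while True:
        src = ptr[(state, i, j)]
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        if src == "*" or (i == 0 and j == 0):
            break
        state = src
    return best_score, "".join(reversed(out_a)), "".join(reversed(out_b))
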