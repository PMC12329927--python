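"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities with straightforward quadratic or
exhaustive algorithms in plain Python, independent of the package's numba
kernels and vectorized paths.
"""

from __future__ import annotations

import math
from functools import lru_cache

NEG = float("-inf")


def oracle_score(a: str, b: str, scoring) -> int:
    """Optimal near-free-end-gap affine alignment score, plain-Python DP."""
    match, mismatch, gap_open, gap_extend, end_gap = scoring
    n, m = len(a), len(b)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        H[0][j] = end_gap * j
    for i in range(n + 1):
        H[i][0] = end_gap * i
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    best = H[n][m]
    for j in range(m + 1):
        best = max(best, H[n][j] + end_gap * (m - j))
    for i in range(n + 1):
        best = max(best, H[i][m] + end_gap * (n - i))
    return int(best)


def oracle_distance(a: str, b: str) -> float:
    """Onegap/noendgap distance of the best-scoring alignment.

    Memoized recursion over (i, j, last op) that maximizes the scaled
    distance-dialect score while tracking matches, pair columns, and
    internal gap runs along an optimal path.  Suitable up to ~80 bases.
    """
    MATCH, MISMATCH, OPEN, EXT, END = 10, -10, -20, -10, -1
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def rest(i: int, j: int, last: str):
        # (best score, matches, pair columns, internal gap runs) for tails
        if i == n or j == m:   # trailing terminal gap
            return END * ((n - i) + (m - j)), 0, 0, 0
        cands = []
        s = MATCH if a[i] == b[j] else MISMATCH
        sc, mt, pc, gr = rest(i + 1, j + 1, "p")
        cands.append((s + sc, mt + (a[i] == b[j]), pc + 1, gr))
        cost = EXT if last == "ga" else OPEN
        sc, mt, pc, gr = rest(i, j + 1, "ga")
        cands.append((cost + sc, mt, pc, gr + (last != "ga")))
        cost = EXT if last == "gb" else OPEN
        sc, mt, pc, gr = rest(i + 1, j, "gb")
        cands.append((cost + sc, mt, pc, gr + (last != "gb")))
        return max(cands, key=lambda c: c[0])

    best = None
    for i0 in range(n + 1):   # leading terminal gap skipping a prefix of a
        sc, mt, pc, gr = rest(i0, 0, "start")
        cand = (END * i0 + sc, mt, pc, gr)
        if best is None or cand[0] > best[0]:
            best = cand
    for j0 in range(m + 1):
        sc, mt, pc, gr = rest(0, j0, "start")
        cand = (END * j0 + sc, mt, pc, gr)
        if cand[0] > best[0]:
            best = cand
    rest.cache_clear()
    _, matches, paircols, gapruns = best
    cols = paircols + gapruns
    return 1.0 - matches / cols if cols else 1.0


def oracle_merge(fwd: str, rc_rev: str, min_overlap: int = 10):
    """Exhaustive overlap scoring: (best offset, score, overlap length)."""
    best = (-1, -(10 ** 9), 0)
    for off in range(0, len(fwd) - min_overlap + 1):
        ov = min(len(fwd) - off, len(rc_rev))
        if ov < min_overlap:
            continue
        sc = sum(1 if fwd[off + k] == rc_rev[k] else -1 for k in range(ov))
        if sc > best[1]:
            best = (off, sc, ov)
    return best


def oracle_metrics(tp: int, fp: int, fn: int):
    """Direct evaluation of the printed metric formulas."""
    precision = tp / (tp + fp) * 100.0 if tp + fp else None
    recall = tp / (tp + fn) * 100.0 if tp + fn else None
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    return precision, recall, f1


def oracle_l1(observed: dict[str, float], theoretical: dict[str, float]) -> float:
    taxa = set(observed) | set(theoretical)
    return sum(abs(observed.get(t, 0.0) - theoretical.get(t, 0.0)) for t in taxa)


def oracle_mcc(assignment, close) -> float:
    n = len(assignment)
    tp = fp = fn = tn = 0
    for i in range(n):
        for j in range(i + 1, n):
            tog = assignment[i] == assignment[j]
            if tog and close[i][j]:
                tp += 1
            elif tog:
                fp += 1
            elif close[i][j]:
                fn += 1
            else:
                tn += 1
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / den if den else 0.0
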