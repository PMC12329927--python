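"""Pairwise alignment kernels.

Two dialects are needed and both are free-end-gap (semi-global) affine
Needleman-Wunsch alignments:

* the *distance* dialect used for OTU clustering and 1-NN classification:
  identity = matches / aligned columns where a run of internal gap columns
  counts as a single difference (and a single column), terminal gaps are
  excluded;
* the *search* dialect used by the top-hit classifier: BLAST-like scoring
  (match +2, mismatch -3, gap open -5, gap extend -2), per-column identity,
  and query coverage = fraction of query bases inside the aligned core.

The DP and traceback are written as numba kernels; sequences at the scales
this package targets are a few hundred bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_ENC_TABLE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENC_TABLE[ord(_c)] = _i
    _ENC_TABLE[ord(_c.lower())] = _i

NEG = np.int32(-(10 ** 8))


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3, anything else (ambiguity) as 4."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _dp_traceback(a, b, match, mismatch, gap_open, gap_extend, end_gap):  # pragma: no cover
    """Free-end-gap affine NW.  Returns (score, ops, i0, j0, i1, j1).

    ``ops`` is the core alignment 5'->3': 0 = pair column, 1 = gap in a
    (consumes b), 2 = gap in b (consumes a).  The core spans a[i0:i1] and
    b[j0:j1]; everything outside is terminal gap.  ``gap_open`` is the cost
    of the first gap base, ``gap_extend`` of each subsequent one.
    ``end_gap`` is a token per-column cost on terminal gaps: they stay
    effectively free (and are excluded from identity), but the token cost
    anchors the optimum to a spanning core instead of a degenerate few-base
    chance overlap between unrelated sequences.
    """
    n, m = len(a), len(b)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    E = np.empty((n + 1, m + 1), dtype=np.int32)  # gap in a, consumes b
    F = np.empty((n + 1, m + 1), dtype=np.int32)  # gap in b, consumes a
    PH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 diag, 1 from E, 2 from F
    PE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = extended
    PF = np.zeros((n + 1, m + 1), dtype=np.uint8)

    for j in range(m + 1):
        H[0, j] = end_gap * j   # near-free leading terminal gap
        E[0, j] = NEG
        F[0, j] = NEG
    for i in range(1, n + 1):
        H[i, 0] = end_gap * i
        E[i, 0] = NEG
        F[i, 0] = NEG

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1] + gap_extend
            if ee > eo:
                E[i, j] = ee
                PE[i, j] = 1
            else:
                E[i, j] = eo
                PE[i, j] = 0
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j] + gap_extend
            if fe > fo:
                F[i, j] = fe
                PF[i, j] = 1
            else:
                F[i, j] = fo
                PF[i, j] = 0
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            best = H[i - 1, j - 1] + s
            src = np.uint8(0)
            if E[i, j] > best:
                best = E[i, j]
                src = np.uint8(1)
            if F[i, j] > best:
                best = F[i, j]
                src = np.uint8(2)
            H[i, j] = best
            PH[i, j] = src

    # best end over last row and last column (near-free trailing gaps)
    bi, bj = n, m
    score = H[n, m]
    for j in range(m + 1):
        cand = H[n, j] + end_gap * (m - j)
        if cand > score:
            score = cand
            bi, bj = n, j
    for i in range(n + 1):
        cand = H[i, m] + end_gap * (n - i)
        if cand > score:
            score = cand
            bi, bj = i, m

    ops = np.empty(n + m, dtype=np.uint8)
    k = n + m
    i, j = bi, bj
    state = 0  # 0 in H, 1 in E, 2 in F
    while i > 0 and j > 0:
        if state == 0:
            src = PH[i, j]
            if src == 0:
                k -= 1
                ops[k] = 0
                i -= 1
                j -= 1
            else:
                state = src
        elif state == 1:
            k -= 1
            ops[k] = 1
            ext = PE[i, j]
            j -= 1
            state = 1 if ext == 1 else 0
        else:
            k -= 1
            ops[k] = 2
            ext = PF[i, j]
            i -= 1
            state = 2 if ext == 1 else 0
    return score, ops[k:], i, j, bi, bj


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of one free-end-gap alignment core."""

    score: int
    matches: int
    pair_columns: int        # columns with a base on both sides
    gap_runs: int            # maximal runs of internal gap columns
    gap_columns: int         # individual internal gap columns
    query_span: int          # query bases inside the core
    query_len: int

    @property
    def identity_onegap(self) -> float:
        """matches / (pair columns + gap runs); a gap run is one difference."""
        cols = self.pair_columns + self.gap_runs
        return self.matches / cols if cols else 0.0

    @property
    def identity_percol(self) -> float:
        """matches / all core columns (each gap column counted)."""
        cols = self.pair_columns + self.gap_columns
        return self.matches / cols if cols else 0.0

    @property
    def coverage(self) -> float:
        return self.query_span / self.query_len if self.query_len else 0.0

    @property
    def distance(self) -> float:
        """1 - onegap identity: the clustering distance dialect."""
        return 1.0 - self.identity_onegap


def _stats_from_ops(a: np.ndarray, b: np.ndarray, score: int,
                    ops: np.ndarray, i0: int, j0: int,
                    i1: int, j1: int) -> AlignmentStats:
    matches = 0
    pair_cols = 0
    gap_runs = 0
    gap_cols = 0
    i, j = i0, j0
    prev_gap = False
    for op in ops:
        if op == 0:
            if a[i] == b[j] and a[i] < 4:
                matches += 1
            pair_cols += 1
            i += 1
            j += 1
            prev_gap = False
        else:
            gap_cols += 1
            if not prev_gap:
                gap_runs += 1
            prev_gap = True
            if op == 1:
                j += 1
            else:
                i += 1
    return AlignmentStats(
        score=int(score), matches=matches, pair_columns=pair_cols,
        gap_runs=gap_runs, gap_columns=gap_cols,
        query_span=i1 - i0, query_len=len(a),
    )


# Scores are x10 integers so the terminal-gap anchor can be a tenth of a
# match.  Distance dialect follows the +1/-1, gap -2/-1 convention.
DIST_SCORING = (10, -10, -20, -10, -1)
# Search dialect for the top-hit classifier (+2/-3, gap open -5, extend -2).
SEARCH_SCORING = (20, -30, -50, -20, -1)


def align_stats(query: str | np.ndarray, ref: str | np.ndarray,
                scoring: tuple[int, ...] = DIST_SCORING) -> AlignmentStats:
    """Align ``query`` against ``ref`` with free end gaps; return core stats."""
    a = encode(query) if isinstance(query, str) else query
    b = encode(ref) if isinstance(ref, str) else ref
    if len(a) == 0 or len(b) == 0:
        return AlignmentStats(0, 0, 0, 0, 0, 0, len(a))
    score, ops, i0, j0, i1, j1 = _dp_traceback(a, b, *scoring)
    return _stats_from_ops(a, b, score, ops, i0, j0, i1, j1)


def distance(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> float:
    """Clustering distance between two sequences (onegap, ends free)."""
    return align_stats(seq_a, seq_b, DIST_SCORING).distance


@njit(cache=True)
def best_ungapped_overlap(f, r, min_overlap):  # pragma: no cover
    """Best ungapped dovetail of r onto f (r starting at offset >= 0 in f).

    Returns (offset, matches - mismatches, overlap_length); offset = -1 when
    no offset leaves at least ``min_overlap`` overlapping bases.  Ties go to
    the smallest offset (longest overlap).
    """
    nf, nr = len(f), len(r)
    best_off = -1
    best_score = -(10 ** 9)
    best_len = 0
    max_off = nf - min_overlap
    for off in range(0, max_off + 1):
        ov = nf - off
        if ov > nr:
            ov = nr
        if ov < min_overlap:
            break
        sc = 0
        for k in range(ov):
            if f[off + k] == r[k] and f[off + k] < 4:
                sc += 1
            else:
                sc -= 1
        if sc > best_score:
            best_score = sc
            best_off = off
            best_len = ov
    return best_off, best_score, best_len


@njit(cache=True)
def hamming(a, b):  # pragma: no cover
    n = len(a)
    d = 0
    for i in range(n):
        if a[i] != b[i] or a[i] >= 4:
            d += 1
    return d
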