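"""Read preprocessing: quality trimming, pair merging, marker extraction,
and ambiguity/homopolymer screening.

Trimming follows the LEADING / TRAILING / SLIDINGWINDOW / MINLEN scheme
(thresholds 10 / 10 / 4:20 / 10 by default).  Pair merging searches the best
ungapped dovetail overlap and resolves mismatches by base quality.  Marker
extraction trims the fixed conserved flank anchors (allowing two mismatches
per anchor, and a partially eroded 5' anchor down to 15 of 25 bases) — an
anchor-based stand-in for HMM boundary detection.  Screening removes
sequences with more than ten ambiguous bases or a single-base run longer
than ten.

Every input read is accounted for exactly once in the stage logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import best_ungapped_overlap, encode
from .records import SequenceRecord, revcomp


@dataclass
class ScreenParams:
    max_ambiguities: int = 10
    max_homopolymer: int = 10

    def __post_init__(self) -> None:
        if self.max_ambiguities < 0 or self.max_homopolymer < 0:
            raise ValueError("screen thresholds must be >= 0")


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------

def quality_trim(read: SequenceRecord, leading_q: int = 10, trailing_q: int = 10,
                 window: int = 4, window_q: float = 20.0,
                 min_len: int = 10) -> SequenceRecord | None:
    """Trim low-quality ends, then cut at the first bad sliding window.

    Order: LEADING -> TRAILING -> SLIDINGWINDOW; reads shorter than
    ``min_len`` afterwards are dropped (returns None).
    """
    if read.qualities is None:
        raise ValueError(f"{read.id}: quality_trim requires qualities")
    q = np.asarray(read.qualities)
    start, end = 0, len(q)
    while start < end and q[start] < leading_q:
        start += 1
    while end > start and q[end - 1] < trailing_q:
        end -= 1
    q = q[start:end]
    cut = len(q)
    if window > 0 and len(q) >= window:
        means = np.convolve(q, np.ones(window) / window, mode="valid")
        bad = np.nonzero(means < window_q)[0]
        if len(bad):
            cut = int(bad[0])
    seq = read.sequence[start:end][:cut]
    if len(seq) < min_len:
        return None
    return SequenceRecord(id=read.id, sequence=seq,
                          qualities=list(q[:cut]), weight=read.weight)


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------

def merge_pairs(fwd: SequenceRecord, rev: SequenceRecord,
                min_overlap: int = 10) -> SequenceRecord | None:
    """Merge a read pair into a contig via the best ungapped overlap.

    The reverse read is reverse-complemented, then slid along the forward
    read; the overlap (>= min_overlap) maximizing matches-minus-mismatches
    wins.  The overlap must reach a score of at least half its length
    (>= 75% identity) or the pair is reported unmerged (returns None).  At
    each overlap mismatch the higher-quality base is kept; quality ties
    become 'N'.
    """
    rc_seq = revcomp(rev.sequence)
    rc_qual = list(reversed(rev.qualities)) if rev.qualities is not None else None
    f_enc = encode(fwd.sequence)
    r_enc = encode(rc_seq)
    off, score, ov = best_ungapped_overlap(f_enc, r_enc, min_overlap)
    if off < 0 or score < 0.5 * ov:
        return None

    f_qual = fwd.qualities if fwd.qualities is not None else [40] * len(fwd)
    if rc_qual is None:
        rc_qual = [40] * len(rc_seq)

    chars = list(fwd.sequence[:off])
    quals = list(f_qual[:off])
    for k in range(ov):
        fb, rb = fwd.sequence[off + k], rc_seq[k]
        fq, rq = f_qual[off + k], rc_qual[k]
        if fb == rb:
            chars.append(fb)
            quals.append(max(fq, rq))
        elif fq > rq:
            chars.append(fb)
            quals.append(fq)
        elif rq > fq:
            chars.append(rb)
            quals.append(rq)
        else:
            chars.append("N")
            quals.append(min(fq, rq))
    # tails beyond the overlap
    if off + ov < len(fwd.sequence):
        chars.extend(fwd.sequence[off + ov:])
        quals.extend(f_qual[off + ov:])
    if ov < len(rc_seq):
        chars.extend(rc_seq[ov:])
        quals.extend(rc_qual[ov:])
    cid = fwd.id.rsplit("/", 1)[0].replace("_R1", "")
    return SequenceRecord(id=cid, sequence="".join(chars), qualities=quals,
                          weight=fwd.weight)


# ---------------------------------------------------------------------------
# Marker extraction
# ---------------------------------------------------------------------------

def _find_anchor(seq_enc: np.ndarray, anchor_enc: np.ndarray,
                 max_mismatch: int = 2) -> int | None:
    """Start of the best full-anchor match with <= max_mismatch, else None."""
    n, m = len(seq_enc), len(anchor_enc)
    best_pos, best_mm = None, max_mismatch + 1
    for pos in range(0, n - m + 1):
        mm = int(np.count_nonzero(seq_enc[pos:pos + m] != anchor_enc))
        if mm < best_mm:
            best_mm, best_pos = mm, pos
            if mm == 0:
                break
    return best_pos if best_mm <= max_mismatch else None


def extract_marker(contig: SequenceRecord, flank_pair: tuple[str, str],
                   max_mismatch: int = 2,
                   min_eroded_anchor: int = 15) -> tuple[SequenceRecord | None, str]:
    """Return the subsequence strictly between the two flank anchors.

    Accepts a 5' anchor eroded from its start down to ``min_eroded_anchor``
    bases (the contig then begins inside the anchor), mirroring how residual
    conserved bases can survive boundary detection.  Returns (record, reason);
    the record is None when an anchor is missing.
    """
    f5, f3 = flank_pair
    s = encode(contig.sequence)
    a5, a3 = encode(f5), encode(f3)

    start = None
    pos5 = _find_anchor(s, a5, max_mismatch)
    if pos5 is not None:
        start = pos5 + len(a5)
    else:
        # eroded 5' anchor: contig starts mid-anchor
        for keep in range(len(f5) - 1, min_eroded_anchor - 1, -1):
            if len(s) < keep:
                continue
            mm = int(np.count_nonzero(s[:keep] != a5[len(a5) - keep:]))
            if mm <= max_mismatch:
                start = keep
                break
    if start is None:
        return None, "missing_5p_anchor"

    pos3 = _find_anchor(s[start:], a3, max_mismatch)
    if pos3 is None:
        return None, "missing_3p_anchor"
    end = start + pos3
    marker = contig.sequence[start:end]
    quals = contig.qualities[start:end] if contig.qualities is not None else None
    return SequenceRecord(id=contig.id, sequence=marker, qualities=quals,
                          weight=contig.weight), "ok"


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def longest_homopolymer(seq: str) -> int:
    best = run = 0
    prev = ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


def screen_sequences(
    seqs: list[SequenceRecord], params: ScreenParams | None = None,
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Drop sequences with too many ambiguities or too long a homopolymer.

    Removal fires iff ambiguity count > max_ambiguities OR longest run >
    max_homopolymer (both thresholds inclusive-keep).  Returns (survivors,
    log of (id, rule)).
    """
    params = params or ScreenParams()
    kept: list[SequenceRecord] = []
    removed: list[tuple[str, str]] = []
    for rec in seqs:
        n_ambig = sum(1 for c in rec.sequence if c not in "ACGT")
        if n_ambig > params.max_ambiguities:
            removed.append((rec.id, "ambiguities"))
            continue
        if longest_homopolymer(rec.sequence) > params.max_homopolymer:
            removed.append((rec.id, "homopolymer"))
            continue
        kept.append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# Stage driver
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    markers: list[SequenceRecord]
    log: dict[str, int]
    rejected: list[tuple[str, str]]


def preprocess_pairs(
    fwd_reads: list[SequenceRecord],
    rev_reads: list[SequenceRecord],
    flank_pair: tuple[str, str],
    screen: ScreenParams | None = None,
    min_overlap: int = 10,
) -> PreprocessResult:
    """trim -> merge -> extract marker -> screen, with per-stage accounting."""
    log = {"input_pairs": len(fwd_reads), "trim_dropped": 0, "unmerged": 0,
           "no_anchor": 0, "screened_out": 0, "markers": 0}
    rejected: list[tuple[str, str]] = []
    contigs: list[SequenceRecord] = []
    for f, r in zip(fwd_reads, rev_reads):
        tf = quality_trim(f)
        tr = quality_trim(r)
        if tf is None or tr is None:
            log["trim_dropped"] += 1
            rejected.append((f.id, "trim"))
            continue
        contig = merge_pairs(tf, tr, min_overlap=min_overlap)
        if contig is None:
            log["unmerged"] += 1
            rejected.append((f.id, "unmerged"))
            continue
        contigs.append(contig)

    markers: list[SequenceRecord] = []
    for c in contigs:
        rec, reason = extract_marker(c, flank_pair)
        if rec is None or len(rec.sequence) == 0:
            log["no_anchor"] += 1
            rejected.append((c.id, reason))
            continue
        markers.append(rec)

    kept, screened = screen_sequences(markers, screen)
    log["screened_out"] = len(screened)
    rejected.extend(screened)
    log["markers"] = len(kept)
    return PreprocessResult(markers=kept, log=log, rejected=rejected)
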