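"""OTU pipeline: dereplication, abundance-aware pre-clustering, de novo
chimera removal, pairwise distances, clustering at 0.03, rare-OTU
filtering, and representative selection.

Clustering implements the MCC-optimizing scheme (OptiClust-style): starting
from singleton OTUs, sequences are iteratively moved to the assignment that
maximizes the Matthews correlation coefficient between "clustered together"
and "within the distance cutoff", with a deterministic sweep order.  A
greedy abundance-sorted complete-linkage clusterer is provided as a
baseline for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._align import align_stats, encode, hamming
from .records import SequenceRecord


@dataclass
class ClusterParams:
    distance_cutoff: float = 0.03
    method: str = "opticlust"      # opticlust | greedy_baseline

    def __post_init__(self) -> None:
        if not 0.0 < self.distance_cutoff < 1.0:
            raise ValueError("distance_cutoff must lie in (0, 1)")
        if self.method not in ("opticlust", "greedy_baseline"):
            raise ValueError(f"unknown clustering method {self.method!r}")


@dataclass
class RareFilterParams:
    min_fraction: float = 0.0005   # OTUs at <= this fraction of reads are removed
    drop_singletons: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError("min_fraction must lie in [0, 1]")


@dataclass
class OTU:
    otu_id: str
    members: dict[str, int]                    # sequence id -> weight
    representative: SequenceRecord
    per_dmc_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.members.values())


# ---------------------------------------------------------------------------
# Dereplication and pre-clustering
# ---------------------------------------------------------------------------

def dereplicate(seqs: list[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse exact duplicates; weight = reads collapsed, id = first seen."""
    by_seq: dict[str, SequenceRecord] = {}
    for rec in seqs:
        hit = by_seq.get(rec.sequence)
        if hit is None:
            by_seq[rec.sequence] = SequenceRecord(
                id=rec.id, sequence=rec.sequence, weight=rec.weight)
        else:
            hit.weight += rec.weight
    return list(by_seq.values())


def _overlay_diffs(a: np.ndarray, b: np.ndarray, max_diffs: int) -> int:
    """Mismatch count under the best ungapped overlay.

    Equal lengths: Hamming.  Unequal: slide the shorter inside the longer;
    the length difference counts toward the diffs.  Returns a value
    > max_diffs early when no overlay can qualify.
    """
    if len(a) == len(b):
        return hamming(a, b)
    if len(a) > len(b):
        a, b = b, a
    ld = len(b) - len(a)
    if ld > max_diffs:
        return max_diffs + 1
    best = max_diffs + 1
    for off in range(ld + 1):
        d = ld + hamming(a, b[off:off + len(a)])
        best = min(best, d)
    return best


def precluster(
    seqs: list[SequenceRecord], max_diffs: int = 2,
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Absorb rare sequences into abundant near-identical ones.

    Sequences are processed in decreasing weight (ties broken by
    lexicographically smaller sequence); each merges its weight into the
    first retained sequence within ``max_diffs`` mismatches (Hamming or
    best ungapped overlay for unequal lengths, length difference counted).
    Returns (retained, merge log of (child_id, parent_id)).
    """
    order = sorted(seqs, key=lambda r: (-r.weight, r.sequence))
    retained: list[SequenceRecord] = []
    enc: list[np.ndarray] = []
    log: list[tuple[str, str]] = []
    for rec in order:
        e = encode(rec.sequence)
        parent = None
        for i, kept in enumerate(retained):
            if abs(len(kept.sequence) - len(rec.sequence)) > max_diffs:
                continue
            if _overlay_diffs(e, enc[i], max_diffs) <= max_diffs:
                parent = kept
                break
        if parent is None:
            retained.append(SequenceRecord(id=rec.id, sequence=rec.sequence,
                                           weight=rec.weight))
            enc.append(e)
        else:
            parent.weight += rec.weight
            log.append((rec.id, parent.id))
    return retained, log


# ---------------------------------------------------------------------------
# Chimera detection
# ---------------------------------------------------------------------------

def _side_profiles(q: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Left-anchored prefix and right-anchored suffix mismatch cumulants.

    left[c]  = mismatches of q[:c] vs p[:c]          (inf when c > len(p))
    right[c] = mismatches of q[c:] vs p right-anchored (inf when too long)
    """
    L = len(q)
    big = 10 ** 6
    left = np.full(L + 1, big, dtype=np.int64)
    n = min(L, len(p))
    mm = (q[:n] != p[:n]).astype(np.int64)
    left[: n + 1] = np.concatenate(([0], np.cumsum(mm)))
    right = np.full(L + 1, big, dtype=np.int64)
    mmr = (q[L - n:] != p[len(p) - n:]).astype(np.int64)
    right[L - n:] = np.concatenate((np.cumsum(mmr[::-1])[::-1], [0]))
    return left, right


def detect_chimeras(
    seqs: list[SequenceRecord],
    min_parent_fold: float = 2.0,
    min_diff_gain: int = 4,
    min_side_identity: float = 0.8,
) -> tuple[list[SequenceRecord], list[str]]:
    """Flag de novo two-parent single-crossover chimeras.

    Queries are visited in ascending weight; candidate parents must be at
    least ``min_parent_fold`` times as abundant as the query.  A query is
    chimeric when some parent-prefix + parent-suffix model at one crossover
    explains it with at least ``min_diff_gain`` fewer mismatches than the
    best single parent, and each side shows >= ``min_side_identity`` to its
    parent segment.  Returns (clean sequences, flagged ids).
    """
    order = sorted(seqs, key=lambda r: (r.weight, r.sequence))
    enc = {r.id: encode(r.sequence) for r in seqs}
    flagged: set[str] = set()
    for rec in order:
        parents = [p for p in seqs
                   if p.id != rec.id and p.id not in flagged
                   and p.weight >= min_parent_fold * rec.weight]
        if len(parents) < 2:
            continue
        q = enc[rec.id]
        L = len(q)
        profiles = {p.id: _side_profiles(q, enc[p.id]) for p in parents}
        best_single = min(
            min(profiles[p.id][0][L], profiles[p.id][1][0]) for p in parents
        )
        cpos = np.arange(L + 1)
        best_two = None
        for pa in parents:
            la = profiles[pa.id][0]
            for pb in parents:
                if pb.id == pa.id:
                    continue
                rb = profiles[pb.id][1]
                total = la + rb
                # each side must be non-trivial and sufficiently identical
                with np.errstate(divide="ignore", invalid="ignore"):
                    left_ok = la <= np.maximum(0, (1 - min_side_identity) * cpos)
                    right_ok = rb <= np.maximum(0, (1 - min_side_identity) * (L - cpos))
                ok = left_ok & right_ok & (cpos >= 1) & (cpos <= L - 1)
                if ok.any():
                    cand = int(total[ok].min())
                    if best_two is None or cand < best_two:
                        best_two = cand
        if best_two is not None and best_single - best_two >= min_diff_gain:
            flagged.add(rec.id)
    clean = [r for r in seqs if r.id not in flagged]
    return clean, sorted(flagged)


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def pairwise_distances(seqs: list[SequenceRecord]) -> np.ndarray:
    """Condensed distance vector (scipy ordering) over the sequences.

    Distance = 1 - identity from a free-end-gap global alignment; identity
    counts matches over aligned columns with each internal gap run as one
    difference and terminal gaps excluded.
    """
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences for pairwise distances")
    enc = [encode(r.sequence) for r in seqs]
    n = len(seqs)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if seqs[i].sequence == seqs[j].sequence:
                out[k] = 0.0
            else:
                out[k] = align_stats(enc[i], enc[j]).distance
            k += 1
    return out


def _square(dist: np.ndarray, n: int) -> np.ndarray:
    sq = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            sq[i, j] = sq[j, i] = dist[k]
            k += 1
    return sq


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def partition_mcc(assignment: list[int], close: np.ndarray) -> float:
    """MCC of (pairs co-clustered) vs (pairs within cutoff)."""
    n = len(assignment)
    tp = fp = fn = tn = 0
    for i in range(n):
        for j in range(i + 1, n):
            together = assignment[i] == assignment[j]
            if together and close[i, j]:
                tp += 1
            elif together:
                fp += 1
            elif close[i, j]:
                fn += 1
            else:
                tn += 1
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0


def _mcc_from_counts(tp: int, fp: int, fn: int, tn: int) -> float:
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0


def cluster(
    seqs: list[SequenceRecord],
    distances: np.ndarray,
    params: ClusterParams | None = None,
    max_iters: int = 100,
) -> list[list[int]]:
    """Partition sequences into OTUs at the distance cutoff.

    Returns clusters as lists of indices into ``seqs``.  The MCC optimizer
    sweeps sequences in deterministic order (weight descending, then id),
    trying each move to a neighbouring cluster or to a fresh singleton, and
    accepts the best strictly-improving move, until a full sweep makes no
    change or ``max_iters`` sweeps have run.
    """
    params = params or ClusterParams()
    n = len(seqs)
    if n == 1:
        return [[0]]
    sq = _square(np.asarray(distances, dtype=float), n)
    close = sq <= params.distance_cutoff
    np.fill_diagonal(close, False)
    order = sorted(range(n), key=lambda i: (-seqs[i].weight, seqs[i].id))

    if params.method == "greedy_baseline":
        clusters: list[list[int]] = []
        for i in order:
            for c in clusters:
                if all(close[i, j] for j in c):
                    c.append(i)
                    break
            else:
                clusters.append([i])
        return [sorted(c) for c in clusters]

    # opticlust-style MCC optimization
    assign = list(range(n))
    neighbours = [np.nonzero(close[i])[0] for i in range(n)]
    total_close = int(close.sum() // 2)
    total_pairs = n * (n - 1) // 2

    def counts() -> tuple[int, int, int, int]:
        tp = fp = 0
        for i in range(n):
            for j in range(i + 1, n):
                if assign[i] == assign[j]:
                    if close[i, j]:
                        tp += 1
                    else:
                        fp += 1
        fn = total_close - tp
        tn = total_pairs - tp - fp - fn
        return tp, fp, fn, tn

    tp, fp, fn, tn = counts()
    for _ in range(max_iters):
        changed = False
        for i in order:
            cur = assign[i]
            cur_members = [j for j in range(n) if assign[j] == cur and j != i]
            cur_close = sum(1 for j in cur_members if close[i, j])
            cur_far = len(cur_members) - cur_close
            # candidate clusters: those holding a close neighbour, plus singleton
            cand_ids = {assign[j] for j in neighbours[i]} - {cur}
            best = (_mcc_from_counts(tp, fp, fn, tn), cur)
            # moving out of current cluster removes its pair contributions
            base_tp = tp - cur_close
            base_fp = fp - cur_far
            base_fn = fn + cur_close
            base_tn = tn + cur_far
            for cid in list(cand_ids) + ([-1] if cur_members else []):
                if cid == -1:   # fresh singleton
                    ntp, nfp, nfn, ntn = base_tp, base_fp, base_fn, base_tn
                else:
                    mem = [j for j in range(n) if assign[j] == cid]
                    add_close = sum(1 for j in mem if close[i, j])
                    add_far = len(mem) - add_close
                    ntp = base_tp + add_close
                    nfp = base_fp + add_far
                    nfn = base_fn - add_close
                    ntn = base_tn - add_far
                m = _mcc_from_counts(ntp, nfp, nfn, ntn)
                if m > best[0] + 1e-12:
                    best = (m, cid)
            if best[1] != cur:
                new_cid = best[1]
                if new_cid == -1:
                    new_cid = max(assign) + 1
                # recompute counts incrementally
                mem = [j for j in range(n) if assign[j] == new_cid and j != i]
                add_close = sum(1 for j in mem if close[i, j])
                add_far = len(mem) - add_close
                tp = tp - cur_close + add_close
                fp = fp - cur_far + add_far
                fn = fn + cur_close - add_close
                tn = tn + cur_far - add_far
                assign[i] = new_cid
                changed = True
        if not changed:
            break

    groups: dict[int, list[int]] = {}
    for i, c in enumerate(assign):
        groups.setdefault(c, []).append(i)
    return [sorted(g) for g in sorted(groups.values(), key=lambda g: g[0])]


# ---------------------------------------------------------------------------
# OTU table construction, rare filtering, representatives
# ---------------------------------------------------------------------------

def make_otus(seqs: list[SequenceRecord], clusters: list[list[int]],
              dmc_id: str | None = None, prefix: str = "otu") -> list[OTU]:
    otus = []
    for k, idxs in enumerate(clusters):
        members = {seqs[i].id: seqs[i].weight for i in idxs}
        rep = pick_representative([seqs[i] for i in idxs])
        otu = OTU(otu_id=f"{prefix}{k + 1:04d}", members=members,
                  representative=rep)
        if dmc_id is not None:
            otu.per_dmc_counts[dmc_id] = otu.total_count
        otus.append(otu)
    return otus


def pick_representative(members: list[SequenceRecord]) -> SequenceRecord:
    """Most abundant member; ties to the lexicographically smaller sequence."""
    if not members:
        raise ValueError("empty OTU has no representative")
    return min(members, key=lambda r: (-r.weight, r.sequence))


def pick_representatives(otus: list[OTU]) -> dict[str, SequenceRecord]:
    return {o.otu_id: o.representative for o in otus}


def filter_rare(
    otus: list[OTU], params: RareFilterParams | None = None,
    threshold_override: float | None = None,
) -> list[OTU]:
    """Remove singleton OTUs and OTUs at <= the abundance threshold.

    The threshold comparison is inclusive (<=); ``threshold_override``
    replaces the default fraction for sweep analyses.
    """
    params = params or RareFilterParams()
    total = sum(o.total_count for o in otus)
    if total <= 0:
        raise ValueError("filter_rare needs a positive total read count")
    thr = params.min_fraction if threshold_override is None else threshold_override
    out = []
    for o in otus:
        if params.drop_singletons and o.total_count == 1:
            continue
        if thr > 0 and o.total_count / total <= thr:
            continue
        out.append(o)
    return out


def run_otu_pipeline(
    markers: list[SequenceRecord],
    dmc_id: str | None = None,
    cluster_params: ClusterParams | None = None,
    rare_params: RareFilterParams | None = None,
    precluster_diffs: int = 2,
    sanger_mode: bool = False,
    skip_rare_filter: bool | None = None,
) -> tuple[list[OTU], dict[str, int]]:
    """unique -> pre.cluster -> chimera removal -> distances -> cluster ->
    rare filter -> representatives.

    ``sanger_mode`` (weight-1 in-silico mixes) skips pre-clustering's
    abundance logic implicitly and skips the rare filter entirely.
    """
    log: dict[str, int] = {"input_reads": sum(r.weight for r in markers)}
    uniq = dereplicate(markers)
    log["unique"] = len(uniq)
    pre, merges = precluster(uniq, max_diffs=precluster_diffs)
    log["preclustered"] = len(pre)
    clean, flagged = detect_chimeras(pre)
    log["chimeric"] = len(flagged)
    if not clean:
        return [], log
    if len(clean) == 1:
        clusters = [[0]]
    else:
        dists = pairwise_distances(clean)
        clusters = cluster(clean, dists, cluster_params)
    prefix = f"{dmc_id}_otu" if dmc_id else "otu"
    otus = make_otus(clean, clusters, dmc_id=dmc_id, prefix=prefix)
    log["otus_raw"] = len(otus)
    skip = sanger_mode if skip_rare_filter is None else skip_rare_filter
    if not skip:
        otus = filter_rare(otus, rare_params)
    log["otus"] = len(otus)
    return otus, log
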