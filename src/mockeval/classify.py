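"""Taxonomic classification of OTU representatives.

Three back-ends:

* :func:`tophit_search` — top-hit alignment search with BLAST-like scoring
  and coverage/identity cutoffs; tied best hits form an equivalence group;
* :func:`nb_classify` — k-mer naive-Bayes with bootstrap confidence (the
  Wang scheme): 8-mer presence models per species, 100 bootstrap rounds
  each scoring a random eighth of the query k-mers, lineage truncated below
  the deepest rank whose agreement reaches the cutoff (80% by default);
* :func:`knn_classify` — single nearest neighbour by alignment distance,
  assigning the neighbour's full lineage without confidence filtering.

Names carrying the "sp"/"unclassified" placeholder convention are demoted
to unclassified at the affected ranks by :func:`truncate_unannotated`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._align import SEARCH_SCORING, align_stats, encode
from .records import (RANKS, ReferenceDatabase, SequenceRecord,
                      is_unannotated)
from .synthetic import rng_for


@dataclass
class TopHitParams:
    min_identity: float = 0.95
    min_coverage: float = 0.80

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_coverage):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class NBParams:
    kmer_size: int = 8
    bootstrap_iters: int = 100
    bootstrap_cutoff: float = 0.80

    def __post_init__(self) -> None:
        if self.kmer_size < 1:
            raise ValueError("kmer_size must be >= 1")
        if not 0.0 <= self.bootstrap_cutoff <= 1.0:
            raise ValueError("bootstrap_cutoff must lie in [0, 1]")


@dataclass
class Hit:
    lineage: tuple[str, ...]
    identity: float
    score: float
    accession: str = ""


@dataclass
class ClassificationResult:
    otu_id: str
    method: str                 # tophit | nb | knn
    marker: str
    database: str
    hit_list: list[Hit] = field(default_factory=list)
    equivalence_group: list[Hit] = field(default_factory=list)
    confidences: dict[str, float] | None = None   # rank -> bootstrap agreement
    assigned: tuple[str, ...] | None = None       # possibly truncated lineage
    unclassified_flag: bool = False
    unclassified_reason: str = ""
    unclassified_ranks: set[str] = field(default_factory=set)

    def name_at(self, level: str) -> str | None:
        """Assigned name at a rank, or None when unclassified there."""
        if self.unclassified_flag or self.assigned is None:
            return None
        if level in self.unclassified_ranks:
            return None
        idx = RANKS.index(level)
        if idx >= len(self.assigned) or not self.assigned[idx]:
            return None
        return self.assigned[idx]

    def group_names_at(self, level: str) -> list[str]:
        """Distinct leading-equivalence-group names at a rank (sorted)."""
        if self.unclassified_flag:
            return []
        if level in self.unclassified_ranks:
            return []
        idx = RANKS.index(level)
        if self.equivalence_group:
            return sorted({h.lineage[idx] for h in self.equivalence_group})
        return [self.assigned[idx]] if self.assigned else []


# ---------------------------------------------------------------------------
# Top-hit search
# ---------------------------------------------------------------------------

def tophit_search(query: SequenceRecord, db: ReferenceDatabase, marker: str,
                  params: TopHitParams | None = None) -> ClassificationResult:
    """Align the query to every reference; keep hits above the identity and
    coverage cutoffs; the leading equivalence group is all hits tied with
    the best on (identity, score)."""
    params = params or TopHitParams()
    entries = db.entries_for(marker)
    if not entries:
        raise ValueError(f"database {db.name!r} has no {marker} entries")
    q = encode(query.sequence)
    hits: list[Hit] = []
    for e in entries:
        st = align_stats(q, encode(e.sequence), SEARCH_SCORING)
        if st.coverage < params.min_coverage:
            continue
        if st.identity_percol < params.min_identity:
            continue
        hits.append(Hit(lineage=e.lineage, identity=st.identity_percol,
                        score=st.score, accession=e.accession))
    hits.sort(key=lambda h: (-h.score, -h.identity, h.accession))
    res = ClassificationResult(otu_id=query.id, method="tophit", marker=marker,
                               database=db.name, hit_list=hits)
    if not hits:
        res.unclassified_flag = True
        res.unclassified_reason = "no_hit"
        return res
    best = hits[0]
    group = [h for h in hits
             if h.score == best.score and h.identity == best.identity]
    res.equivalence_group = group
    res.assigned = best.lineage
    return res


# ---------------------------------------------------------------------------
# Naive Bayes (Wang) with bootstrap
# ---------------------------------------------------------------------------

class KmerModel:
    """Per-species k-mer presence model with Wang-style smoothing.

    Word prior P_i = (n_i + 0.5) / (N + 1) over all N reference sequences;
    species likelihood for word i is (m_i + P_i) / (M + 1) with m_i the
    number of the species' M sequences containing the word.
    """

    def __init__(self, db: ReferenceDatabase, marker: str, k: int = 8):
        entries = db.entries_for(marker)
        if not entries:
            raise ValueError(f"database {db.name!r} has no {marker} entries")
        self.k = k
        self.db_name = db.name
        species: dict[tuple[str, ...], list[set[int]]] = {}
        kmer_ids: dict[str, int] = {}
        for e in entries:
            words = set()
            s = e.sequence
            for i in range(len(s) - k + 1):
                w = s[i:i + k]
                if w not in kmer_ids:
                    kmer_ids[w] = len(kmer_ids)
                words.add(kmer_ids[w])
            species.setdefault(e.lineage, []).append(words)
        self.kmer_ids = kmer_ids
        self.lineages = sorted(species)
        N = sum(len(v) for v in species.values())
        n_words = len(kmer_ids)
        n_i = np.zeros(n_words)
        for sets in species.values():
            for ws in sets:
                for w in ws:
                    n_i[w] += 1
        prior = (n_i + 0.5) / (N + 1)
        # log-likelihood matrix: species x known word
        self.loglik = np.empty((len(self.lineages), n_words))
        self.log_default = np.empty(len(self.lineages))
        for si, lin in enumerate(self.lineages):
            sets = species[lin]
            M = len(sets)
            m_i = np.zeros(n_words)
            for ws in sets:
                for w in ws:
                    m_i[w] += 1
            self.loglik[si] = np.log((m_i + prior) / (M + 1))
            # unseen-anywhere words: n_i = 0 -> prior 0.5/(N+1), m_i = 0
            self.log_default[si] = np.log((0.5 / (N + 1)) / (M + 1))

    def query_word_ids(self, seq: str) -> tuple[np.ndarray, int]:
        """(ids of query words known to the db, count of unknown words)."""
        ids = []
        unknown = 0
        words = {seq[i:i + self.k] for i in range(len(seq) - self.k + 1)}
        for w in words:
            wid = self.kmer_ids.get(w)
            if wid is None:
                unknown += 1
            else:
                ids.append(wid)
        return np.array(ids, dtype=np.int64), unknown

    def score(self, word_ids: np.ndarray, n_unknown: int = 0) -> np.ndarray:
        s = self.log_default * n_unknown
        if len(word_ids):
            s = s + self.loglik[:, word_ids].sum(axis=1)
        return s


def nb_classify(query: SequenceRecord, db: ReferenceDatabase, marker: str,
                params: NBParams | None = None,
                model: KmerModel | None = None,
                seed: int = 0) -> ClassificationResult:
    """Wang-style naive-Bayes classification with bootstrap confidence."""
    params = params or NBParams()
    model = model or KmerModel(db, marker, params.kmer_size)
    res = ClassificationResult(otu_id=query.id, method="nb", marker=marker,
                               database=db.name)
    word_ids, n_unknown = model.query_word_ids(query.sequence)
    if len(word_ids) == 0:
        res.unclassified_flag = True
        res.unclassified_reason = "no_shared_kmers"
        return res
    full = model.score(word_ids)
    best = int(np.argmax(full))
    best_lineage = model.lineages[best]

    rng = rng_for(seed, "nb_bootstrap", db.name, query.id)
    n_sub = max(1, len(word_ids) // params.kmer_size)
    agree = np.zeros(len(RANKS))
    for _ in range(params.bootstrap_iters):
        sub = word_ids[rng.integers(0, len(word_ids), size=n_sub)]
        scores = model.score(sub)
        ties = np.flatnonzero(scores == scores.max())
        # a subsample that cannot discriminate tied models votes at random,
        # which is what depresses bootstrap support for confusable congeners
        w = int(ties[rng.integers(0, len(ties))]) if len(ties) > 1 \
            else int(ties[0])
        lin = model.lineages[w]
        for r in range(len(RANKS)):
            if lin[r] == best_lineage[r]:
                agree[r] += 1
    conf = agree / params.bootstrap_iters
    # aggregate votes upward: confidence is monotone toward the root
    for r in range(len(RANKS) - 2, -1, -1):
        conf[r] = max(conf[r], conf[r + 1])
    res.confidences = dict(zip(RANKS, conf.tolist()))

    deepest = -1
    for r in range(len(RANKS)):
        if conf[r] >= params.bootstrap_cutoff:
            deepest = r
        else:
            break
    if deepest < 0:
        res.unclassified_flag = True
        res.unclassified_reason = "bootstrap_below_cutoff"
        return res
    res.assigned = best_lineage
    res.unclassified_ranks = set(RANKS[deepest + 1:])
    res.hit_list = [Hit(lineage=best_lineage, identity=float("nan"),
                        score=float(full[best]))]
    res.equivalence_group = list(res.hit_list)
    if deepest < len(RANKS) - 1:
        res.unclassified_reason = "bootstrap_truncated"
    return res


# ---------------------------------------------------------------------------
# 1-nearest-neighbour
# ---------------------------------------------------------------------------

def knn_classify(query: SequenceRecord, db: ReferenceDatabase, marker: str,
                 k: int = 1) -> ClassificationResult:
    """Assign the lineage of the nearest reference by alignment distance.

    Ties break to higher identity then accession order (logged in the hit
    list); never returns unclassified on a non-empty database.
    """
    if k != 1:
        raise NotImplementedError("only the single nearest neighbour is supported")
    entries = db.entries_for(marker)
    if not entries:
        raise ValueError(f"database {db.name!r} has no {marker} entries")
    q = encode(query.sequence)
    scored = []
    for e in entries:
        st = align_stats(q, encode(e.sequence))
        scored.append((st.distance, -st.identity_onegap, e.accession, e))
    scored.sort()
    best = scored[0]
    ties = [s for s in scored if s[0] == best[0]]
    hits = [Hit(lineage=s[3].lineage, identity=-s[1], score=-s[0],
                accession=s[2]) for s in ties]
    return ClassificationResult(
        otu_id=query.id, method="knn", marker=marker, database=db.name,
        hit_list=hits, equivalence_group=[hits[0]], assigned=best[3].lineage,
    )


# ---------------------------------------------------------------------------
# Placeholder demotion
# ---------------------------------------------------------------------------

def truncate_unannotated(result: ClassificationResult,
                         db: ReferenceDatabase | None = None) -> ClassificationResult:
    """Demote placeholder names ("... sp", "unclassified") to unclassified.

    A placeholder at a rank marks that rank and all deeper ranks
    unclassified; a placeholder at every rank flags the whole result.
    """
    if result.unclassified_flag or result.assigned is None:
        return result
    bad: set[str] = set(result.unclassified_ranks)
    for idx, rank in enumerate(RANKS):
        if rank in bad:
            continue
        if is_unannotated(result.assigned[idx]):
            bad.update(RANKS[idx:])
            break
    if set(RANKS) <= bad:
        return replace(result, unclassified_flag=True,
                       unclassified_reason="placeholder", unclassified_ranks=bad)
    if bad != result.unclassified_ranks:
        return replace(result, unclassified_ranks=bad)
    return result
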