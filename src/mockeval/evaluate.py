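"""Adjudication of classifications against mock-community ground truth,
confusion counts, precision/recall/F1, L1 abundance distances, and
abundance-threshold sweeps.

Verdicts are three-way: an OTU is a true positive (correctly classified), a
false positive (incorrectly classified), or a false negative (unclassified)
— incorrect calls are FPs, never FNs.  Two settings exist:

* strict — correct only when a *single* top hit (after collapsing the
  equivalence group at the evaluated rank) names an expected taxon; tied
  distinct top hits count as unclassified;
* loose — correct when an expected taxon appears anywhere in the leading
  equivalence group; a group with no expected taxon is an FP, reported
  under a seeded-random group member.

Synonyms canonicalize both call and truth before comparison.  Genus-level
adjudication reuses the same machinery on genus names; the table-driven
subgeneric step rescues species-level misses whose whole equivalence group
shares the truth member's section/series/species-complex.  The consensus
approach accepts a taxon only when both markers independently call it
correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationResult
from .otu import OTU, RareFilterParams, filter_rare
from .records import closure_canonicalize, genus_of
from .synthetic import MockCommunitySpec, rng_for

VERDICTS = ("TP", "FP", "FN_unclassified")


@dataclass
class AdjudicatedCall:
    otu_id: str
    dmc_id: str
    level: str                      # species | genus | subgeneric
    verdict: str                    # TP | FP | FN_unclassified
    matched_taxon: str | None = None
    equivalence_group_size: int = 0
    setting: str = "strict"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict in ("TP", "FP") and not self.matched_taxon:
            raise ValueError(f"{self.verdict} requires a matched taxon")


@dataclass
class ConfusionCounts:
    dmc_id: str
    level: str
    TP: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN


@dataclass
class MetricsRow:
    """Aggregate precision/recall/F1 over DMCs for one combination."""

    combination: str
    level: str
    precision_mean: float
    precision_sd: float
    recall_mean: float
    recall_sd: float
    f1_mean: float
    f1_sd: float
    n_dmcs_precision: int
    n_dmcs_recall: int


# ---------------------------------------------------------------------------
# Synonyms
# ---------------------------------------------------------------------------

def apply_synonyms(taxon: str, synonym_map: Mapping[str, str] | None) -> str:
    """Map a taxon to its canonical representative (chains resolved)."""
    if not synonym_map:
        return taxon
    canon = closure_canonicalize(synonym_map)
    return canon.get(taxon, taxon)


def _canonicalizer(synonym_map: Mapping[str, str] | None):
    canon = closure_canonicalize(synonym_map) if synonym_map else {}
    return lambda t: canon.get(t, t)


def _names_at_level(result: ClassificationResult, level: str,
                    canon) -> list[str]:
    """Distinct post-synonym leading-group names at the evaluated rank.

    Genus names derive from canonicalized species names (so synonyms that
    cross genera resolve correctly); when the species rank is unclassified
    but the genus rank is not, the genus names are used directly.
    """
    if level == "genus":
        sp = result.group_names_at("species")
        if sp:
            return sorted({genus_of(canon(n)) for n in sp})
        return sorted({canon(n) for n in result.group_names_at("genus")})
    return sorted({canon(n) for n in result.group_names_at("species")})


def _truth_at_level(truth: MockCommunitySpec, level: str, canon) -> set[str]:
    if level == "genus":
        return {genus_of(canon(m)) for m in truth.members}
    return {canon(m) for m in truth.members}


# ---------------------------------------------------------------------------
# Strict / loose adjudication
# ---------------------------------------------------------------------------

def adjudicate_strict(result: ClassificationResult, truth: MockCommunitySpec,
                      level: str = "species",
                      synonym_map: Mapping[str, str] | None = None,
                      ) -> AdjudicatedCall:
    """Single unambiguous top hit required; tied distinct names at the
    evaluated rank count as unclassified."""
    canon = _canonicalizer(synonym_map)
    names = _names_at_level(result, level, canon)
    expected = _truth_at_level(truth, level, canon)
    base = dict(otu_id=result.otu_id, dmc_id=truth.dmc_id, level=level,
                setting="strict")
    if not names:
        return AdjudicatedCall(verdict="FN_unclassified",
                               notes=result.unclassified_reason or "unclassified",
                               equivalence_group_size=0, **base)
    if len(names) > 1:
        return AdjudicatedCall(verdict="FN_unclassified",
                               notes="multiple_equivalent_hits",
                               equivalence_group_size=len(names), **base)
    name = names[0]
    verdict = "TP" if name in expected else "FP"
    return AdjudicatedCall(verdict=verdict, matched_taxon=name,
                           equivalence_group_size=1, **base)


def adjudicate_loose(result: ClassificationResult, truth: MockCommunitySpec,
                     level: str = "species",
                     synonym_map: Mapping[str, str] | None = None,
                     seed: int = 0) -> AdjudicatedCall:
    """Expected taxon anywhere in the equivalence group counts as correct;
    a group with no expected taxon is an FP attributed to a seeded-random
    group member."""
    canon = _canonicalizer(synonym_map)
    names = _names_at_level(result, level, canon)
    expected = _truth_at_level(truth, level, canon)
    base = dict(otu_id=result.otu_id, dmc_id=truth.dmc_id, level=level,
                setting="loose")
    if not names:
        return AdjudicatedCall(verdict="FN_unclassified",
                               notes=result.unclassified_reason or "unclassified",
                               equivalence_group_size=0, **base)
    matched = sorted(set(names) & expected)
    if matched:
        return AdjudicatedCall(verdict="TP", matched_taxon=matched[0],
                               equivalence_group_size=len(names), **base)
    rng = rng_for(seed, "loose_fp", truth.dmc_id, result.otu_id,
                  result.database, result.method, level)
    pick = names[int(rng.integers(0, len(names)))]
    return AdjudicatedCall(verdict="FP", matched_taxon=pick,
                           equivalence_group_size=len(names), **base)


def adjudicate(result: ClassificationResult, truth: MockCommunitySpec,
               level: str = "species", setting: str = "strict",
               synonym_map: Mapping[str, str] | None = None,
               seed: int = 0) -> AdjudicatedCall:
    if setting == "strict":
        return adjudicate_strict(result, truth, level, synonym_map)
    if setting == "loose":
        return adjudicate_loose(result, truth, level, synonym_map, seed)
    raise ValueError(f"unknown setting {setting!r}")


def adjudicate_at_genus(result: ClassificationResult, truth: MockCommunitySpec,
                        setting: str = "strict",
                        synonym_map: Mapping[str, str] | None = None,
                        seed: int = 0) -> AdjudicatedCall:
    """Genus-level adjudication: species-level FPs whose genus is expected
    become genus-level TPs."""
    return adjudicate(result, truth, "genus", setting, synonym_map, seed)


# ---------------------------------------------------------------------------
# Subgeneric rescue
# ---------------------------------------------------------------------------

def map_subgeneric(call: AdjudicatedCall, result: ClassificationResult,
                   truth: MockCommunitySpec,
                   subgeneric_map: Mapping[str, tuple[str, str]],
                   synonym_map: Mapping[str, str] | None = None,
                   ) -> AdjudicatedCall:
    """Rescue a species-level non-TP at the subgeneric rank.

    The rescue fires only when every leading-equivalence-group member maps
    to the same section/series/species-complex as some truth member; calls
    with unmapped names are left unchanged (noted).
    """
    if call.level != "species" or call.verdict == "TP":
        return call
    canon = _canonicalizer(synonym_map)
    names = _names_at_level(result, "species", canon)
    if not names:
        return call
    groups = set()
    for n in names:
        entry = subgeneric_map.get(n)
        if entry is None:
            return AdjudicatedCall(
                otu_id=call.otu_id, dmc_id=call.dmc_id, level=call.level,
                verdict=call.verdict, matched_taxon=call.matched_taxon,
                equivalence_group_size=call.equivalence_group_size,
                setting=call.setting, notes="subgeneric_unmapped")
        groups.add(entry)
    truth_groups = {subgeneric_map[canon(m)] for m in truth.members
                    if canon(m) in subgeneric_map}
    if len(groups) == 1 and next(iter(groups)) in truth_groups:
        kind, name = next(iter(groups))
        return AdjudicatedCall(
            otu_id=call.otu_id, dmc_id=call.dmc_id, level="subgeneric",
            verdict="TP", matched_taxon=f"{kind}:{name}",
            equivalence_group_size=call.equivalence_group_size,
            setting=call.setting, notes="subgeneric_rescue")
    return call


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusOutcome:
    dmc_id: str
    level: str
    tp_taxa: set[str]
    fp_taxa: set[str]
    fn_taxa: set[str]

    def counts(self) -> ConfusionCounts:
        return ConfusionCounts(dmc_id=self.dmc_id, level=self.level,
                               TP=len(self.tp_taxa), FP=len(self.fp_taxa),
                               FN=len(self.fn_taxa))


def consensus_combine(calls_its1: Sequence[AdjudicatedCall],
                      calls_its2: Sequence[AdjudicatedCall],
                      truth: MockCommunitySpec, level: str = "species",
                      synonym_map: Mapping[str, str] | None = None,
                      ) -> ConsensusOutcome:
    """Taxon-level consensus: accepted only when both markers call it
    correctly at the same level.

    A taxon called (TP or FP) in at least one marker that is not a
    consensus TP and not a truth member becomes a consensus FP; truth
    members missing from the consensus TP set count toward FN.
    """
    canon = _canonicalizer(synonym_map)
    expected = _truth_at_level(truth, level, canon)

    def tp_taxa(calls):
        return {canon(c.matched_taxon) for c in calls
                if c.level == level and c.verdict == "TP" and c.matched_taxon}

    def called_taxa(calls):
        return {canon(c.matched_taxon) for c in calls
                if c.level == level and c.verdict in ("TP", "FP")
                and c.matched_taxon}

    tp = tp_taxa(calls_its1) & tp_taxa(calls_its2)
    called = called_taxa(calls_its1) | called_taxa(calls_its2)
    fp = {t for t in called if t not in tp and t not in expected}
    fn = expected - tp
    return ConsensusOutcome(dmc_id=truth.dmc_id, level=level,
                            tp_taxa=tp, fp_taxa=fp, fn_taxa=fn)


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

def confusion_counts(calls: Iterable[AdjudicatedCall],
                     level: str | None = None) -> dict[str, ConfusionCounts]:
    """Tally TP/FP/FN (unit: one adjudicated OTU) per DMC."""
    out: dict[str, ConfusionCounts] = {}
    for c in calls:
        if level is not None and c.level != level:
            continue
        cc = out.setdefault(c.dmc_id,
                            ConfusionCounts(dmc_id=c.dmc_id,
                                            level=level or c.level))
        if c.verdict == "TP":
            cc.TP += 1
        elif c.verdict == "FP":
            cc.FP += 1
        else:
            cc.FN += 1
    return out


def precision_pct(tp: int, fp: int) -> float | None:
    return 100.0 * tp / (tp + fp) if (tp + fp) else None


def recall_pct(tp: int, fn: int) -> float | None:
    return 100.0 * tp / (tp + fn) if (tp + fn) else None


def f1_score(tp: int, fp: int, fn: int) -> float | None:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else None


def _mean_sd(values: list[float]) -> tuple[float, float, int]:
    vals = [v for v in values if v is not None]
    if not vals:
        return float("nan"), float("nan"), 0
    mean = sum(vals) / len(vals)
    if len(vals) < 2:
        return mean, 0.0, len(vals)
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    return mean, math.sqrt(var), len(vals)


def metrics(counts: Iterable[ConfusionCounts], combination: str = "",
            level: str = "") -> MetricsRow:
    """Per-DMC precision/recall/F1 aggregated as mean +/- sample sd.

    DMCs where a metric's denominator is zero are excluded from that
    metric's mean and sd.
    """
    counts = list(counts)
    precisions = [precision_pct(c.TP, c.FP) for c in counts]
    recalls = [recall_pct(c.TP, c.FN) for c in counts]
    f1s = [f1_score(c.TP, c.FP, c.FN) for c in counts]
    pm, ps, np_ = _mean_sd(precisions)
    rm, rs, nr = _mean_sd(recalls)
    fm, fs, _ = _mean_sd(f1s)
    lv = level or (counts[0].level if counts else "")
    return MetricsRow(combination=combination, level=lv,
                      precision_mean=pm, precision_sd=ps,
                      recall_mean=rm, recall_sd=rs,
                      f1_mean=fm, f1_sd=fs,
                      n_dmcs_precision=np_, n_dmcs_recall=nr)


# ---------------------------------------------------------------------------
# Abundance profiles and L1
# ---------------------------------------------------------------------------

@dataclass
class AbundanceComparison:
    dmc_id: str
    observed: dict[str, float]
    theoretical: dict[str, float]
    l1: float | None


def abundance_profile(otus: Sequence[OTU], calls: Sequence[AdjudicatedCall],
                      truth: MockCommunitySpec, level: str = "species",
                      synonym_map: Mapping[str, str] | None = None,
                      ) -> AbundanceComparison:
    """Observed taxon fractions over classified reads vs 20% theory.

    Reads of unclassified OTUs are excluded and the remaining fractions are
    renormalized; L1 = sum over taxa of |observed - theoretical| with
    theoretical 1/5 for members and 0 for non-members.  When no reads are
    classified, L1 is undefined (None).
    """
    canon = _canonicalizer(synonym_map)
    by_otu = {o.otu_id: o for o in otus}
    taxon_reads: dict[str, float] = {}
    for c in calls:
        if c.level != level or c.verdict == "FN_unclassified":
            continue
        otu = by_otu.get(c.otu_id)
        if otu is None or c.matched_taxon is None:
            continue
        reads = otu.per_dmc_counts.get(truth.dmc_id, otu.total_count)
        taxon = canon(c.matched_taxon)
        taxon_reads[taxon] = taxon_reads.get(taxon, 0.0) + reads
    total = sum(taxon_reads.values())
    theoretical = {
        (genus_of(canon(m)) if level == "genus" else canon(m)): 0.0
        for m in truth.members}
    for m, a in truth.theoretical_abundances.items():
        key = genus_of(canon(m)) if level == "genus" else canon(m)
        theoretical[key] += a
    if total == 0:
        return AbundanceComparison(truth.dmc_id, {}, theoretical, None)
    observed = {t: r / total for t, r in taxon_reads.items()}
    taxa = set(observed) | set(theoretical)
    l1 = sum(abs(observed.get(t, 0.0) - theoretical.get(t, 0.0)) for t in taxa)
    return AbundanceComparison(truth.dmc_id, observed, theoretical, l1)


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepParams:
    thresholds: tuple[float, ...] = tuple(
        round(0.0005 * i, 6) for i in range(21))   # 0 .. 1% step 0.05%

    def __post_init__(self) -> None:
        t = self.thresholds
        if list(t) != sorted(t) or any(x < 0 or x > 1 for x in t):
            raise ValueError("thresholds must be ascending within [0, 1]")


def threshold_sweep(
    otus_by_dmc: Mapping[str, Sequence[OTU]],
    results_by_otu: Mapping[str, ClassificationResult],
    truths: Mapping[str, MockCommunitySpec],
    level: str = "species",
    setting: str = "loose",
    synonym_map: Mapping[str, str] | None = None,
    sweep: SweepParams | None = None,
    rare_params: RareFilterParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-filter, re-adjudicate, and re-score at each abundance threshold.

    ``otus_by_dmc`` must hold the *pre-filter* OTU tables.  Returns a tidy
    frame with one row per threshold carrying the aggregate metrics and the
    surviving-OTU count.
    """
    sweep = sweep or SweepParams()
    rare_params = rare_params or RareFilterParams()
    rows = []
    for thr in sweep.thresholds:
        calls: list[AdjudicatedCall] = []
        n_otus = 0
        for dmc_id, otus in otus_by_dmc.items():
            surviving = filter_rare(list(otus), rare_params,
                                    threshold_override=thr)
            n_otus += len(surviving)
            truth = truths[dmc_id]
            for o in surviving:
                res = results_by_otu.get(o.otu_id)
                if res is None:
                    continue
                calls.append(adjudicate(res, truth, level, setting,
                                        synonym_map, seed))
        counts = confusion_counts(calls, level)
        row = metrics(counts.values(), combination=f"threshold={thr}",
                      level=level)
        rows.append({
            "threshold": thr, "level": level, "setting": setting,
            "n_otus": n_otus,
            "precision_mean": row.precision_mean,
            "precision_sd": row.precision_sd,
            "recall_mean": row.recall_mean, "recall_sd": row.recall_sd,
            "f1_mean": row.f1_mean, "f1_sd": row.f1_sd,
            "n_dmcs_precision": row.n_dmcs_precision,
            "n_dmcs_recall": row.n_dmcs_recall,
        })
    return pd.DataFrame(rows)
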