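"""Adjudication rules, confusion counts, metrics, L1, threshold sweeps."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mockeval.classify import ClassificationResult, Hit
from mockeval.evaluate import (ConfusionCounts,
                               SweepParams, abundance_profile, adjudicate,
                               adjudicate_loose, adjudicate_strict,
                               apply_synonyms, confusion_counts,
                               consensus_combine, map_subgeneric, metrics,
                               threshold_sweep)
from mockeval.otu import OTU
from mockeval.records import SequenceRecord
from mockeval.synthetic import MockCommunitySpec

from _oracles import oracle_l1, oracle_metrics


def truth(members, dmc_id="dmc01"):
    return MockCommunitySpec(
        dmc_id=dmc_id, members=tuple(members),
        theoretical_abundances={m: 1 / len(members) for m in members})


def result(group_species, otu_id="otu1", unclassified=False):
    """Build a classification result with the given tied species names."""
    hits = [Hit(lineage=("Fungi", "P", "C", "O", "F", sp.split()[0], sp),
                identity=0.99, score=100)
            for sp in group_species]
    return ClassificationResult(
        otu_id=otu_id, method="tophit", marker="ITS1", database="db",
        hit_list=hits, equivalence_group=hits,
        assigned=hits[0].lineage if hits else None,
        unclassified_flag=unclassified,
        unclassified_reason="forced" if unclassified else "")


TRUTH5 = truth(["GenA sp1", "GenB sp1", "GenC sp1", "GenD sp1", "GenE sp1"])


class TestSynonyms:
    def test_either_synonym_matches(self):
        syn = {"Mycosphaerella tassiana": "Cladosporium herbarum"}
        call = adjudicate_strict(result(["Mycosphaerella tassiana"]),
                                 truth(["Cladosporium herbarum", "GenB sp1",
                                        "GenC sp1", "GenD sp1", "GenE sp1"]),
                                 "species", synonym_map=syn)
        assert call.verdict == "TP"

    def test_identity_without_entry(self):
        assert apply_synonyms("GenA sp1", {}) == "GenA sp1"
        assert apply_synonyms("GenA sp1", {"X": "Y"}) == "GenA sp1"

    def test_chained_synonyms_canonicalize_together(self):
        syn = {"A a": "B b", "B b": "C c"}
        assert apply_synonyms("A a", syn) == apply_synonyms("B b", syn) \
            == apply_synonyms("C c", syn) == "C c"


class TestStrict:
    def test_single_member_hit_tp(self):
        call = adjudicate_strict(result(["GenA sp1"]), TRUTH5, "species")
        assert call.verdict == "TP"
        assert call.matched_taxon == "GenA sp1"

    def test_tied_hits_including_member_fn(self):
        call = adjudicate_strict(result(["GenA sp1", "GenA sp2"]), TRUTH5,
                                 "species")
        assert call.verdict == "FN_unclassified"
        assert call.notes == "multiple_equivalent_hits"

    def test_single_non_member_fp(self):
        call = adjudicate_strict(result(["GenZ sp9"]), TRUTH5, "species")
        assert call.verdict == "FP"

    def test_unclassified_fn(self):
        call = adjudicate_strict(result([], unclassified=True), TRUTH5,
                                 "species")
        assert call.verdict == "FN_unclassified"


class TestLoose:
    def test_member_within_group_tp(self):
        call = adjudicate_loose(result(["GenA sp1", "GenA sp2"]), TRUTH5,
                                "species", seed=1)
        assert call.verdict == "TP"
        assert call.matched_taxon == "GenA sp1"

    def test_group_without_member_fp_seeded_pick(self):
        r = result(["GenZ sp1", "GenZ sp2"])
        c1 = adjudicate_loose(r, TRUTH5, "species", seed=1)
        c2 = adjudicate_loose(r, TRUTH5, "species", seed=1)
        assert c1.verdict == "FP"
        assert c1.matched_taxon in {"GenZ sp1", "GenZ sp2"}
        assert c1.matched_taxon == c2.matched_taxon   # reproducible

    def test_strict_tp_implies_loose_tp(self):
        r = result(["GenA sp1"])
        assert adjudicate_strict(r, TRUTH5, "species").verdict == "TP"
        assert adjudicate_loose(r, TRUTH5, "species").verdict == "TP"


class TestGenusLevel:
    def test_species_fp_with_member_genus_is_genus_tp(self):
        r = result(["GenA sp9"])   # wrong species, right genus
        assert adjudicate_strict(r, TRUTH5, "species").verdict == "FP"
        assert adjudicate_strict(r, TRUTH5, "genus").verdict == "TP"

    def test_congener_tie_collapses_to_single_genus(self):
        r = result(["GenA sp1", "GenA sp2", "GenA sp3"])
        assert adjudicate_strict(r, TRUTH5, "species").verdict \
            == "FN_unclassified"
        assert adjudicate_strict(r, TRUTH5, "genus").verdict == "TP"

    def test_species_tp_implies_genus_tp(self):
        r = result(["GenC sp1"])
        assert adjudicate_strict(r, TRUTH5, "species").verdict == "TP"
        assert adjudicate_strict(r, TRUTH5, "genus").verdict == "TP"


class TestSubgeneric:
    SUBMAP = {"GenA sp1": ("section", "Alpha"),
              "GenA sp2": ("section", "Alpha"),
              "GenA sp3": ("section", "Alpha"),
              "GenA sp4": ("section", "Beta")}

    def test_congener_group_in_same_section_rescued(self):
        r = result(["GenA sp2", "GenA sp3"])
        call = adjudicate_strict(r, TRUTH5, "species")
        out = map_subgeneric(call, r, TRUTH5, self.SUBMAP)
        assert out.level == "subgeneric"
        assert out.verdict == "TP"
        assert out.matched_taxon == "section:Alpha"

    def test_group_spanning_sections_unchanged(self):
        r = result(["GenA sp2", "GenA sp4"])
        call = adjudicate_strict(r, TRUTH5, "species")
        out = map_subgeneric(call, r, TRUTH5, self.SUBMAP)
        assert out.verdict == call.verdict
        assert out.level == "species"

    def test_species_tp_not_touched(self):
        r = result(["GenA sp1"])
        call = adjudicate_strict(r, TRUTH5, "species")
        out = map_subgeneric(call, r, TRUTH5, self.SUBMAP)
        assert out is call

    def test_unmapped_name_logged_and_unchanged(self):
        r = result(["GenA sp9"])
        call = adjudicate_strict(r, TRUTH5, "species")
        out = map_subgeneric(call, r, TRUTH5, self.SUBMAP)
        assert out.verdict == "FP"
        assert out.notes == "subgeneric_unmapped"


class TestConsensus:
    def _calls(self, verdict_taxa, level="species"):
        calls = []
        for i, (verdict, taxon) in enumerate(verdict_taxa):
            from mockeval.evaluate import AdjudicatedCall
            calls.append(AdjudicatedCall(
                otu_id=f"o{i}", dmc_id=TRUTH5.dmc_id, level=level,
                verdict=verdict, matched_taxon=taxon,
                equivalence_group_size=1))
        return calls

    def test_tp_in_both_markers_is_consensus_tp(self):
        c1 = self._calls([("TP", "GenA sp1")])
        c2 = self._calls([("TP", "GenA sp1")])
        out = consensus_combine(c1, c2, TRUTH5, "species")
        assert out.tp_taxa == {"GenA sp1"}
        assert out.counts().TP == 1

    def test_tp_in_one_marker_only_is_not_consensus_tp(self):
        c1 = self._calls([("TP", "GenA sp1")])
        out = consensus_combine(c1, [], TRUTH5, "species")
        assert out.tp_taxa == set()
        assert "GenA sp1" in out.fn_taxa

    def test_fp_taxon_in_both_markers_is_consensus_fp(self):
        c1 = self._calls([("FP", "GenZ sp9")])
        c2 = self._calls([("FP", "GenZ sp9")])
        out = consensus_combine(c1, c2, TRUTH5, "species")
        assert out.fp_taxa == {"GenZ sp9"}

    def test_consensus_subset_of_marker_tps(self):
        c1 = self._calls([("TP", "GenA sp1"), ("TP", "GenB sp1"),
                          ("FP", "GenZ sp1")])
        c2 = self._calls([("TP", "GenB sp1"), ("TP", "GenC sp1")])
        out = consensus_combine(c1, c2, TRUTH5, "species")
        tp1 = {"GenA sp1", "GenB sp1"}
        tp2 = {"GenB sp1", "GenC sp1"}
        assert out.tp_taxa <= (tp1 & tp2)


class TestConfusionAndMetrics:
    def test_tally_and_brute_force_recount(self, rng):
        from mockeval.evaluate import AdjudicatedCall
        verdicts = ["TP", "FP", "FN_unclassified"]
        calls = []
        for i in range(60):
            v = verdicts[int(rng.integers(0, 3))]
            calls.append(AdjudicatedCall(
                otu_id=f"o{i}", dmc_id=f"dmc{int(rng.integers(1, 4)):02d}",
                level="species", verdict=v,
                matched_taxon="X x" if v != "FN_unclassified" else None))
        out = confusion_counts(calls, "species")
        for dmc_id, cc in out.items():
            sub = [c for c in calls if c.dmc_id == dmc_id]
            assert cc.TP == sum(c.verdict == "TP" for c in sub)
            assert cc.FP == sum(c.verdict == "FP" for c in sub)
            assert cc.FN == sum(c.verdict == "FN_unclassified" for c in sub)
            assert cc.total == len(sub)

    def test_formulas_match_direct_evaluation_exhaustively(self):
        """metrics() agrees with the printed formulas on all
        (TP, FP, FN) in [0,5]^3."""
        for tp, fp, fn in itertools.product(range(6), repeat=3):
            row = metrics([ConfusionCounts("d", "species", tp, fp, fn)])
            op, orc, of1 = oracle_metrics(tp, fp, fn)
            if op is None:
                assert row.n_dmcs_precision == 0
            else:
                assert row.precision_mean == pytest.approx(op)
            if orc is None:
                assert row.n_dmcs_recall == 0
            else:
                assert row.recall_mean == pytest.approx(orc)
            if of1 is not None:
                assert row.f1_mean == pytest.approx(of1)

    def test_worked_example(self):
        row = metrics([ConfusionCounts("d", "species", 3, 1, 2)])
        assert row.precision_mean == pytest.approx(75.0)
        assert row.recall_mean == pytest.approx(60.0)
        assert row.f1_mean == pytest.approx(6 / 9)

    def test_zero_denominator_excluded_from_aggregate(self):
        counts = [ConfusionCounts("d1", "species", 5, 0, 0),
                  ConfusionCounts("d2", "species", 0, 0, 2)]
        row = metrics(counts)
        assert row.precision_mean == pytest.approx(100.0)   # d2 excluded
        assert row.n_dmcs_precision == 1
        assert row.recall_mean == pytest.approx(50.0)       # both defined
        assert row.n_dmcs_recall == 2

    def test_sd_is_sample_sd(self):
        counts = [ConfusionCounts("d1", "species", 4, 0, 1),
                  ConfusionCounts("d2", "species", 2, 0, 3)]
        row = metrics(counts)
        assert row.recall_mean == pytest.approx(60.0)
        assert row.recall_sd == pytest.approx(np.std([80, 40], ddof=1))


def _otu(oid, count, seq="ACGT" * 10, dmc="dmc01"):
    rep = SequenceRecord(id=oid, sequence=seq, weight=count)
    return OTU(otu_id=oid, members={oid: count}, representative=rep,
               per_dmc_counts={dmc: count})


class TestAbundance:
    def _calls_for(self, taxa_counts):
        from mockeval.evaluate import AdjudicatedCall
        calls, otus = [], []
        for i, (taxon, count) in enumerate(taxa_counts):
            oid = f"o{i}"
            otus.append(_otu(oid, count))
            if taxon is None:
                calls.append(AdjudicatedCall(
                    otu_id=oid, dmc_id="dmc01", level="species",
                    verdict="FN_unclassified"))
            else:
                verdict = "TP" if taxon in TRUTH5.members else "FP"
                calls.append(AdjudicatedCall(
                    otu_id=oid, dmc_id="dmc01", level="species",
                    verdict=verdict, matched_taxon=taxon))
        return otus, calls

    def test_perfect_profile_l1_zero(self):
        otus, calls = self._calls_for([(m, 200) for m in TRUTH5.members])
        cmp = abundance_profile(otus, calls, TRUTH5, "species")
        assert cmp.l1 == pytest.approx(0.0)

    def test_all_mass_on_non_members_l1_two(self):
        otus, calls = self._calls_for([("GenZ sp1", 500), ("GenZ sp2", 500)])
        cmp = abundance_profile(otus, calls, TRUTH5, "species")
        assert cmp.l1 == pytest.approx(2.0)

    def test_skewed_member_l1(self):
        counts = [("GenA sp1", 400), ("GenC sp1", 200), ("GenD sp1", 200),
                  ("GenE sp1", 200)]   # GenB missing, GenA doubled
        otus, calls = self._calls_for(counts)
        cmp = abundance_profile(otus, calls, TRUTH5, "species")
        assert cmp.l1 == pytest.approx(0.4)
        assert cmp.l1 == pytest.approx(oracle_l1(cmp.observed,
                                                 cmp.theoretical))

    def test_unclassified_reads_excluded_and_renormalized(self):
        otus, calls = self._calls_for([("GenA sp1", 100), (None, 900)])
        cmp = abundance_profile(otus, calls, TRUTH5, "species")
        assert cmp.observed == {"GenA sp1": pytest.approx(1.0)}

    def test_no_classified_reads_l1_undefined(self):
        otus, calls = self._calls_for([(None, 500)])
        cmp = abundance_profile(otus, calls, TRUTH5, "species")
        assert cmp.l1 is None

    def test_l1_bounds_on_random_profiles(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 6))
            taxa = [f"Gen{c} sp1" for c in "AZBYCX"[:n]]
            counts = rng.integers(1, 500, size=n)
            otus, calls = self._calls_for(list(zip(taxa, counts)))
            cmp = abundance_profile(otus, calls, TRUTH5, "species")
            assert 0.0 <= cmp.l1 <= 2.0


class TestSweep:
    def _setup(self):
        otus = {"dmc01": [_otu("o1", 960), _otu("o2", 25), _otu("o3", 10),
                          _otu("o4", 4), _otu("o5", 1)]}
        results = {f"o{i}": result(["GenA sp1"], otu_id=f"o{i}")
                   for i in range(1, 6)}
        truths = {"dmc01": TRUTH5}
        return otus, results, truths

    def test_default_grid_has_21_thresholds(self):
        assert len(SweepParams().thresholds) == 21
        assert SweepParams().thresholds[0] == 0.0
        assert SweepParams().thresholds[-1] == pytest.approx(0.01)

    def test_survivor_counts_non_increasing(self):
        otus, results, truths = self._setup()
        df = threshold_sweep(otus, results, truths)
        assert len(df) == 21
        assert (np.diff(df.n_otus.values) <= 0).all()

    def test_zero_threshold_is_superset_of_default(self):
        from mockeval.otu import filter_rare
        otus, _, _ = self._setup()
        at0 = {o.otu_id for o in filter_rare(otus["dmc01"],
                                             threshold_override=0.0)}
        atdef = {o.otu_id for o in filter_rare(otus["dmc01"])}
        assert atdef <= at0


# ---------------------------------------------------------------------------
# Randomized containment properties
# ---------------------------------------------------------------------------

SPECIES_POOL = [f"Gen{g} sp{s}" for g in "ABCDEFGH" for s in (1, 2, 3)]


@st.composite
def scenario(draw):
    members = draw(st.permutations(SPECIES_POOL).map(lambda p: p[:5]))
    group = draw(st.lists(st.sampled_from(SPECIES_POOL), min_size=1,
                          max_size=4, unique=True))
    unclassified = draw(st.booleans())
    return tuple(members), tuple(group), unclassified


@given(scenario())
@settings(max_examples=300, deadline=None, derandomize=True)
def test_rule_containment_properties(sc):
    """strict-TP => loose-TP; species-TP => genus-TP; consensus TP subset."""
    members, group, unclassified = sc
    t = truth(list(members))
    r = result(list(group), unclassified=unclassified)
    s_sp = adjudicate_strict(r, t, "species")
    l_sp = adjudicate_loose(r, t, "species", seed=0)
    s_gn = adjudicate_strict(r, t, "genus")
    l_gn = adjudicate_loose(r, t, "genus", seed=0)
    if s_sp.verdict == "TP":
        assert l_sp.verdict == "TP"
    if s_gn.verdict == "TP":
        assert l_gn.verdict == "TP"
    if l_sp.verdict == "TP":
        assert l_gn.verdict == "TP"   # species-TP implies genus-TP
    out = consensus_combine([l_sp], [l_sp], t, "species")
    tp1 = {l_sp.matched_taxon} if l_sp.verdict == "TP" else set()
    assert out.tp_taxa <= tp1
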